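"""Readers and writers for the interchange formats.

Column schemas
--------------
midlines.csv     : frame, point_index, x, y[, time] — image-pixel
                   coordinates (x rightward, y downward), 0-based frames,
                   points ordered head to tail.
annotation.csv   : frame, channel_start_s, channel_end_s — body-coordinate
                   channel limits; empty cells mean the frame is free.
activity.csv     : interval, activity.
scores.csv       : worm_id, group, event_day, status (dead|censored).
kymograph.csv    : first column s, remaining columns one per frame (header
                   holds the frame times in seconds).
Ground truth sidecars are plain ``key: value`` text files.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    ActivityTrace,
    ConstraintAnnotation,
    CurvatureKymograph,
    FrameStack,
    Midline,
    SurvivalRecord,
)
from .exceptions import SchemaError

__all__ = [
    "read_frame_stack", "write_frame_stack",
    "read_activity_trace", "write_activity_trace",
    "read_midlines", "write_midlines",
    "read_annotation", "write_annotation",
    "read_score_sheet", "write_score_sheet",
    "read_kymograph", "write_kymograph",
    "write_ground_truth", "write_metadata",
]

_STATUS_VALUES = ("dead", "censored")


# --------------------------------------------------------------------------
# frame stacks (multi-page TIFF or a directory of numbered images)


def read_frame_stack(path: Union[str, Path],
                     frame_interval: float = 1.0) -> FrameStack:
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise SchemaError(f"no image files found in {path}")
        frames = [_read_single(p) for p in files]
    else:
        try:
            arr = tifffile.imread(path)
        except Exception as err:
            raise SchemaError(f"cannot read TIFF stack {path}: {err}") from err
        if arr.ndim not in (2, 3):
            raise SchemaError(f"{path}: expected a 2D/3D grayscale stack")
        frames = [arr] if arr.ndim == 2 else list(arr)
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise SchemaError(f"frames have mixed shapes: {sorted(shapes)}")
    dtypes = {f.dtype for f in frames}
    if len(dtypes) != 1:
        raise SchemaError(f"frames have mixed bit depths: {sorted(map(str, dtypes))}")
    if len(frames) < 2:
        raise SchemaError("a frame stack needs at least 2 frames")
    return FrameStack(frames=np.stack(frames).astype(float),
                      frame_interval=frame_interval)


def _read_single(p: Path) -> np.ndarray:
    try:
        arr = tifffile.imread(p)
    except Exception as err:
        raise SchemaError(f"cannot read image {p}: {err}") from err
    if arr.ndim != 2:
        raise SchemaError(f"{p} is not a single-channel 2D image")
    return arr


def write_frame_stack(stack: FrameStack, path: Union[str, Path]) -> None:
    tifffile.imwrite(str(path), stack.frames.astype(np.float32),
                     photometric="minisblack")


# --------------------------------------------------------------------------
# CSV helpers


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def write_activity_trace(trace: ActivityTrace, path: Union[str, Path]) -> None:
    pd.DataFrame({"interval": np.arange(len(trace)),
                  "activity": trace.values}).to_csv(path, index=False)


def read_activity_trace(path: Union[str, Path],
                        frame_interval: float = 1.0) -> ActivityTrace:
    df = pd.read_csv(path)
    _require_columns(df, ["interval", "activity"], "activity trace")
    df = df.sort_values("interval")
    return ActivityTrace(values=df["activity"].to_numpy(dtype=float),
                         frame_interval=frame_interval)


def write_midlines(midlines: Sequence[Midline], path: Union[str, Path]) -> None:
    rows = []
    for frame, ml in enumerate(midlines):
        for i, (x, y) in enumerate(ml.points):
            rows.append((frame, i, x, y, ml.timestamp))
    pd.DataFrame(rows, columns=["frame", "point_index", "x", "y", "time"]) \
        .to_csv(path, index=False)


def read_midlines(path: Union[str, Path]) -> List[Midline]:
    df = pd.read_csv(path)
    _require_columns(df, ["frame", "point_index", "x", "y"], "midline file")
    midlines = []
    for frame, grp in df.groupby("frame", sort=True):
        idx = grp["point_index"].to_numpy()
        if not np.all(np.diff(idx) > 0):
            raise SchemaError(
                f"midline file: point_index not strictly increasing in frame {frame}"
            )
        ts = float(grp["time"].iloc[0]) if "time" in grp.columns else float(frame)
        midlines.append(Midline(points=grp[["x", "y"]].to_numpy(dtype=float),
                                timestamp=ts))
    if not midlines:
        raise SchemaError("midline file contains no frames")
    return midlines


def write_annotation(ann: ConstraintAnnotation, path: Union[str, Path]) -> None:
    pd.DataFrame({
        "frame": np.arange(ann.anterior.size),
        "channel_start_s": ann.anterior,
        "channel_end_s": ann.posterior,
    }).to_csv(path, index=False)


def read_annotation(path: Union[str, Path],
                    n_frames: Optional[int] = None) -> ConstraintAnnotation:
    df = pd.read_csv(path)
    _require_columns(df, ["frame", "channel_start_s", "channel_end_s"],
                     "annotation file")
    frames = df["frame"].to_numpy(dtype=int)
    size = n_frames if n_frames is not None else int(frames.max()) + 1
    anterior = np.full(size, np.nan)
    posterior = np.full(size, np.nan)
    inside = frames < size
    anterior[frames[inside]] = df["channel_start_s"].to_numpy(dtype=float)[inside]
    posterior[frames[inside]] = df["channel_end_s"].to_numpy(dtype=float)[inside]
    return ConstraintAnnotation(anterior=anterior, posterior=posterior)


def write_score_sheet(records: Sequence[SurvivalRecord],
                      path: Union[str, Path]) -> None:
    pd.DataFrame(
        [(r.worm_id, r.group, r.event_day, r.status) for r in records],
        columns=["worm_id", "group", "event_day", "status"],
    ).to_csv(path, index=False)


def read_score_sheet(path: Union[str, Path]) -> List[SurvivalRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["worm_id", "group", "event_day", "status"],
                     "score sheet")
    bad = df.loc[~df["status"].isin(_STATUS_VALUES)]
    if len(bad):
        raise SchemaError(
            f"score sheet row {bad.index[0]}: status {bad['status'].iloc[0]!r} "
            f"not allowed (allowed: {list(_STATUS_VALUES)})"
        )
    return [
        SurvivalRecord(worm_id=str(r.worm_id), group=str(r.group),
                       event_day=float(r.event_day), status=str(r.status))
        for r in df.itertuples(index=False)
    ]


def write_kymograph(kymo: CurvatureKymograph, path: Union[str, Path]) -> None:
    df = pd.DataFrame(kymo.K, columns=[f"{t:.6f}" for t in kymo.times])
    df.insert(0, "s", kymo.s_grid)
    df.to_csv(path, index=False)
    meta = Path(str(path)).with_suffix(".meta.json")
    meta.write_text(json.dumps({
        "body_length": list(map(float, kymo.body_length)),
    }))


def read_kymograph(path: Union[str, Path]) -> CurvatureKymograph:
    df = pd.read_csv(path)
    if "s" not in df.columns:
        raise SchemaError("kymograph file: missing 's' column")
    s = df["s"].to_numpy(dtype=float)
    times = np.array([float(c) for c in df.columns if c != "s"])
    K = df.drop(columns="s").to_numpy(dtype=float)
    meta = Path(str(path)).with_suffix(".meta.json")
    if meta.exists():
        body_length = np.asarray(json.loads(meta.read_text())["body_length"])
    else:
        body_length = np.ones(times.size)
    return CurvatureKymograph(K=K, s_grid=s, times=times, body_length=body_length)


def write_ground_truth(truth_dict: Dict[str, object],
                       path: Union[str, Path]) -> None:
    """Key-value sidecar; arrays are summarized by length, scalars verbatim."""
    lines = []
    for key, val in truth_dict.items():
        if isinstance(val, np.ndarray):
            lines.append(f"{key}: array(len={val.size})")
        else:
            lines.append(f"{key}: {val}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_metadata(path: Union[str, Path], params: Dict[str, object],
                   seed: Optional[int] = None) -> None:
    from . import __version__
    payload = {"version": __version__, "parameters": params, "seed": seed}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
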