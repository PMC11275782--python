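"""Curvature kymographs and the compensatory curvature response (CCR).

The normalized bending curvature is K(s, t) = k(s, t) * L(t): the signed
midline curvature k times body length L, a dimensionless quantity on the
body coordinate s in [0, 1] (0 = head, 1 = tail). When a worm's mid-body is
held in a straight microfluidic channel, wild-type animals increase their
anterior bending amplitude — the compensatory curvature response. The CCR
statistic is the average of A_const(s)/A_free(s) - 1 over the anterior
interval s in [0.1, 0.3], where A_const is the per-period windowed maximum
of |K| under constraint and A_free the window-averaged free-locomotion
amplitude profile.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import interpolate
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    AmplitudeProfile,
    CCRResult,
    ConstraintAnnotation,
    CurvatureKymograph,
    Midline,
)
from .exceptions import (
    DegenerateProfileError,
    InsufficientDataError,
    InvalidConfigError,
    InvalidMidlineError,
)

__all__ = [
    "CurvatureExtractor",
    "CCRAnalyzer",
    "extract_curvature",
    "free_amplitude_profile",
    "segment_constrained_periods",
    "constrained_amplitude",
    "normalized_anterior_change",
    "ccr_pipeline",
]

_EPS = 1e-12


class CurvatureExtractor(BaseEstimator, TransformerMixin):
    """Turn a sequence of worm midlines into a normalized-curvature kymograph.

    Each midline is fitted with a parametric spline in normalized arc
    length, resampled at ``n_body_points`` uniformly spaced body
    coordinates, and differentiated analytically; the signed curvature
    k = (x'y'' - y'x'') / (x'^2 + y'^2)^{3/2} is multiplied by the frame's
    body length L to give K.

    Parameters
    ----------
    n_body_points : int, default 100
        Number of body-coordinate samples per frame.
    smoothing : float, default 0.0
        Spline smoothing factor per coordinate (scipy ``splrep`` ``s``,
        scaled by the squared midline extent). 0 interpolates exactly;
        raise it for noisy tracked midlines, since curvature is a
        second-derivative quantity.
    """

    def __init__(self, n_body_points: int = 100, smoothing: float = 0.0):
        self.n_body_points = n_body_points
        self.smoothing = smoothing

    def fit(self, X: Sequence[Midline], y=None) -> "CurvatureExtractor":
        if self.n_body_points < 5:
            raise InvalidConfigError("n_body_points must be >= 5")
        return self

    def transform(self, X: Sequence[Midline]) -> CurvatureKymograph:
        self.fit(X)
        midlines = list(X)
        if not midlines:
            raise InvalidMidlineError("empty midline sequence")
        s_grid = np.linspace(0.0, 1.0, self.n_body_points)
        K = np.empty((self.n_body_points, len(midlines)))
        lengths = np.empty(len(midlines))
        times = np.empty(len(midlines))
        for j, ml in enumerate(midlines):
            try:
                K[:, j], lengths[j] = self._frame_curvature(ml, s_grid)
            except InvalidMidlineError as err:
                raise InvalidMidlineError(f"frame {j}: {err}") from err
            times[j] = ml.timestamp
        return CurvatureKymograph(K=K, s_grid=s_grid, times=times,
                                  body_length=lengths)

    def _frame_curvature(self, ml: Midline,
                         s_grid: np.ndarray) -> Tuple[np.ndarray, float]:
        pts = ml.points
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        L = float(seg.sum())
        if L <= 0:
            raise InvalidMidlineError("midline has zero length")
        s_raw = np.concatenate([[0.0], np.cumsum(seg)]) / L
        scale2 = float(np.ptp(pts, axis=0).max()) ** 2
        smooth = self.smoothing * scale2
        k = min(3, len(pts) - 1)
        tck_x = interpolate.splrep(s_raw, pts[:, 0], k=k, s=smooth)
        tck_y = interpolate.splrep(s_raw, pts[:, 1], k=k, s=smooth)
        dx = interpolate.splev(s_grid, tck_x, der=1)
        dy = interpolate.splev(s_grid, tck_y, der=1)
        ddx = interpolate.splev(s_grid, tck_x, der=2)
        ddy = interpolate.splev(s_grid, tck_y, der=2)
        speed2 = dx * dx + dy * dy
        if np.any(speed2 < _EPS):
            raise InvalidMidlineError("degenerate parametrization (zero speed)")
        # curvature of the parametric curve; the parameter is normalized
        # arc length, so the formula absorbs any residual non-uniformity
        kappa = (dx * ddy - dy * ddx) / speed2**1.5
        return kappa * L, L


def extract_curvature(midlines: Sequence[Midline], n_body_points: int = 100,
                      smoothing: float = 0.0) -> CurvatureKymograph:
    """Normalized-curvature kymograph K(s, t) from midlines (see CurvatureExtractor)."""
    return CurvatureExtractor(n_body_points=n_body_points,
                              smoothing=smoothing).transform(midlines)


def free_amplitude_profile(kymo: CurvatureKymograph,
                           window: float = 3.0) -> AmplitudeProfile:
    """Averaged free-locomotion curvature amplitude profile A_free(s).

    The recording is partitioned into consecutive, non-overlapping windows
    of ``window`` seconds; in each window the amplitude at every body
    coordinate is max over t of |K(s, t)|; A_free is the mean across
    windows.
    """
    w = _window_frames(kymo, window)
    n_windows = kymo.K.shape[1] // w
    if n_windows < 1:
        raise InsufficientDataError(
            f"recording shorter than one {window} s window"
        )
    maxima = [
        np.abs(kymo.K[:, i * w:(i + 1) * w]).max(axis=1)
        for i in range(n_windows)
    ]
    return AmplitudeProfile(A=np.mean(maxima, axis=0), s_grid=kymo.s_grid,
                            n_periods=n_windows)


def _window_frames(kymo: CurvatureKymograph, window: float) -> int:
    dt = kymo.frame_interval
    if dt <= 0:
        raise InvalidConfigError("kymograph needs at least two frames")
    w = int(round(window / dt))
    if w < 1:
        raise InvalidConfigError("window must cover at least one frame")
    return w


def segment_constrained_periods(
    kymo: CurvatureKymograph,
    annotation: ConstraintAnnotation,
    window: float = 3.0,
    gate: Tuple[float, float] = (0.35, 0.65),
) -> List[Tuple[int, int]]:
    """Split constrained movement into whole ``window``-second periods.

    A frame qualifies when the channel's anterior and posterior limits both
    lie within ``gate`` (default [0.35, 0.65], i.e. the constraint sits on
    the mid-body). Each maximal run of qualifying frames is partitioned
    into consecutive non-overlapping windows; leftover frames shorter than
    a window are dropped. Returns (start, stop) frame-index pairs.
    """
    if annotation.anterior.size != kymo.K.shape[1]:
        raise InvalidConfigError("annotation is not aligned to the kymograph")
    w = _window_frames(kymo, window)
    ok = (
        annotation.constrained
        & (annotation.anterior >= gate[0] - _EPS)
        & (annotation.posterior <= gate[1] + _EPS)
    )
    periods: List[Tuple[int, int]] = []
    i, n = 0, ok.size
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        for start in range(i, j - w + 1, w):
            periods.append((start, start + w))
        i = j
    return periods


def constrained_amplitude(kymo: CurvatureKymograph,
                          period: Tuple[int, int]) -> AmplitudeProfile:
    """A_const(s) = max over t within the period of |K_const(s, t)|."""
    start, stop = period
    if stop <= start or stop > kymo.K.shape[1]:
        raise InvalidConfigError(f"invalid period {period}")
    return AmplitudeProfile(A=np.abs(kymo.K[:, start:stop]).max(axis=1),
                            s_grid=kymo.s_grid, n_periods=1)


def normalized_anterior_change(
    A_const: AmplitudeProfile,
    A_free: AmplitudeProfile,
    anterior: Tuple[float, float] = (0.1, 0.3),
) -> float:
    """Mean of A_const(s)/A_free(s) over the anterior interval, minus 1."""
    if A_const.s_grid.shape != A_free.s_grid.shape or not np.allclose(
            A_const.s_grid, A_free.s_grid):
        raise InvalidConfigError("profiles are on different body grids")
    mask = (A_const.s_grid >= anterior[0] - _EPS) & (
        A_const.s_grid <= anterior[1] + _EPS)
    if not np.any(mask):
        raise InvalidConfigError("anterior interval contains no grid point")
    if np.any(A_free.A[mask] <= 0):
        raise DegenerateProfileError(
            "free amplitude is zero inside the anterior interval"
        )
    return float(np.mean(A_const.A[mask] / A_free.A[mask]) - 1.0)


class CCRAnalyzer(BaseEstimator):
    """Score the compensatory curvature response of one worm.

    ``fit`` takes the worm's curvature kymograph and per-frame channel
    annotation, builds A_free(s) from the unconstrained frames, segments
    the mid-body-constrained frames into whole windows, and scores each
    period's normalized anterior curvature change.

    Parameters
    ----------
    window : float, default 3.0
        Period length in seconds, used for both free and constrained
        amplitude estimation.
    gate : pair of float, default (0.35, 0.65)
        Body-coordinate interval the channel limits must stay within for a
        frame to count as mid-body constrained.
    anterior : pair of float, default (0.1, 0.3)
        Body-coordinate interval over which the amplitude ratio is
        averaged.
    aggregate : {"mean", "median"}, default "mean"
        Per-worm aggregation across valid periods.

    Attributes
    ----------
    result_ : CCRResult
    free_profile_ : AmplitudeProfile
    """

    def __init__(self, window: float = 3.0,
                 gate: Tuple[float, float] = (0.35, 0.65),
                 anterior: Tuple[float, float] = (0.1, 0.3),
                 aggregate: str = "mean"):
        self.window = window
        self.gate = gate
        self.anterior = anterior
        self.aggregate = aggregate

    def fit(self, X: CurvatureKymograph,
            annotation: ConstraintAnnotation) -> "CCRAnalyzer":
        if self.aggregate not in ("mean", "median"):
            raise InvalidConfigError("aggregate must be 'mean' or 'median'")
        free_mask = ~annotation.constrained
        free_kymo = _contiguous_subkymo(X, free_mask)
        self.free_profile_ = free_amplitude_profile(free_kymo, self.window)
        periods = segment_constrained_periods(X, annotation, self.window,
                                              self.gate)
        profiles, changes = [], []
        for period in periods:
            a_const = constrained_amplitude(X, period)
            ratio = np.full_like(a_const.A, np.nan)
            pos = self.free_profile_.A > 0
            ratio[pos] = a_const.A[pos] / self.free_profile_.A[pos] - 1.0
            profiles.append(ratio)
            changes.append(normalized_anterior_change(
                a_const, self.free_profile_, self.anterior))
        changes_arr = np.asarray(changes, dtype=float)
        if changes_arr.size == 0:
            mean_change = float("nan")
        elif self.aggregate == "mean":
            mean_change = float(np.mean(changes_arr))
        else:
            mean_change = float(np.median(changes_arr))
        self.result_ = CCRResult(
            period_profiles=(np.vstack(profiles) if profiles
                             else np.empty((0, X.s_grid.size))),
            period_changes=changes_arr,
            mean_anterior_change=mean_change,
            n_periods=len(changes),
            s_grid=X.s_grid,
        )
        return self


def _contiguous_subkymo(kymo: CurvatureKymograph,
                        mask: np.ndarray) -> CurvatureKymograph:
    """Restrict a kymograph to the masked frames, keeping the time step.

    Frames are re-indexed onto a uniform grid; window boundaries therefore
    never straddle a masked-out gap longer than a window (gaps contribute
    their own partial windows, which the callers drop).
    """
    if not np.any(mask):
        raise InsufficientDataError("no frames left after masking")
    idx = np.flatnonzero(mask)
    dt = kymo.frame_interval
    return CurvatureKymograph(
        K=kymo.K[:, idx],
        s_grid=kymo.s_grid,
        times=np.arange(idx.size) * dt,
        body_length=kymo.body_length[idx],
    )


def ccr_pipeline(midlines: Sequence[Midline],
                 annotation: ConstraintAnnotation,
                 n_body_points: int = 100, smoothing: float = 0.0,
                 window: float = 3.0,
                 gate: Tuple[float, float] = (0.35, 0.65),
                 anterior: Tuple[float, float] = (0.1, 0.3),
                 aggregate: str = "mean") -> CCRResult:
    """Full CCR analysis: midlines -> kymograph -> per-period anterior change."""
    kymo = extract_curvature(midlines, n_body_points=n_body_points,
                             smoothing=smoothing)
    analyzer = CCRAnalyzer(window=window, gate=gate, anterior=anterior,
                           aggregate=aggregate)
    analyzer.fit(kymo, annotation)
    return analyzer.result_
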