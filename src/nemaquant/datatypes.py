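"""Core data containers shared across the nemaquant pipelines.

Conventions
-----------
* Body coordinate ``s`` runs from 0 at the head to 1 at the tail.
* Normalized bending curvature ``K`` is the local midline curvature ``k``
  (1/length) multiplied by the worm body length ``L``; it is dimensionless
  and signed.
* Times are in seconds, lifespan event days in days of adulthood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import InvalidConfigError, InvalidMidlineError


@dataclass
class FrameStack:
    """Uniformly sampled grayscale movie of a single worm.

    Parameters
    ----------
    frames : ndarray of shape (T, H, W)
        Nonnegative pixel intensities.
    frame_interval : float
        Seconds between consecutive frames.
    """

    frames: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidConfigError(
                f"frames must be a (T, H, W) array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise InvalidConfigError("a frame stack needs at least 2 frames")
        if self.frame_interval <= 0:
            raise InvalidConfigError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ActivityTrace:
    """Per-interval motion activity (changed-pixel counts, possibly smoothed)."""

    values: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidConfigError("activity values must be one-dimensional")
        if np.any(self.values < 0):
            raise InvalidConfigError("activity values must be nonnegative")
        if self.frame_interval <= 0:
            raise InvalidConfigError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class HistogramFit:
    """Seven-parameter fit of an activity histogram.

    Model: ``c1*exp(-a/l1) + c2*exp(-a/l2) + g*exp(-(a-mu)^2/(2*sd^2))``
    fitted to bin counts against bin centers, with the zero bin excluded.
    """

    exp1_amp: float
    exp1_scale: float
    exp2_amp: float
    exp2_scale: float
    gauss_amp: float
    gauss_mean: float
    gauss_sd: float
    bin_edges: np.ndarray
    residual_norm: float
    converged: bool

    def predict(self, a: np.ndarray) -> np.ndarray:
        """Evaluate the fitted mixture at activity values ``a``."""
        a = np.asarray(a, dtype=float)
        return (
            self.exp1_amp * np.exp(-a / self.exp1_scale)
            + self.exp2_amp * np.exp(-a / self.exp2_scale)
            + self.gauss_amp
            * np.exp(-((a - self.gauss_mean) ** 2) / (2.0 * self.gauss_sd**2))
        )


@dataclass
class DwellingResult:
    """Dwelling fraction and the component areas it is derived from."""

    dwelling_fraction: float
    exp_area: float
    gauss_area: float
    fit: Optional[HistogramFit] = None


@dataclass
class Midline:
    """Ordered 2D midline points, head first.

    Coordinates follow the image convention (x rightward, y downward),
    in pixels or micrometers — curvature statistics are unit-free.
    """

    points: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidMidlineError("midline points must be an (N, 2) array")
        if self.points.shape[0] < 10:
            raise InvalidMidlineError(
                f"midline needs >= 10 points, got {self.points.shape[0]}"
            )
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise InvalidMidlineError("consecutive midline points must be distinct")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class CurvatureKymograph:
    """Normalized curvature K(s, t) on a uniform body-coordinate grid.

    ``K`` has shape (M, T): rows are body positions ``s_grid``, columns are
    frames at ``times``. ``body_length`` gives L per frame.
    """

    K: np.ndarray
    s_grid: np.ndarray
    times: np.ndarray
    body_length: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.body_length = np.asarray(self.body_length, dtype=float)
        if self.K.shape != (self.s_grid.size, self.times.size):
            raise InvalidConfigError(
                f"K shape {self.K.shape} does not match (len(s_grid), len(times))"
            )
        if not np.all(np.isfinite(self.K)):
            raise InvalidConfigError("K must be finite")

    @property
    def frame_interval(self) -> float:
        if self.times.size < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


@dataclass
class ConstraintAnnotation:
    """Per-frame channel limits in body coordinates; NaN means unconstrained.

    ``anterior`` and ``posterior`` are arrays aligned with the kymograph's
    frames; where present, 0 <= anterior < posterior <= 1.
    """

    anterior: np.ndarray
    posterior: np.ndarray

    def __post_init__(self) -> None:
        self.anterior = np.asarray(self.anterior, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)
        if self.anterior.shape != self.posterior.shape:
            raise InvalidConfigError("anterior/posterior arrays must align")
        present = ~np.isnan(self.anterior)
        if np.any(np.isnan(self.posterior[present])):
            raise InvalidConfigError("anterior and posterior must be present together")
        a, p = self.anterior[present], self.posterior[present]
        if np.any(a < 0) or np.any(p > 1) or np.any(a >= p):
            raise InvalidConfigError("need 0 <= anterior < posterior <= 1 per frame")

    @property
    def constrained(self) -> np.ndarray:
        """Boolean mask of frames with a recorded channel position."""
        return ~np.isnan(self.anterior)

    @classmethod
    def empty(cls, n_frames: int) -> "ConstraintAnnotation":
        nan = np.full(n_frames, np.nan)
        return cls(anterior=nan.copy(), posterior=nan.copy())


@dataclass
class AmplitudeProfile:
    """Curvature amplitude A(s) >= 0 on a kymograph's body-coordinate grid."""

    A: np.ndarray
    s_grid: np.ndarray
    n_periods: int = 1

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        if self.A.shape != self.s_grid.shape:
            raise InvalidConfigError("A and s_grid must have the same shape")
        if np.any(self.A < 0):
            raise InvalidConfigError("amplitudes must be nonnegative")


@dataclass
class CCRResult:
    """Compensatory curvature response of one worm.

    ``period_profiles`` holds, per valid constrained period, the normalized
    curvature change profile A_const(s)/A_free(s) - 1; ``period_changes``
    the per-period normalized anterior change; ``mean_anterior_change`` the
    arithmetic mean over valid periods (NaN when no period qualified).
    """

    period_profiles: np.ndarray
    period_changes: np.ndarray
    mean_anterior_change: float
    n_periods: int
    s_grid: np.ndarray


@dataclass
class SurvivalRecord:
    """One worm in a lifespan assay."""

    worm_id: str
    group: str
    event_day: float
    status: str  # "dead" or "censored"

    def __post_init__(self) -> None:
        if self.status not in ("dead", "censored"):
            raise InvalidConfigError(
                f"status must be 'dead' or 'censored', got {self.status!r}"
            )
        if self.event_day <= 0:
            raise InvalidConfigError("event_day must be positive")


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit estimate for one group."""

    times: np.ndarray          # distinct recorded days, ascending
    survival: np.ndarray       # S_hat at each time (right-continuous step)
    at_risk: np.ndarray        # number at risk just before each time
    deaths: np.ndarray         # deaths at each time
    censored: np.ndarray       # censorings at each time
    group: str = ""

    def survival_at(self, t: float) -> float:
        """S_hat(t) for arbitrary t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


@dataclass
class LifespanSummary:
    """Restricted-mean and 75%-mortality lifespan for one group."""

    mean_lifespan: float
    day75: Optional[float]
    n: int
    n_censored: int
    group: str = ""
    day75_defined: bool = True


@dataclass
class LogRankResult:
    """Mantel–Cox log-rank comparison of two groups."""

    chi_square: float
    df: int
    p: float
    p_bonferroni: float
    groups: tuple = ("", "")


@dataclass
class ContingencyTable2x2:
    """2x2 marker-penetrance count table [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise InvalidConfigError("counts must be nonnegative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise InvalidConfigError("table must have at least one positive margin")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class GroundTruth:
    """Ground truth carried by every synthetic dataset."""

    true_dwelling_fraction: Optional[float] = None
    true_anterior_gain: Optional[float] = None
    true_median_lifespan: Optional[dict] = None
    changed_pixel_counts: Optional[np.ndarray] = None
    state_sequence: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict)
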