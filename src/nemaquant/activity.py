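"""Difference-image activity metric and roaming/dwelling decomposition.

The activity of a worm in an interval is the number of pixels that moved
between consecutive frames: the absolute difference image is normalized by
the mean intensity of the two frames, Gaussian-smoothed, binarized at a
fixed threshold, and summed. Each worm's smoothed-activity histogram (with
the zero bin, i.e. quiescence, excluded) is then decomposed by nonlinear
least squares into two exponential components (dwelling: slow, local
movement) and one Gaussian component (roaming: fast, sustained movement).
The dwelling fraction is the exponential components' share of the total
fitted area.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import ndimage, optimize, special
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ActivityTrace, DwellingResult, FrameStack, HistogramFit
from .exceptions import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidConfigError,
    NormalizationError,
)

__all__ = [
    "ActivityExtractor",
    "ActivityHistogramMixture",
    "compute_activity",
    "smooth_activity",
    "fit_activity_histogram",
    "dwelling_fraction",
    "dwelling_pipeline",
]


class ActivityExtractor(BaseEstimator, TransformerMixin):
    """Compute per-interval activity from a grayscale frame stack.

    Parameters
    ----------
    gaussian_sd : float, default 1.0
        SD (pixels) of the Gaussian filter applied to each normalized
        difference image. 0 disables filtering.
    threshold : float, default 0.6
        Binary threshold applied to the filtered difference image; a pixel
        above it counts as "moved".
    boundary_mode : str, default "reflect"
        Boundary handling of the Gaussian filter.

    Notes
    -----
    Each difference image is normalized by the scalar mean intensity over
    all pixels of both frames, which makes the fixed threshold invariant
    to uniform illumination gain.
    """

    def __init__(self, gaussian_sd: float = 1.0, threshold: float = 0.6,
                 boundary_mode: str = "reflect"):
        self.gaussian_sd = gaussian_sd
        self.threshold = threshold
        self.boundary_mode = boundary_mode

    def _validate(self) -> None:
        if self.gaussian_sd < 0:
            raise InvalidConfigError("gaussian_sd must be >= 0")
        if self.threshold <= 0:
            raise InvalidConfigError("threshold must be > 0")

    def fit(self, X: FrameStack, y=None) -> "ActivityExtractor":
        """No-op; present for estimator-API compatibility."""
        self._validate()
        return self

    def transform(self, X: FrameStack) -> ActivityTrace:
        """Return the length-(T-1) activity trace of the stack."""
        self._validate()
        frames = X.frames
        values = np.empty(frames.shape[0] - 1, dtype=float)
        for t in range(frames.shape[0] - 1):
            values[t] = self._interval_activity(frames[t], frames[t + 1], t)
        return ActivityTrace(values=values, frame_interval=X.frame_interval)

    def _interval_activity(self, f0: np.ndarray, f1: np.ndarray, index: int) -> int:
        mean_intensity = 0.5 * (f0.mean() + f1.mean())
        if mean_intensity == 0:
            raise NormalizationError(
                f"frame pair ({index}, {index + 1}) has zero mean intensity"
            )
        diff = np.abs(f1 - f0) / mean_intensity
        if self.gaussian_sd > 0:
            diff = ndimage.gaussian_filter(
                diff, sigma=self.gaussian_sd, mode=self.boundary_mode
            )
        return int(np.count_nonzero(diff > self.threshold))


def compute_activity(stack: FrameStack, gaussian_sd: float = 1.0,
                     threshold: float = 0.6) -> ActivityTrace:
    """Per-interval changed-pixel counts of ``stack`` (see ActivityExtractor)."""
    return ActivityExtractor(gaussian_sd=gaussian_sd, threshold=threshold).transform(stack)


def smooth_activity(trace: ActivityTrace, smoothing_window: float = 5.0) -> ActivityTrace:
    """Moving-average the trace with a window of ``smoothing_window`` seconds.

    The window is centered and shrinks at the trace edges (the average runs
    over the samples that exist), so constant traces stay constant.
    """
    w = int(round(smoothing_window / trace.frame_interval))
    if w < 1:
        raise InvalidConfigError(
            "smoothing window must cover at least one sample"
        )
    if w == 1:
        return ActivityTrace(trace.values.copy(), trace.frame_interval)
    n = len(trace.values)
    left = w // 2
    right = w - 1 - left
    csum = np.concatenate([[0.0], np.cumsum(trace.values)])
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, n)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return ActivityTrace(values=smoothed, frame_interval=trace.frame_interval)


def _mixture(a: np.ndarray, p: np.ndarray) -> np.ndarray:
    c1, l1, c2, l2, g, mu, sd = p
    return (
        c1 * np.exp(-a / l1)
        + c2 * np.exp(-a / l2)
        + g * np.exp(-((a - mu) ** 2) / (2.0 * sd**2))
    )


class ActivityHistogramMixture(BaseEstimator):
    """Two-exponential + Gaussian decomposition of an activity histogram.

    The histogram of the (smoothed) activity trace is built on ``n_bins``
    equal-width bins over [0, max]; the bin containing zero (quiescence) is
    excluded; then bin counts against bin centers are fitted by bounded
    nonlinear least squares to

        c1*exp(-a/l1) + c2*exp(-a/l2) + g*exp(-(a-mu)^2/(2*sd^2))

    with nonnegative amplitudes and positive scales. The fit is multimodal,
    so ``n_starts`` seeded starts are tried around data-driven initial
    values (exponential scales from the low-activity log-slope, the
    Gaussian from the highest-activity local mode) and the best residual
    wins.

    Attributes
    ----------
    fit_ : HistogramFit
        Best fit found (parameters, bin edges, residual, convergence flag).
    dwelling_fraction_ : float
        Exponential components' share of the total fitted area over a >= 0.
    exp_area_, gauss_area_ : float
        The analytic component areas.
    """

    def __init__(self, n_bins: int = 50, n_starts: int = 10,
                 random_state: Optional[int] = 0):
        self.n_bins = n_bins
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, trace: ActivityTrace, y=None) -> "ActivityHistogramMixture":
        self.fit_ = fit_activity_histogram(
            trace, n_bins=self.n_bins, n_starts=self.n_starts,
            random_state=self.random_state,
        )
        result = dwelling_fraction(self.fit_)
        self.dwelling_fraction_ = result.dwelling_fraction
        self.exp_area_ = result.exp_area
        self.gauss_area_ = result.gauss_area
        return self


def fit_activity_histogram(trace: ActivityTrace, n_bins: int = 50,
                           n_starts: int = 10,
                           random_state: Optional[int] = 0) -> HistogramFit:
    """Fit the 7-parameter exponential+Gaussian mixture to a trace's histogram."""
    if n_bins < 2:
        raise InvalidConfigError("need at least 2 bins")
    vals = trace.values
    if np.count_nonzero(vals > 0) < 50:
        raise InsufficientDataError(
            "need at least 50 positive activity values to fit the histogram"
        )
    vmax = float(vals.max())
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    # the zero bin (quiescence) is the bin whose interval contains 0
    counts, centers = counts[1:].astype(float), centers[1:]
    nonzero = np.count_nonzero(counts)
    if nonzero < 8:
        raise InsufficientDataError(
            f"only {nonzero} nonzero histogram bins; need at least 8"
        )

    rng = np.random.default_rng(random_state)
    x0 = _initial_guess(centers, counts)
    lower = np.array([0.0, 1e-9, 0.0, 1e-9, 0.0, 0.0, 1e-9])
    upper = np.array([np.inf, np.inf, np.inf, np.inf, np.inf, vmax, vmax])
    x0 = np.clip(x0, lower + 1e-12, np.where(np.isfinite(upper), upper, x0 + 1))

    def resid(p):
        return _mixture(centers, p) - counts

    def jac(p):
        c1, l1, c2, l2, g, mu, sd = p
        e1 = np.exp(-centers / l1)
        e2 = np.exp(-centers / l2)
        z = (centers - mu) / sd
        eg = np.exp(-0.5 * z**2)
        return np.column_stack([
            e1, c1 * e1 * centers / l1**2,
            e2, c2 * e2 * centers / l2**2,
            eg, g * eg * z / sd, g * eg * z**2 / sd,
        ])

    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            p0 = x0
        else:
            p0 = x0 * rng.uniform(0.3, 3.0, size=7)
            p0 = np.clip(p0, lower + 1e-12,
                         np.where(np.isfinite(upper), upper, p0 + 1))
        try:
            sol = optimize.least_squares(resid, p0, jac=jac,
                                         bounds=(lower, upper),
                                         x_scale="jac", max_nfev=3000)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise DegenerateFitError("least-squares fitting failed from every start")

    c1, l1, c2, l2, g, mu, sd = best.x
    # order the exponential components by scale for reproducibility
    if l2 < l1:
        c1, l1, c2, l2 = c2, l2, c1, l1
    return HistogramFit(
        exp1_amp=float(c1), exp1_scale=float(l1),
        exp2_amp=float(c2), exp2_scale=float(l2),
        gauss_amp=float(g), gauss_mean=float(mu), gauss_sd=float(sd),
        bin_edges=edges, residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
    )


def _initial_guess(centers: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Data-driven starting point for the 7-parameter fit."""
    pos = counts > 0
    c_pos, n_pos = centers[pos], counts[pos]
    # exponential scales from the log-slope of the low-activity half
    half = max(3, len(c_pos) // 2)
    x, y = c_pos[:half], np.log(n_pos[:half])
    slope = np.polyfit(x, y, 1)[0] if len(x) >= 2 else -1.0 / max(c_pos[0], 1.0)
    lam = -1.0 / slope if slope < 0 else c_pos[: half].mean()
    lam = float(np.clip(lam, centers[0] * 0.1, centers[-1]))
    amp = float(n_pos[0])
    # Gaussian from the highest-activity local mode
    upper_half = centers >= centers[len(centers) // 2]
    if np.any(counts[upper_half] > 0):
        rel = np.argmax(counts[upper_half])
        mu = float(centers[upper_half][rel])
        g = float(counts[upper_half][rel])
    else:
        mu = float(centers[-1])
        g = max(float(counts.max()) * 0.1, 1.0)
    sd = max((centers[-1] - centers[0]) / 10.0, (centers[1] - centers[0]))
    return np.array([amp, max(lam / 2, 1e-6), amp / 2, lam, g, mu, sd])


def dwelling_fraction(fit: HistogramFit) -> DwellingResult:
    """Dwelling fraction = exponential components' share of the fitted area.

    Areas are analytic integrals over activity a >= 0: each exponential
    contributes ``c * lambda``; the Gaussian contributes
    ``g * sd * sqrt(2*pi) * Phi(mu/sd)`` (truncated to the nonnegative
    half-line, since activity cannot be negative).
    """
    exp_area = fit.exp1_amp * fit.exp1_scale + fit.exp2_amp * fit.exp2_scale
    gauss_area = (
        fit.gauss_amp * fit.gauss_sd * math.sqrt(2.0 * math.pi)
        * 0.5 * (1.0 + special.erf(fit.gauss_mean / (fit.gauss_sd * math.sqrt(2.0))))
    )
    total = exp_area + gauss_area
    if total <= 0:
        raise DegenerateFitError("fitted mixture has zero total area")
    frac = float(exp_area / total)
    return DwellingResult(dwelling_fraction=frac, exp_area=float(exp_area),
                          gauss_area=float(gauss_area), fit=fit)


def dwelling_pipeline(stack: FrameStack, gaussian_sd: float = 1.0,
                      threshold: float = 0.6, smoothing_window: float = 5.0,
                      n_bins: int = 50, n_starts: int = 10,
                      random_state: Optional[int] = 0) -> DwellingResult:
    """Full decomposition: stack -> activity -> smoothing -> histogram fit."""
    trace = compute_activity(stack, gaussian_sd=gaussian_sd, threshold=threshold)
    smoothed = smooth_activity(trace, smoothing_window=smoothing_window)
    fit = fit_activity_histogram(smoothed, n_bins=n_bins, n_starts=n_starts,
                                 random_state=random_state)
    return dwelling_fraction(fit)
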