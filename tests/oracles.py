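"""Independent brute-force oracles used by the test suite.

Each oracle reimplements a quantity from first principles (explicit loops,
direct convolution, exhaustive enumeration) without touching the library
code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def brute_force_activity_pair(f0: np.ndarray, f1: np.ndarray,
                              sigma: float = 1.0,
                              threshold: float = 0.6) -> int:
    """Activity of one frame pair with fully explicit per-pixel loops."""
    mean_intensity = 0.5 * (f0.mean() + f1.mean())
    diff = np.abs(f1 - f0) / mean_intensity
    k1 = gaussian_kernel_1d(sigma)
    k2 = np.outer(k1, k1)
    r = len(k1) // 2
    # scipy's 'reflect' boundary duplicates the edge sample: np.pad 'symmetric'
    padded = np.pad(diff, r, mode="symmetric")
    H, W = diff.shape
    count = 0
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for di in range(2 * r + 1):
                for dj in range(2 * r + 1):
                    acc += k2[di, dj] * padded[i + di, j + dj]
            if acc > threshold:
                count += 1
    return count


def brute_force_activity_trace(frames: np.ndarray, sigma: float = 1.0,
                               threshold: float = 0.6) -> np.ndarray:
    """Per-interval activity via direct Gaussian-kernel convolution.

    The convolution loops over kernel offsets on a symmetric-padded
    difference image; it shares no code with the pipeline.
    """
    k1 = gaussian_kernel_1d(sigma)
    k2 = np.outer(k1, k1)
    r = len(k1) // 2
    T, H, W = frames.shape
    out = np.empty(T - 1, dtype=int)
    for t in range(T - 1):
        f0, f1 = frames[t], frames[t + 1]
        diff = np.abs(f1 - f0) / (0.5 * (f0.mean() + f1.mean()))
        padded = np.pad(diff, r, mode="symmetric")
        filtered = np.zeros((H, W))
        for di in range(2 * r + 1):
            for dj in range(2 * r + 1):
                filtered += k2[di, dj] * padded[di:di + H, dj:dj + W]
        out[t] = int((filtered > threshold).sum())
    return out


def finite_difference_curvature(points: np.ndarray) -> np.ndarray:
    """Signed normalized curvature K = k * L from raw midline points.

    Tangent angles from chord differences; dtheta/d(arc length) by central
    differences on segment midpoints.
    """
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    L = seg_len.sum()
    theta = np.unwrap(np.arctan2(seg[:, 1], seg[:, 0]))
    mid = np.concatenate([[0.0], np.cumsum(seg_len)])
    mid = 0.5 * (mid[:-1] + mid[1:])
    k = np.gradient(theta, mid)
    return k * L


def logrank_chi2(days_a, observed_a, days_b, observed_b) -> float:
    """Mantel-Cox statistic by direct O-E / hypergeometric-variance sums."""
    days_a = np.asarray(days_a, float)
    days_b = np.asarray(days_b, float)
    observed_a = np.asarray(observed_a, bool)
    observed_b = np.asarray(observed_b, bool)
    event_times = np.unique(np.concatenate([
        days_a[observed_a], days_b[observed_b]]))
    O = E = V = 0.0
    for t in event_times:
        n1 = np.sum(days_a >= t)
        n2 = np.sum(days_b >= t)
        d1 = np.sum(observed_a & (days_a == t))
        d2 = np.sum(observed_b & (days_b == t))
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        O += d1
        E += d * n1 / n
        V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0
    return (O - E) ** 2 / V


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def km_hand_product_limit(days, observed):
    """Empirical product-limit computation at each distinct event day."""
    days = np.asarray(days, float)
    observed = np.asarray(observed, bool)
    times = np.unique(days[observed])
    s, out = 1.0, []
    for t in times:
        n_at_risk = np.sum(days >= t)
        d = np.sum(observed & (days == t))
        s *= 1.0 - d / n_at_risk
        out.append((t, s))
    return out


def mixture_component_areas_numeric(c1, l1, c2, l2, g, mu, sd,
                                    upper=None) -> tuple:
    """Component areas over a >= 0 by numeric integration (Simpson)."""
    from scipy import integrate

    if upper is None:
        upper = max(20 * max(l1, l2), mu + 12 * sd)
    a = np.linspace(0, upper, 200001)
    exp_part = c1 * np.exp(-a / l1) + c2 * np.exp(-a / l2)
    gauss_part = g * np.exp(-((a - mu) ** 2) / (2 * sd**2))
    return (float(integrate.simpson(exp_part, x=a)),
            float(integrate.simpson(gauss_part, x=a)))


def monte_carlo_dwell_occupancy(roam_rate, dwell_rate, dt, n_steps,
                                seed=12345) -> float:
    """Occupancy of the dwell state from a direct chain simulation."""
    rng = np.random.default_rng(seed)
    p_dr = 1.0 - math.exp(-roam_rate * dt)
    p_rd = 1.0 - math.exp(-dwell_rate * dt)
    state, count = 0, 0
    for _ in range(n_steps):
        count += state == 0
        if state == 0:
            if rng.random() < p_dr:
                state = 1
        elif rng.random() < p_rd:
            state = 0
    return count / n_steps
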