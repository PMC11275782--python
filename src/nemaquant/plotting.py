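"""Basic diagnostic figures: kymograph heatmap and Kaplan-Meier step plot."""

from __future__ import annotations

import numpy as np

from .datatypes import CurvatureKymograph, KMCurve


def plot_kymograph(kymo: CurvatureKymograph, ax=None):
    """Heatmap of K(s, t); body coordinate on the y axis, head at the top."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vmax = np.abs(kymo.K).max() or 1.0
    im = ax.imshow(kymo.K, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   extent=(kymo.times[0], kymo.times[-1], 1.0, 0.0))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("body coordinate s")
    ax.figure.colorbar(im, ax=ax, label="normalized curvature K")
    return ax


def plot_km(curves, ax=None):
    """Step plot of one or several KM curves."""
    import matplotlib.pyplot as plt

    if isinstance(curves, KMCurve):
        curves = [curves]
    if ax is None:
        _, ax = plt.subplots()
    for curve in curves:
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=curve.group or None)
    ax.set_xlabel("day of adulthood")
    ax.set_ylabel("fraction alive")
    ax.set_ylim(0, 1.02)
    if any(c.group for c in curves):
        ax.legend()
    return ax
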