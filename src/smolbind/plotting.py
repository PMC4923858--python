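"""Convenience plots for traces, force histograms and binding fits.

All functions draw on a provided (or fresh) matplotlib Axes and return
it; nothing here is asserted by the analyses.
"""

from __future__ import annotations

import numpy as np


def plot_trace(trace, fit=None, ax=None):
    """Intensity trace with the fitted piecewise-constant levels overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trace.times, trace.values, lw=0.7, color="0.4", label="trace")
    if fit is not None:
        bounds = np.concatenate(([0], fit.change_points, [len(trace)]))
        for lvl, a, b in zip(fit.levels, bounds[:-1], bounds[1:]):
            ax.plot(
                [a * trace.frame_interval, b * trace.frame_interval],
                [lvl, lvl], color="C3", lw=2,
            )
        ax.set_title(f"{fit.n_steps} step(s), accepted={fit.accepted}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("background-corrected intensity")
    return ax


def plot_force_histogram(hist_fit, ax=None):
    """Rupture-force histogram with the fitted Gaussian."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(
        hist_fit.bin_centers, hist_fit.bin_counts,
        width=hist_fit.bin_width * 0.95, color="C0", alpha=0.7,
    )
    x = np.linspace(hist_fit.bin_centers[0], hist_fit.bin_centers[-1], 300)
    ax.plot(
        x,
        hist_fit.amplitude * np.exp(-((x - hist_fit.peak) ** 2) / (2 * hist_fit.sd**2)),
        color="C3",
    )
    ax.set_xlabel("rupture force (pN)")
    ax.set_ylabel("count")
    ax.set_title(f"peak {hist_fit.peak:.1f} pN (n={hist_fit.n_forces})")
    return ax


def plot_binding_fit(results, ax=None, n_points: int = 200):
    """Concentration–response data with the fitted binding curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    model = results.model
    c = model.concentrations
    y = getattr(model, "responses", getattr(model, "pct_specific", None))
    grid = np.geomspace(c.min(), c.max(), n_points)
    ax.semilogx(c, y, "o", color="C0")
    ax.semilogx(grid, results.predict(grid), color="C3")
    ax.set_xlabel("concentration")
    ax.set_ylabel("response")
    return ax
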