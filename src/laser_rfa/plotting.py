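"""Scatter + fitted-curve panels for the fixation-measure correlations."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless backend; figures are written, not shown
import matplotlib.pyplot as plt
import numpy as np

from .validation import (
    MEASURES,
    SpecimenMeasurements,
    _complete_pairs,
    _measure_values,
    compare_fits,
    fit_linear,
)

_LABELS = {
    "rf": "Resonance frequency (Hz)",
    "isq": "ISQ (a.u.)",
    "peak_torque": "Peak torque (Nm)",
    "pullout": "Pull-out force (N)",
}


def plot_pair_grid(cohort: Sequence[SpecimenMeasurements], path=None):
    """Grid of pairwise scatter plots with linear and logarithmic fits.

    One panel per measure pair (six panels for the full table); the linear
    fit is drawn dashed, the logarithmic fit solid, each labelled with its
    Pearson R. Returns the matplotlib figure; if ``path`` is given the figure
    is also written there (PNG/SVG by extension).
    """
    pairs = [
        (a, b) for i, a in enumerate(MEASURES) for b in MEASURES[i + 1 :]
    ]
    fig, axes = plt.subplots(2, 3, figsize=(13, 8))
    for ax, (yname, xname) in zip(axes.ravel(), pairs):
        y = _measure_values(cohort, yname)
        x = _measure_values(cohort, xname)
        xs, ys = _complete_pairs(x, y)
        ax.set_xlabel(_LABELS[xname])
        ax.set_ylabel(_LABELS[yname])
        if xs.size < 3:
            ax.set_title("unavailable")
            continue
        ax.scatter(xs, ys, s=18, color="0.25", zorder=3)
        grid = np.linspace(xs.min(), xs.max(), 200)
        try:
            lin, log, preferred = compare_fits(xs, ys)
            ax.plot(grid, lin.predict(grid), "--", color="tab:blue",
                    label=f"linear R={lin.pearson_r:.3f}")
            ax.plot(grid[grid > 0], log.predict(grid[grid > 0]), "-",
                    color="tab:red",
                    label=f"log R={log.pearson_r:.3f}")
            ax.set_title(f"preferred: {preferred}", fontsize=10)
        except ValueError:
            lin = fit_linear(xs, ys)
            ax.plot(grid, lin.predict(grid), "--", color="tab:blue",
                    label=f"linear R={lin.pearson_r:.3f}")
            ax.set_title("linear only", fontsize=10)
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
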