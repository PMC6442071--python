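"""Observed-vs-predicted scatter panels with percentile guide lines.

Mirrors the standard presentation: one panel per (clustering, weight)
combination, predicted on x, observed on y, dashed lines at the empirical
20/50/80 percentiles of each axis, and the per-cell classification rates
printed inside the resulting 4 x 4 grid.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import (PERCENTILE_CUTS, PredictionResult,
                         classification_grid, predictive_ability)

__all__ = ["plot_prediction_panel", "prediction_panel_figure"]


def plot_prediction_panel(ax: "plt.Axes", r: PredictionResult) -> None:
    """One scatter panel for a single strategy."""
    ax.scatter(r.predicted, r.observed, s=8, alpha=0.5, color="tab:blue")
    qx = np.quantile(r.predicted, np.asarray(PERCENTILE_CUTS) / 100)
    qy = np.quantile(r.observed, np.asarray(PERCENTILE_CUTS) / 100)
    for v in qx:
        ax.axvline(v, color="grey", lw=0.7, ls="--")
    for v in qy:
        ax.axhline(v, color="grey", lw=0.7, ls="--")
    grid = classification_grid(r)
    xb = [r.predicted.min(), *qx, r.predicted.max()]
    yb = [r.observed.min(), *qy, r.observed.max()]
    for h in range(4):
        for g in range(4):
            if np.isnan(grid.rates[h, g]):
                continue
            ax.text((xb[g] + xb[g + 1]) / 2, (yb[h] + yb[h + 1]) / 2,
                    f"{grid.rates[h, g]:.2f}", ha="center", va="center",
                    fontsize=7, color="tab:red")
    ax.set_title(f"{r.strategy.label}  r={predictive_ability(r):.3f}", fontsize=9)
    ax.set_xlabel("predicted")
    ax.set_ylabel("observed")


def prediction_panel_figure(run_result,
                            weights: tuple[float, ...] = (0.0, 0.5, 1.0)):
    """Panels for the unclustered scheme and the largest clustered scheme."""
    labels = list(run_result.results)
    rows = []
    none_row = [l for l in labels if l.startswith("none_")]
    if none_row:
        rows.append("none_k1")
    clustered = sorted({l.rsplit("_w", 1)[0] for l in labels
                        if not l.startswith("none_")})
    if clustered:
        rows.append(clustered[-1])
    fig, axes = plt.subplots(len(rows), len(weights),
                             figsize=(4 * len(weights), 4 * len(rows)),
                             squeeze=False)
    for i, prefix in enumerate(rows):
        for j, w in enumerate(weights):
            label = f"{prefix}_w{w:g}"
            if label in run_result.results:
                plot_prediction_panel(axes[i][j], run_result.results[label])
            else:
                axes[i][j].set_visible(False)
    fig.tight_layout()
    return fig
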