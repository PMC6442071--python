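"""Evaluation of prediction strategies.

Two surfaces: Pearson predictive ability over the concatenated
observed/predicted vectors, and a 4 x 4 percentile classification-rate
grid.  For the grid, lines are binned at the empirical 20/50/80
percentiles separately for observed and predicted values; cell (h, g) is
the proportion of lines in predicted-group g whose observed value falls in
observed-group h, so each non-empty column sums to 1.  The top-right cell
(h = g = top 20%) is the fraction of predicted-top-20% lines that really
are top-20%, the quantity a breeder selecting on predictions cares about.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cv_clustering import CVStrategy

PERCENTILE_CUTS = (20, 50, 80)

__all__ = [
    "PredictionResult",
    "ClassificationGrid",
    "predictive_ability",
    "percentile_groups",
    "classification_grid",
    "strategy_table",
    "pivot_strategy_table",
]


@dataclass
class PredictionResult:
    """Observed and cross-validated predicted values for one strategy."""

    line_ids: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    strategy: CVStrategy

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        n = len(self.line_ids)
        if self.observed.shape != (n,) or self.predicted.shape != (n,):
            raise ValueError("observed/predicted length mismatch")
        if np.isnan(self.observed).any() or np.isnan(self.predicted).any():
            raise ValueError("missing entries in prediction result")


@dataclass
class ClassificationGrid:
    """4x4 success-rate grid; rates[h, g] conditions on predicted group g."""

    rates: np.ndarray  # (4, 4); NaN column where a predicted group is empty
    percentile_cuts: tuple[int, ...] = PERCENTILE_CUTS
    conditioning: str = "predicted"
    empty_groups: tuple[int, ...] = ()


def predictive_ability(r: PredictionResult) -> float:
    """Pearson correlation between observed and predicted vectors."""
    if len(r.line_ids) < 3:
        raise ValueError("need >= 3 pairs for a correlation")
    if np.ptp(r.observed) == 0 or np.ptp(r.predicted) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(r.observed, r.predicted).statistic)


def percentile_groups(values: np.ndarray,
                      cuts: tuple[int, ...] = PERCENTILE_CUTS) -> np.ndarray:
    """Bin values into len(cuts)+1 groups at their empirical percentiles.

    Quantiles use linear interpolation; a value tied with a cut goes to the
    lower group (deterministic tie handling).
    """
    values = np.asarray(values, dtype=float)
    q = np.quantile(values, np.asarray(cuts) / 100.0)
    return np.searchsorted(q, values, side="left")


def classification_grid(r: PredictionResult,
                        cuts: tuple[int, ...] = PERCENTILE_CUTS,
                        condition_on: str = "predicted") -> ClassificationGrid:
    """Percentile classification-rate grid.

    ``rates[h, g]`` = P(observed group h | predicted group g) by default;
    ``condition_on="observed"`` flips the conditioning for sensitivity
    checks.  Groups are indexed 0 (bottom) .. len(cuts) (top).
    """
    if len(r.line_ids) < len(cuts) + 2:
        raise ValueError("too few lines for all percentile groups")
    if condition_on not in ("predicted", "observed"):
        raise ValueError(f"unknown conditioning {condition_on!r}")
    n_groups = len(cuts) + 1
    obs_g = percentile_groups(r.observed, cuts)
    pred_g = percentile_groups(r.predicted, cuts)
    counts = np.zeros((n_groups, n_groups))
    np.add.at(counts, (obs_g, pred_g), 1.0)
    axis = 0 if condition_on == "predicted" else 1
    totals = counts.sum(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = counts / totals
    empty = tuple(int(i) for i in np.flatnonzero(totals.ravel() == 0))
    return ClassificationGrid(rates=rates, percentile_cuts=tuple(cuts),
                              conditioning=condition_on, empty_groups=empty)


def strategy_table(results: list[PredictionResult]) -> pd.DataFrame:
    """Long-format table (method, k, w, predictive_ability), one row per strategy."""
    seen: set[CVStrategy] = set()
    rows = []
    for r in results:
        if r.strategy in seen:
            raise ValueError(f"duplicate strategy {r.strategy}")
        seen.add(r.strategy)
        rows.append(
            {"method": r.strategy.method, "k": r.strategy.k,
             "w": r.strategy.w, "predictive_ability": predictive_ability(r)}
        )
    return pd.DataFrame(rows)


def pivot_strategy_table(long: pd.DataFrame) -> pd.DataFrame:
    """Wide layout: rows = weights, columns = (method, k)."""
    wide = long.pivot_table(index="w", columns=["method", "k"],
                            values="predictive_ability")
    cols = sorted(wide.columns, key=lambda mk: (mk[1], mk[0]))  # k then method
    return wide[cols]
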