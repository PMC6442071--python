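"""Logistic growth modeling of canopy coverage.

Sparse weekly canopy observations (six measurements, 2-8 weeks after
planting) are expanded to daily coverage values by fitting, per line, a
two-parameter logistic growth curve on the logit scale,

    logit(coverage(t)) = intercept + slope * t,

by ordinary least squares after clipping observations away from the {0, 1}
boundaries, then evaluating the inverse link on a daily grid (canonically
days 14-55, i.e. 42 values).  Coverage is a proportion with natural
asymptotes at 0 and 1, and six points cannot support more parameters
stably, so the asymptotes are fixed rather than estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import expit, logit

from .io_formats import CanopyMatrix

DEFAULT_OBS_DAYS = (14, 21, 28, 35, 42, 49)
DEFAULT_DAY_START = 14
DEFAULT_N_DAYS = 42  # days 14..55 inclusive
DEFAULT_EPS = 1e-3

__all__ = [
    "WeeklyCanopySeries",
    "GrowthCurveFit",
    "fit_growth_curve",
    "extrapolate_daily",
    "build_canopy_matrix",
]


@dataclass
class WeeklyCanopySeries:
    """Sparse canopy observations for one line."""

    line_id: str
    obs_days: np.ndarray  # (m,) int, days after planting
    obs_values: np.ndarray  # (m,) float in [0, 1]

    def __post_init__(self) -> None:
        self.obs_days = np.asarray(self.obs_days, dtype=int)
        self.obs_values = np.asarray(self.obs_values, dtype=float)
        if self.obs_days.shape != self.obs_values.shape:
            raise ValueError(f"{self.line_id}: days/values length mismatch")
        if len(np.unique(self.obs_days)) < 2:
            raise ValueError(f"{self.line_id}: need >= 2 distinct observation days")
        if ((self.obs_values < 0) | (self.obs_values > 1)).any():
            raise ValueError(f"{self.line_id}: coverage values must be in [0, 1]")


@dataclass
class GrowthCurveFit:
    """Fitted logit-linear growth curve for one line."""

    line_id: str
    intercept: float  # logit scale
    slope: float  # logit scale per day
    fit_residual: float  # sum of squared logit-scale residuals


def fit_growth_curve(series: WeeklyCanopySeries,
                     eps: float = DEFAULT_EPS) -> GrowthCurveFit:
    """Least-squares fit of logit(coverage) against day.

    Values are clipped to [eps, 1-eps] before the logit transform, so exact
    0.0 and 1.0 observations are handled.
    """
    if not 0.0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    t = series.obs_days.astype(float)
    z = logit(np.clip(series.obs_values, eps, 1.0 - eps))
    slope, intercept = np.polyfit(t, z, 1)
    resid = float(np.sum((z - (intercept + slope * t)) ** 2))
    return GrowthCurveFit(series.line_id, float(intercept), float(slope), resid)


def extrapolate_daily(fit: GrowthCurveFit,
                      day_start: int = DEFAULT_DAY_START,
                      n_days: int = DEFAULT_N_DAYS) -> np.ndarray:
    """Daily coverage values expit(intercept + slope*t), t = day_start..day_start+n_days-1."""
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    t = np.arange(day_start, day_start + n_days, dtype=float)
    return expit(fit.intercept + fit.slope * t)


def build_canopy_matrix(series_set: Iterable[WeeklyCanopySeries],
                        day_start: int = DEFAULT_DAY_START,
                        n_days: int = DEFAULT_N_DAYS,
                        eps: float = DEFAULT_EPS) -> CanopyMatrix:
    """Fit each line's growth curve and assemble the n x n_days daily matrix.

    Rows follow the input order; all series must share the same
    observation-day grid.
    """
    series_list = list(series_set)
    if not series_list:
        raise ValueError("no canopy series supplied")
    grid = series_list[0].obs_days
    rows = []
    ids = []
    for s in series_list:
        if not np.array_equal(s.obs_days, grid):
            raise ValueError(f"{s.line_id}: observation-day grid differs")
        try:
            fit = fit_growth_curve(s, eps=eps)
        except Exception as exc:  # surface the offending line
            raise ValueError(f"growth-curve fit failed for line {s.line_id!r}: {exc}") from exc
        rows.append(extrapolate_daily(fit, day_start, n_days))
        ids.append(s.line_id)
    days = list(range(day_start, day_start + n_days))
    return CanopyMatrix(ids, days, np.vstack(rows))


def weekly_series_from_matrix(c: CanopyMatrix) -> list[WeeklyCanopySeries]:
    """View each row of a (weekly) canopy matrix as a WeeklyCanopySeries."""
    return [
        WeeklyCanopySeries(lid, np.asarray(c.day_labels), c.values[i])
        for i, lid in enumerate(c.line_ids)
    ]
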