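"""NAM-style population simulator.

Emulates the statistical structure the analysis assumes, at desk scale:

* Family structure: one common inbred parent crossed to ``n_families``
  diverse inbred parents; each recombinant inbred line (RIL) inherits
  contiguous 10-marker blocks from one parent or the other (a cheap stand-in
  for a recombination map that still yields realistic LD and family
  stratification), pushed to near-homozygosity with residual per-locus
  heterozygosity 1/16 (F5).
* Markers: biallelic, target allele frequencies drawn from ``maf_range``,
  re-polarized so codes count the cohort's minor allele.
* Genetic values: i.i.d. normal effects on standardized marker codes,
  rescaled so the realized marker-explained fraction of phenotypic
  variance equals ``h2_marker``.
* Canopy: per-line logistic growth on the logit scale; the growth slope
  correlates with the standardized genetic value with coefficient
  ``canopy_link`` (genetic variation in vigor), plus independent noise.
  Weekly observations add logit-scale measurement noise.
* Yield: mu + trait_sd * (genetic value + environmental noise), kg/ha.

Everything is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .canopy_growth import DEFAULT_OBS_DAYS, WeeklyCanopySeries
from .io_formats import GenotypeMatrix, PhenotypeVector

BLOCK_SIZE = 10  # markers inherited together
HET_RATE = 1.0 / 16.0  # residual heterozygosity of an F5-derived RIL

__all__ = ["SimConfig", "SimTruth", "simulate_nam", "toy_fixture"]


@dataclass
class SimConfig:
    n_families: int = 5
    lines_per_family: int = 40
    n_markers: int = 300
    maf_range: tuple[float, float] = (0.1, 0.5)
    h2_marker: float = 0.5  # fraction of phenotypic variance from markers
    canopy_link: float = 0.4  # corr(growth slope, standardized genetic value)
    obs_days: tuple[int, ...] = DEFAULT_OBS_DAYS
    noise_sd_canopy: float = 0.2  # logit scale
    mu_yield: float = 3000.0  # kg/ha
    trait_sd: float = 600.0  # kg/ha
    base_intercept: float = -4.5  # logit scale at day 0
    base_slope: float = 0.16  # logit units per day
    slope_sd: float = 0.02  # between-line sd of the growth slope
    intercept_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.lines_per_family, self.n_markers) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.h2_marker <= 1.0:
            raise ValueError("h2_marker must be in [0, 1]")
        if not 0.0 <= self.canopy_link <= 1.0:
            raise ValueError("canopy_link must be in [0, 1]")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")

    @property
    def n_lines(self) -> int:
        return self.n_families * self.lines_per_family


@dataclass
class SimTruth:
    marker_effects: np.ndarray  # per final (possibly flipped) marker code
    true_genetic_values: np.ndarray  # per line, trait units
    true_growth_params: np.ndarray  # (n, 2): intercept, slope
    variance_components: tuple[float, float]  # (sigma_u2, sigma_e2), trait units^2


def _ril_genotypes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    p = cfg.n_markers
    freq = rng.uniform(*cfg.maf_range, size=p)
    common = (rng.random(p) < freq).astype(np.int8)
    geno = np.empty((cfg.n_lines, p), dtype=np.int16)
    row = 0
    n_blocks = -(-p // BLOCK_SIZE)
    for _fam in range(cfg.n_families):
        other = (rng.random(p) < freq).astype(np.int8)
        for _ in range(cfg.lines_per_family):
            pick = rng.random(n_blocks) < 0.5  # block-wise parental origin
            from_common = np.repeat(pick, BLOCK_SIZE)[:p]
            allele = np.where(from_common, common, other)
            code = (2 * allele).astype(np.int16)
            het = rng.random(p) < HET_RATE
            code[het] = 1
            geno[row] = code
            row += 1
    # re-polarize: codes count the minor allele in this cohort
    flip = geno.mean(axis=0) / 2.0 > 0.5
    geno[:, flip] = 2 - geno[:, flip]
    return geno


def simulate_nam(
    config: SimConfig,
) -> tuple[GenotypeMatrix, list[WeeklyCanopySeries], PhenotypeVector, SimTruth]:
    """Draw one NAM-style population (genotypes, weekly canopy, yield, truth)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_lines

    geno = _ril_genotypes(cfg, rng)
    line_ids = [f"F{f:02d}_L{l:03d}" for f in range(cfg.n_families)
                for l in range(cfg.lines_per_family)]
    marker_ids = [f"snp{j:04d}" for j in range(cfg.n_markers)]

    # additive genetic values on standardized codes; monomorphic markers get
    # zero effect (they carry no variance)
    sds = geno.std(axis=0, ddof=1)
    poly = sds > 0
    x_std = np.zeros_like(geno, dtype=float)
    x_std[:, poly] = (geno[:, poly] - geno[:, poly].mean(axis=0)) / sds[poly]
    beta = np.zeros(cfg.n_markers)
    beta[poly] = rng.normal(size=int(poly.sum()))
    g_raw = x_std @ beta
    if cfg.h2_marker > 0 and g_raw.std(ddof=1) > 0:
        scale = np.sqrt(cfg.h2_marker) / g_raw.std(ddof=1)
    else:
        scale = 0.0
    g_unit = g_raw * scale  # realized variance exactly h2_marker
    beta_unit = beta * scale
    z_g = (g_unit - g_unit.mean()) / g_unit.std(ddof=1) if g_unit.std(ddof=1) > 0 \
        else np.zeros(n)

    # growth parameters: slope carries the genetic signal
    lam = cfg.canopy_link
    slope_noise = rng.normal(size=n)
    slopes = cfg.base_slope + cfg.slope_sd * (
        lam * z_g + np.sqrt(max(1.0 - lam ** 2, 0.0)) * slope_noise)
    intercepts = cfg.base_intercept + cfg.intercept_sd * rng.normal(size=n)

    days = np.asarray(cfg.obs_days)
    series = []
    for i, lid in enumerate(line_ids):
        eta = intercepts[i] + slopes[i] * days
        obs = expit(eta + cfg.noise_sd_canopy * rng.normal(size=days.size))
        series.append(WeeklyCanopySeries(lid, days, obs))

    env = rng.normal(scale=np.sqrt(max(1.0 - cfg.h2_marker, 0.0)), size=n)
    yield_vals = cfg.mu_yield + cfg.trait_sd * (g_unit + env)

    truth = SimTruth(
        marker_effects=beta_unit * cfg.trait_sd,
        true_genetic_values=g_unit * cfg.trait_sd,
        true_growth_params=np.column_stack([intercepts, slopes]),
        variance_components=(cfg.h2_marker * cfg.trait_sd ** 2,
                             (1.0 - cfg.h2_marker) * cfg.trait_sd ** 2),
    )
    return (
        GenotypeMatrix(line_ids, marker_ids, geno),
        series,
        PhenotypeVector(line_ids, yield_vals),
        truth,
    )


def toy_fixture() -> tuple[GenotypeMatrix, list[WeeklyCanopySeries], PhenotypeVector]:
    """Deterministic 8-line, 10-marker, 6-week fixture for unit tests and docs."""
    line_ids = [f"L{i}" for i in range(1, 9)]
    calls = np.array(
        [
            [0, 1, 2, 0, 1, 2, 0, 1, 2, 0],
            [2, 1, 0, 2, 1, 0, 2, 1, 0, 2],
            [0, 0, 1, 1, 2, 2, 0, 0, 1, 1],
            [1, 2, 0, 1, 2, 0, 1, 2, 0, 1],
            [2, 0, 2, 0, 2, 0, 2, 0, 2, 0],
            [0, 2, 0, 2, 0, 2, 0, 2, 0, 2],
            [1, 1, 1, 0, 0, 2, 2, 1, 1, 0],
            [2, 2, 1, 1, 0, 0, 1, 1, 2, 2],
        ],
        dtype=np.int16,
    )
    geno = GenotypeMatrix(line_ids, [f"snp{j}" for j in range(10)], calls)
    days = np.asarray(DEFAULT_OBS_DAYS)
    slopes = np.array([0.12, 0.14, 0.15, 0.16, 0.17, 0.18, 0.13, 0.19])
    intercepts = np.array([-4.0, -4.2, -4.5, -4.1, -4.8, -4.3, -3.9, -5.0])
    series = [
        WeeklyCanopySeries(lid, days, expit(a + b * days))
        for lid, a, b in zip(line_ids, intercepts, slopes)
    ]
    y = PhenotypeVector(
        line_ids,
        np.array([2800.0, 3100.0, 3250.0, 3000.0, 3400.0, 3300.0, 2900.0, 3500.0]),
    )
    return geno, series, y
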