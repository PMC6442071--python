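"""End-to-end orchestration: QC -> canopy expansion -> kernels -> strategy grid.

A :class:`RunConfig` either points at the three canonical TSV inputs or
embeds a :class:`~hybridgp.synthetic_data.SimConfig`.  The pipeline imputes
and MAF-filters genotypes, expands weekly canopy observations to the daily
grid, standardizes both feature blocks, builds the marker and canopy
kernels, enumerates the strategy grid (default 11 weights x ({no
clustering} plus {CLARA, HL} x {2,3,4,5} clusters) = 99 strategies), runs
within-cluster leave-one-observation-out GBLUP for each strategy, and
evaluates Pearson predictive ability.  Clustering for a given (method, k)
is computed once and reused across all weights, since clusters depend on
the features, not on w.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .canopy_growth import (DEFAULT_DAY_START, DEFAULT_N_DAYS,
                            build_canopy_matrix, weekly_series_from_matrix)
from .cv_clustering import (ClusterAssignment, CVStrategy, clara_cluster,
                            clustered_loo, combined_features, hl_ward_cluster,
                            write_assignment)
from .evaluation import (PredictionResult, classification_grid,
                         pivot_strategy_table, strategy_table)
from .io_formats import (CanopyMatrix, GenotypeMatrix, PhenotypeVector,
                         align_datasets, impute_missing_mode, maf_filter,
                         qc_summary, read_canopy, read_genotypes,
                         read_phenotypes)
from .kernels import (RelationshipKernel, canopy_kernel, hybrid_kernel,
                      marker_kernel, standardize_columns, write_kernel)
from .synthetic_data import SimConfig, simulate_nam

logger = logging.getLogger("hybridgp")

DEFAULT_W_GRID = tuple(round(0.1 * i, 1) for i in range(11))
DEFAULT_METHODS = ("none", "clara", "hl")
DEFAULT_K_LIST = (2, 3, 4, 5)

__all__ = ["RunConfig", "RunResult", "enumerate_strategies", "run_pipeline"]


@dataclass
class RunConfig:
    genotype_path: str | None = None
    canopy_path: str | None = None  # weekly observations
    phenotype_path: str | None = None
    simulate: SimConfig | None = None
    maf_threshold: float = 0.05
    w_grid: tuple[float, ...] = DEFAULT_W_GRID
    methods: tuple[str, ...] = DEFAULT_METHODS
    k_list: tuple[int, ...] = DEFAULT_K_LIST
    loo_mode: str = "fixed_vc"  # or "refit_vc"
    day_start: int = DEFAULT_DAY_START
    n_days: int = DEFAULT_N_DAYS
    clara_seed: int = 0
    output_dir: str | None = None
    write_figures: bool = False

    def __post_init__(self) -> None:
        have_paths = all(p is not None for p in
                         (self.genotype_path, self.canopy_path, self.phenotype_path))
        if have_paths == (self.simulate is not None):
            raise ValueError(
                "exactly one of (genotype/canopy/phenotype paths) or a "
                "simulate block must be given")
        ws = tuple(self.w_grid)
        if len(set(ws)) != len(ws) or list(ws) != sorted(ws):
            raise ValueError("w_grid must be unique and sorted")
        if any(not 0.0 <= w <= 1.0 for w in ws):
            raise ValueError("w_grid values must be in [0, 1]")
        bad = set(self.methods) - {"none", "clara", "hl"}
        if bad:
            raise ValueError(f"unknown clustering methods: {sorted(bad)}")
        bad_k = set(self.k_list) - {2, 3, 4, 5}
        if bad_k:
            raise ValueError(f"cluster counts must be in {{2,3,4,5}}: {sorted(bad_k)}")


@dataclass
class RunResult:
    table_long: pd.DataFrame
    table_wide: pd.DataFrame
    results: dict[str, PredictionResult]  # keyed by strategy label
    assignments: dict[tuple[str, int], ClusterAssignment]
    gx: RelationshipKernel
    gc: RelationshipKernel
    qc: pd.DataFrame
    manifest: dict


def enumerate_strategies(config: RunConfig) -> list[CVStrategy]:
    """Deterministic (method, k, w) grid; 99 strategies at the defaults."""
    strategies: list[CVStrategy] = []
    if "none" in config.methods:
        strategies += [CVStrategy("none", 1, w) for w in config.w_grid]
    for method in ("clara", "hl"):
        if method in config.methods:
            for k in sorted(config.k_list):
                strategies += [CVStrategy(method, k, w) for w in config.w_grid]
    if not strategies:
        raise ValueError("empty strategy grid")
    return strategies


def _load_inputs(config: RunConfig) -> tuple[GenotypeMatrix, list, PhenotypeVector]:
    if config.simulate is not None:
        g, series, y, _truth = simulate_nam(config.simulate)
        return g, series, y
    g = read_genotypes(config.genotype_path)
    weekly = read_canopy(config.canopy_path)
    y = read_phenotypes(config.phenotype_path)
    return g, weekly_series_from_matrix(weekly), y


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage in order and (optionally) write run artifacts."""
    t0 = time.time()
    g_raw, series, y = _load_inputs(config)
    logger.info("inputs: %d lines, %d markers, %d canopy series",
                g_raw.n_lines, g_raw.n_markers, len(series))

    g_imp = impute_missing_mode(g_raw)
    g_qc = maf_filter(g_imp, config.maf_threshold)
    qc = qc_summary(g_raw, g_qc, config.maf_threshold)
    logger.info("QC: kept %d / %d markers (MAF >= %g)",
                g_qc.n_markers, g_raw.n_markers, config.maf_threshold)

    canopy = build_canopy_matrix(series, config.day_start, config.n_days)
    g_al, c_al, y_al = align_datasets(g_qc, canopy, y)
    obs = y_al.observed_mask
    if not obs.all():  # phenotyped lines only enter the CV
        keep = [l for l, m in zip(y_al.line_ids, obs) if m]
        gi = [g_al.line_ids.index(l) for l in keep]
        g_al = GenotypeMatrix(keep, list(g_al.marker_ids), g_al.calls[gi])
        c_al = CanopyMatrix(keep, list(c_al.day_labels), c_al.values[gi])
        y_al = PhenotypeVector(keep, y_al.values[gi])

    x_std = standardize_columns(g_al.line_ids, g_al.calls.astype(float))
    c_std = standardize_columns(c_al.line_ids, c_al.values)
    gx = marker_kernel(x_std)
    gc = canopy_kernel(c_std)
    feats = combined_features(x_std, c_std)

    assignments: dict[tuple[str, int], ClusterAssignment] = {}
    for method in config.methods:
        if method == "none":
            continue
        for k in sorted(config.k_list):
            if method == "clara":
                assignments[(method, k)] = clara_cluster(
                    g_al.line_ids, feats, k, seed=config.clara_seed)
            else:
                assignments[(method, k)] = hl_ward_cluster(g_al.line_ids, feats, k)
            logger.info("clustered: %s k=%d sizes=%s", method, k,
                        np.bincount(assignments[(method, k)].labels).tolist())

    strategies = enumerate_strategies(config)
    hybrids = {w: hybrid_kernel(gx, gc, w) for w in config.w_grid}
    results: dict[str, PredictionResult] = {}
    for s in strategies:
        kf = hybrids[s.w]
        if s.method == "none":
            assignment = ClusterAssignment(list(g_al.line_ids),
                                           np.zeros(g_al.n_lines, dtype=int),
                                           "none", 1)
        else:
            assignment = assignments[(s.method, s.k)]
        ids, obs_v, pred_v = clustered_loo(y_al.values, kf, assignment,
                                           mode=config.loo_mode)
        results[s.label] = PredictionResult(ids, obs_v, pred_v, s)
        logger.debug("strategy %s done", s.label)

    long = strategy_table(list(results.values()))
    wide = pivot_strategy_table(long)
    manifest = {
        "package_version": __version__,
        "config": _config_dict(config),
        "n_lines": g_al.n_lines,
        "n_markers_post_qc": g_al.n_markers,
        "n_strategies": len(strategies),
        "elapsed_s": round(time.time() - t0, 2),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()[:16]

    out = RunResult(long, wide, results, assignments, gx, gc, qc, manifest)
    if config.output_dir is not None:
        _write_artifacts(out, config)
    return out


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if config.simulate is not None:
        d["simulate"] = asdict(config.simulate)
    return d


def _write_artifacts(res: RunResult, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    res.table_long.to_csv(outdir / "strategy_table.tsv", sep="\t", index=False,
                          float_format="%.6g")
    res.table_wide.to_csv(outdir / "strategy_table_wide.tsv", sep="\t",
                          float_format="%.6g")
    res.qc.to_csv(outdir / "qc_summary.tsv", sep="\t", index=False)
    write_kernel(res.gx, outdir / "kernel_marker.tsv")
    write_kernel(res.gc, outdir / "kernel_canopy.tsv")
    for (method, k), a in res.assignments.items():
        write_assignment(a, outdir / f"clusters_{method}_k{k}.tsv")
    for label, r in res.results.items():
        pd.DataFrame({"line_id": r.line_ids, "observed": r.observed,
                      "predicted": r.predicted}).to_csv(
            outdir / f"predictions_{label}.tsv", sep="\t", index=False,
            float_format="%.6g")
        grid = classification_grid(r)
        pd.DataFrame(grid.rates).to_csv(outdir / f"grid_{label}.tsv", sep="\t",
                                        index=False, header=False,
                                        float_format="%.4f")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, default=str)
    if config.write_figures:
        from .viz import prediction_panel_figure
        fig = prediction_panel_figure(res)
        fig.savefig(outdir / "prediction_panels.png", dpi=150)
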