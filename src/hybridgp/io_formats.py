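"""Tabular input/output, quality control and dataset alignment.

Canonical on-disk layout: UTF-8 tab-separated text with a header row and
the first column named ``line_id``.  Genotypes are minor-allele counts in
{0, 1, 2} (missing allowed before imputation), canopy coverage values are
proportions in [0, 1] with integer day-after-planting column labels, and
phenotypes are a single real-valued column (grain yield, kg/ha).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for missing genotype calls

__all__ = [
    "GenotypeMatrix",
    "CanopyMatrix",
    "PhenotypeVector",
    "read_genotypes",
    "read_genotypes_vcf",
    "write_genotypes",
    "read_canopy",
    "write_canopy",
    "read_phenotypes",
    "write_phenotypes",
    "impute_missing_mode",
    "maf_filter",
    "align_datasets",
]


class ValidationError(ValueError):
    """Raised when an input file or matrix violates the format contract."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups = sorted({x for x in labels if x in seen or seen.add(x)})  # type: ignore[func-returns-value]
    if dups:
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class GenotypeMatrix:
    """Lines x markers minor-allele counts (0/1/2; ``MISSING`` = -1)."""

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # (n, p) int

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValidationError(
                f"genotype shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        _check_unique(self.line_ids, "line IDs")
        _check_unique(self.marker_ids, "marker IDs")
        bad = (self.calls != MISSING) & ((self.calls < 0) | (self.calls > 2))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"invalid genotype code {self.calls[i, j]} at line "
                f"{self.line_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_missing(self) -> int:
        return int((self.calls == MISSING).sum())

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker, ignoring missing calls."""
        calls = np.ma.masked_equal(self.calls, MISSING)
        freq = calls.mean(axis=0).filled(0.0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class CanopyMatrix:
    """Lines x days canopy-coverage proportions in [0, 1]."""

    line_ids: list[str]
    day_labels: list[int]
    values: np.ndarray  # (n, q) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.line_ids), len(self.day_labels)):
            raise ValidationError("canopy shape does not match labels")
        _check_unique(self.line_ids, "line IDs")
        days = np.asarray(self.day_labels)
        if len(days) > 1 and not (np.diff(days) > 0).all():
            raise ValidationError("day labels must be strictly increasing")
        if ((self.values < 0) | (self.values > 1)).any():
            i, j = map(int, np.argwhere((self.values < 0) | (self.values > 1))[0])
            raise ValidationError(
                f"canopy value {self.values[i, j]} outside [0,1] at line "
                f"{self.line_ids[i]!r}, day {self.day_labels[j]}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)


@dataclass
class PhenotypeVector:
    """Per-line trait values (NaN = missing)."""

    line_ids: list[str]
    values: np.ndarray  # (n,) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.line_ids),):
            raise ValidationError("phenotype length does not match line IDs")
        _check_unique(self.line_ids, "line IDs")

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


# ---------------------------------------------------------------------------
# readers / writers

def _read_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype={0: str})
    if df.columns[0] != "line_id":
        raise ValidationError(
            f"{path}: first column must be 'line_id', got {df.columns[0]!r}"
        )
    return df.set_index("line_id")


def read_genotypes(path: str | Path, delimiter: str = "\t") -> GenotypeMatrix:
    """Read a line-by-marker TSV of minor-allele counts.

    Missing calls may be encoded as ``NA``, empty, ``.`` or ``-1``.
    """
    df = _read_table(path, delimiter)
    raw = df.replace({".": np.nan, "-1": np.nan}).to_numpy(dtype=object)
    calls = np.full(raw.shape, MISSING, dtype=np.int16)
    for (i, j), v in np.ndenumerate(raw):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        try:
            code = int(v)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: non-integer genotype {v!r} at line "
                f"{df.index[i]!r}, marker {df.columns[j]!r}"
            ) from None
        if code not in (0, 1, 2):
            raise ValidationError(
                f"{path}: invalid genotype code {code} at line "
                f"{df.index[i]!r}, marker {df.columns[j]!r}"
            )
        calls[i, j] = code
    return GenotypeMatrix(list(df.index), list(df.columns), calls)


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.calls, index=pd.Index(g.line_ids, name="line_id"),
                      columns=g.marker_ids)
    df.to_csv(path, sep="\t")


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Ingest genotypes from a VCF (v4.x), re-polarized to minor-allele counts.

    Requires :mod:`cyvcf2`.  Biallelic sites only; samples become lines and
    site IDs (or CHROM:POS) become marker IDs.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic markers only
        counts = np.full(len(line_ids), MISSING, dtype=np.int16)
        for s, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if alleles:
                counts[s] = sum(alleles)
        obs = counts[counts != MISSING]
        if obs.size and obs.mean() / 2.0 > 0.5:  # coded allele must be minor
            counts[counts != MISSING] = 2 - counts[counts != MISSING]
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        cols.append(counts)
    if not cols:
        raise ValidationError(f"{path}: no biallelic sites found")
    return GenotypeMatrix(line_ids, marker_ids, np.column_stack(cols))


def read_canopy(path: str | Path, delimiter: str = "\t") -> CanopyMatrix:
    """Read a line-by-day (or line-by-week) canopy coverage TSV.

    Column headers are integer days after planting, optionally prefixed
    with ``day_``.
    """
    df = _read_table(path, delimiter)
    days = [int(str(c).removeprefix("day_")) for c in df.columns]
    return CanopyMatrix(list(df.index), days, df.to_numpy(dtype=float))


def write_canopy(c: CanopyMatrix, path: str | Path) -> None:
    df = pd.DataFrame(c.values, index=pd.Index(c.line_ids, name="line_id"),
                      columns=[f"day_{d}" for d in c.day_labels])
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_phenotypes(path: str | Path, delimiter: str = "\t",
                    trait: str | None = None) -> PhenotypeVector:
    df = _read_table(path, delimiter)
    col = trait if trait is not None else df.columns[0]
    return PhenotypeVector(list(df.index), df[col].to_numpy(dtype=float))


def write_phenotypes(y: PhenotypeVector, path: str | Path,
                     trait: str = "grain_yield") -> None:
    df = pd.DataFrame({trait: y.values},
                      index=pd.Index(y.line_ids, name="line_id"))
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# quality control

def impute_missing_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the column's modal code (keeps codes integral)."""
    calls = g.calls.copy()
    for j in range(g.n_markers):
        col = calls[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValidationError(
                f"marker {g.marker_ids[j]!r} has no observed calls")
        mode = np.bincount(obs, minlength=3).argmax()
        col[miss] = mode
    return GenotypeMatrix(list(g.line_ids), list(g.marker_ids), calls)


def maf_filter(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Drop markers whose minor allele frequency is below ``threshold``.

    Removal is strict-less-than: a marker with MAF exactly equal to the
    threshold is retained.  Column order is preserved.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    if (g.calls == MISSING).any():
        raise ValidationError("impute missing calls before MAF filtering")
    keep = g.maf() >= threshold
    return GenotypeMatrix(
        list(g.line_ids),
        [m for m, k in zip(g.marker_ids, keep) if k],
        g.calls[:, keep],
    )


def qc_summary(before: GenotypeMatrix, after: GenotypeMatrix,
               threshold: float) -> pd.DataFrame:
    """One-row QC report (marker counts, missingness, threshold)."""
    return pd.DataFrame(
        {
            "n_lines": [before.n_lines],
            "n_markers_in": [before.n_markers],
            "n_markers_kept": [after.n_markers],
            "n_markers_dropped": [before.n_markers - after.n_markers],
            "maf_threshold": [threshold],
            "n_missing_calls": [before.n_missing],
        }
    )


def align_datasets(
    g: GenotypeMatrix, c: CanopyMatrix, y: PhenotypeVector
) -> tuple[GenotypeMatrix, CanopyMatrix, PhenotypeVector]:
    """Restrict all three datasets to common lines, in sorted-ID order.

    Lines with missing phenotype are retained (they remain valid prediction
    targets); training code masks them via ``PhenotypeVector.observed_mask``.
    """
    common = sorted(set(g.line_ids) & set(c.line_ids) & set(y.line_ids))
    if not common:
        raise ValidationError("no line IDs shared by genotype, canopy and phenotype")
    gi = [g.line_ids.index(l) for l in common]
    ci = [c.line_ids.index(l) for l in common]
    yi = [y.line_ids.index(l) for l in common]
    return (
        GenotypeMatrix(common, list(g.marker_ids), g.calls[gi]),
        CanopyMatrix(common, list(c.day_labels), c.values[ci]),
        PhenotypeVector(common, y.values[yi]),
    )
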