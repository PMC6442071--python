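"""Relationship kernels: marker, canopy, and the weighted hybrid combination.

Feature matrices (minor-allele counts or daily canopy proportions) are
column-centered and scaled to unit sample variance (n-1 divisor), then
turned into n x n similarity matrices

    G_X = X X' / p        (markers, p columns)
    G_C = C C' / q        (canopy, q columns, canonically q = 42)

which act as random-effect covariance structures in GBLUP.  The hybrid
kernel blends the two sources element-wise,

    G_F = (1 - w) G_X + w G_C,        0 <= w <= 1,

a convex combination that stays symmetric positive semidefinite.  w = 0 is
the marker-only model and w = 1 the canopy-only model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StandardizedFeatures",
    "RelationshipKernel",
    "standardize_columns",
    "marker_kernel",
    "canopy_kernel",
    "hybrid_kernel",
    "read_kernel",
    "write_kernel",
]


@dataclass
class StandardizedFeatures:
    """Column-standardized feature matrix with provenance of means/sds."""

    line_ids: list[str]
    values: np.ndarray  # (n, m)
    column_means: np.ndarray
    column_sds: np.ndarray


@dataclass
class RelationshipKernel:
    """Symmetric PSD line-by-line similarity matrix."""

    line_ids: list[str]
    matrix: np.ndarray  # (n, n)
    source_tag: str  # "marker" | "canopy" | "hybrid(w)"

    @property
    def n(self) -> int:
        return len(self.line_ids)

    def check(self, rtol_psd: float = 1e-8) -> None:
        """Assert symmetry and (numerically) positive semidefiniteness."""
        k = self.matrix
        if np.abs(k - k.T).max() >= 1e-10:
            raise ValueError(f"kernel {self.source_tag}: not symmetric")
        ev = np.linalg.eigvalsh(k)
        if ev[0] < -rtol_psd * max(ev[-1], 1.0):
            raise ValueError(
                f"kernel {self.source_tag}: negative eigenvalue {ev[0]:.3e}")


def standardize_columns(line_ids: list[str], raw: np.ndarray,
                        ddof: int = 1) -> StandardizedFeatures:
    """Center each column at 0 and scale to unit variance (default n-1 divisor)."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=ddof)
    const = np.flatnonzero(sds == 0.0)
    if const.size:
        raise ValueError(f"constant column(s) at index {const.tolist()}: "
                         "cannot standardize (filter upstream)")
    return StandardizedFeatures(list(line_ids), (raw - means) / sds, means, sds)


def _cross_product_kernel(feats: StandardizedFeatures, tag: str) -> RelationshipKernel:
    v = feats.values
    k = v @ v.T / v.shape[1]
    k = (k + k.T) / 2.0  # remove floating-point asymmetry
    return RelationshipKernel(list(feats.line_ids), k, tag)


def marker_kernel(x: StandardizedFeatures) -> RelationshipKernel:
    """G_X = XX'/p from standardized marker codes."""
    return _cross_product_kernel(x, "marker")


def canopy_kernel(c: StandardizedFeatures) -> RelationshipKernel:
    """G_C = CC'/q from standardized daily canopy coverage."""
    return _cross_product_kernel(c, "canopy")


def hybrid_kernel(gx: RelationshipKernel, gc: RelationshipKernel,
                  w: float) -> RelationshipKernel:
    """Element-wise G_F = (1-w) G_X + w G_C.

    Line IDs must match in the same order; no silent realignment.  The
    endpoints return exact copies of the corresponding base kernel.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"hybrid weight must be in [0, 1], got {w}")
    if gx.line_ids != gc.line_ids:
        raise ValueError("marker and canopy kernels have mismatched line IDs")
    if w == 0.0:
        m = gx.matrix.copy()
    elif w == 1.0:
        m = gc.matrix.copy()
    else:
        m = (1.0 - w) * gx.matrix + w * gc.matrix
    return RelationshipKernel(list(gx.line_ids), m, f"hybrid({w:g})")


def write_kernel(k: RelationshipKernel, path: str | Path) -> None:
    """Square symmetric TSV with line IDs as both header and first column."""
    df = pd.DataFrame(k.matrix, index=pd.Index(k.line_ids, name="line_id"),
                      columns=k.line_ids)
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_kernel(path: str | Path, source_tag: str = "imported") -> RelationshipKernel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: kernel row/column IDs differ")
    return RelationshipKernel(list(df.index), df.to_numpy(dtype=float), source_tag)
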