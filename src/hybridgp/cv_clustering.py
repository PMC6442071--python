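"""Cluster-based cross-validation design.

Lines are partitioned by one of two unsupervised methods operating on the
Euclidean distance over the column-concatenated standardized marker and
canopy features:

* CLARA (Clustering Large Applications): sampling-based k-medoids.  A
  subsample is drawn, k medoids are found on it by PAM (BUILD + SWAP),
  every line is assigned to its nearest medoid, and the medoid set with
  the smallest total dissimilarity over all lines wins across a fixed
  number of draws.  Deterministic given the seed.
* HL (hierarchical linkage): agglomerative clustering with the Ward
  criterion (minimum increase in total within-cluster variance), tree cut
  at k clusters.

Prediction then runs leave-one-observation-out GBLUP independently inside
each cluster and concatenates the per-cluster prediction vectors into one
vector over all lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .gblup import loo_predict
from .kernels import RelationshipKernel, StandardizedFeatures

__all__ = [
    "ClusterAssignment",
    "CVStrategy",
    "combined_features",
    "clara_cluster",
    "hl_ward_cluster",
    "clustered_loo",
]


@dataclass
class ClusterAssignment:
    line_ids: list[str]
    labels: np.ndarray  # (n,) ints in {0..k-1}
    method: str  # "none" | "clara" | "hl"
    k: int
    seed: int | None = None  # clara only

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.line_ids),):
            raise ValueError("labels length does not match line IDs")
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError(
                f"expected {self.k} non-empty clusters labelled 0..{self.k - 1}, "
                f"got labels {present.tolist()}")

    def members(self, label: int) -> list[str]:
        return [l for l, g in zip(self.line_ids, self.labels) if g == label]


@dataclass(frozen=True)
class CVStrategy:
    """One cell of the strategy grid: clustering method, k, hybrid weight."""

    method: str  # "none" | "clara" | "hl"
    k: int  # 1 iff method == "none"
    w: float

    def __post_init__(self) -> None:
        if (self.method == "none") != (self.k == 1):
            raise ValueError("method 'none' requires k == 1 and vice versa")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"weight must be in [0, 1], got {self.w}")

    @property
    def label(self) -> str:
        return f"{self.method}_k{self.k}_w{self.w:g}"


def combined_features(x: StandardizedFeatures,
                      c: StandardizedFeatures) -> np.ndarray:
    """Column-wise concatenation of standardized marker and canopy blocks."""
    if x.line_ids != c.line_ids:
        raise ValueError("marker and canopy features have mismatched line IDs")
    return np.hstack([x.values, c.values])


# ---------------------------------------------------------------------------
# k-medoids (PAM) and CLARA

def _pam(dist: np.ndarray, k: int) -> np.ndarray:
    """Classic PAM on a dense distance matrix: greedy BUILD then SWAP to a
    local optimum.  Ties break toward the lowest index (deterministic)."""
    m = dist.shape[0]
    # BUILD: start from the most central object, then add the object giving
    # the largest reduction in total dissimilarity.
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        nearest = dist[:, medoids].min(axis=1)
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    best = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(k):
            for h in range(m):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1:])
                c = cost(trial)
                if c < best - 1e-12:
                    medoids, best = trial, c
                    improved = True
    return np.asarray(medoids, dtype=int)


def clara_cluster(line_ids: list[str], features: np.ndarray, k: int,
                  n_samples: int = 5, sample_size: int | None = None,
                  seed: int = 0) -> ClusterAssignment:
    """CLARA: k-medoids via PAM on random subsamples; best medoid set over
    ``n_samples`` draws by total distance of ALL lines to their nearest medoid.

    Default sample size 40 + 2k follows the classic algorithm.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds number of lines ({n})")
    if sample_size is None:
        sample_size = 40 + 2 * k
    sample_size = min(sample_size, n)
    if sample_size < k:
        raise ValueError(f"sample_size {sample_size} smaller than k={k}")
    rng = np.random.default_rng(seed)

    best_cost = np.inf
    best_medoids: np.ndarray | None = None
    for _ in range(n_samples):
        idx = np.sort(rng.choice(n, size=sample_size, replace=False))
        sub = features[idx]
        meds_local = _pam(cdist(sub, sub), k)
        meds = idx[meds_local]
        total = cdist(features, features[meds]).min(axis=1).sum()
        if total < best_cost - 1e-12:
            best_cost, best_medoids = total, meds
    assert best_medoids is not None
    assign = np.argmin(cdist(features, features[best_medoids]), axis=1)
    # relabel by order of first appearance so labels are canonical
    labels = _canonical_labels(assign)
    if labels.max() + 1 < k:
        # a medoid captured no points outside the sample: extremely unlikely
        # with Euclidean assignment, but fail loudly rather than return an
        # empty cluster
        raise RuntimeError("CLARA produced an empty cluster")
    return ClusterAssignment(list(line_ids), labels, "clara", k, seed)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    order: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, g in enumerate(raw):
        if g not in order:
            order[g] = len(order)
        out[i] = order[g]
    return out


def hl_ward_cluster(line_ids: list[str], features: np.ndarray,
                    k: int) -> ClusterAssignment:
    """Agglomerative Ward clustering on Euclidean distance, cut at k clusters."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds number of lines ({n})")
    z = linkage(features, method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(list(line_ids), _canonical_labels(raw), "hl", k)


# ---------------------------------------------------------------------------
# clustered leave-one-out

def clustered_loo(y: np.ndarray, k_full: RelationshipKernel,
                  assignment: ClusterAssignment,
                  mode: str = "fixed_vc") -> tuple[list[str], np.ndarray, np.ndarray]:
    """Within-cluster leave-one-observation-out prediction.

    Runs :func:`hybridgp.gblup.loo_predict` independently inside each
    cluster (training restricted to cluster members) and assembles one
    prediction vector over all lines, in the kernel's line order.

    Returns ``(line_ids, observed, predicted)``.
    """
    y = np.asarray(y, dtype=float)
    if assignment.line_ids != k_full.line_ids:
        raise ValueError("assignment and kernel line IDs differ")
    if y.shape != (k_full.n,):
        raise ValueError("response length does not match kernel")
    pos = {l: i for i, l in enumerate(k_full.line_ids)}
    predicted = np.full(k_full.n, np.nan)
    for g in range(assignment.k):
        members = assignment.members(g)
        if len(members) < 3:
            raise ValueError(
                f"cluster {g} has only {len(members)} lines (< 3); "
                "leave-one-out within it is not meaningful")
        idx = [pos[l] for l in members]
        sub = RelationshipKernel(
            members, k_full.matrix[np.ix_(idx, idx)], k_full.source_tag)
        predicted[idx] = loo_predict(y[idx], sub, mode=mode)
    assert not np.isnan(predicted).any()
    return list(k_full.line_ids), y.copy(), predicted


def write_assignment(a: ClusterAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"line_id": a.line_ids, "method": a.method, "k": a.k,
         "label": a.labels, "seed": a.seed if a.seed is not None else ""}
    ).to_csv(path, sep="\t", index=False)
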