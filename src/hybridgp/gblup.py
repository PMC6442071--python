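"""Single-kernel GBLUP: REML variance components and BLUP prediction.

Model: y_i = mu + u_i + e_i with u ~ N(0, G sigma_u^2) and
e ~ N(0, I sigma_e^2).  The restricted likelihood is profiled over the
variance ratio delta = sigma_e^2 / sigma_u^2 after a single spectral
decomposition of the kernel, so each candidate ratio costs O(n): with
G = U D U', the rotated model has independent components with variances
sigma_u^2 (d_i + delta), giving closed-form generalized-least-squares
estimates of mu and sigma_u^2 at each delta.

Held-out lines are predicted from the kernel cross-covariance,

    y_hat_test = mu + K_ts (K_tt + delta I)^{-1} (y_train - mu),

and leave-one-out prediction has two modes: ``fixed_vc`` estimates
(mu, delta) once on the full training set and applies the exact
leave-one-out identity for kernel-ridge smoothers, while ``refit_vc``
re-runs the whole REML fit with each line excluded (the brute-force
definition; used by oracle tests and available for small n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .kernels import RelationshipKernel

LOG_DELTA_BOUNDS = (-10.0, 10.0)
_JITTER_REL = 1e-8  # solver-only diagonal jitter, relative to mean(diag)

__all__ = ["GBLUPFit", "fit_gblup", "predict_holdout", "loo_predict"]


@dataclass
class GBLUPFit:
    """REML estimates and random-effect BLUPs for one training set."""

    mu: float
    sigma_u2: float
    sigma_e2: float
    u_hat: np.ndarray  # per-training-line BLUPs
    train_ids: list[str]
    at_boundary: bool = False  # variance-ratio optimum pinned at a bound
    reml_loglik: float = np.nan

    @property
    def h2(self) -> float:
        """Heritability-like ratio sigma_u^2 / (sigma_u^2 + sigma_e^2)."""
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else 0.0

    @property
    def delta(self) -> float:
        """Variance ratio sigma_e^2 / sigma_u^2 (inf at the sigma_u^2=0 boundary)."""
        return self.sigma_e2 / self.sigma_u2 if self.sigma_u2 > 0 else np.inf


def _profile_reml(log_delta: float, d: np.ndarray, x: np.ndarray,
                  yr: np.ndarray) -> tuple[float, float, float]:
    """Profiled restricted log-likelihood at one variance ratio.

    Returns (loglik, mu_hat, sigma_u2_hat) for the rotated model where d
    are kernel eigenvalues, x = U'1 and yr = U'y.
    """
    n = d.size
    v = d + np.exp(log_delta)
    xtvx = np.sum(x * x / v)
    mu = np.sum(x * yr / v) / xtvx
    r = yr - mu * x
    s2u = np.sum(r * r / v) / (n - 1)
    ll = -0.5 * ((n - 1) * np.log(s2u) + np.sum(np.log(v))
                 + np.log(xtvx) + (n - 1))
    return ll, mu, s2u


def fit_gblup(y: np.ndarray, k: RelationshipKernel) -> GBLUPFit:
    """REML fit of the single-random-effect GBLUP model.

    Parameters
    ----------
    y
        Training responses, one per kernel line, no missing values.
    k
        Relationship kernel restricted to the training lines.
    """
    y = np.asarray(y, dtype=float)
    n = k.n
    if y.shape != (n,):
        raise ValueError(f"response length {y.shape} does not match kernel ({n} lines)")
    if n < 3:
        raise ValueError(f"need >= 3 training lines, got {n}")
    if np.isnan(y).any():
        raise ValueError("missing responses in training set")

    if np.ptp(y) == 0.0:  # constant response: nothing to explain
        return GBLUPFit(mu=float(y[0]), sigma_u2=0.0, sigma_e2=1e-12,
                        u_hat=np.zeros(n), train_ids=list(k.line_ids),
                        at_boundary=True)

    d, u_mat = eigh(k.matrix)
    d = np.maximum(d, 0.0)  # clip tiny negative eigenvalues
    x = u_mat.T @ np.ones(n)
    yr = u_mat.T @ y

    res = minimize_scalar(
        lambda ld: -_profile_reml(ld, d, x, yr)[0],
        bounds=LOG_DELTA_BOUNDS, method="bounded",
        options={"xatol": 1e-9},
    )
    log_delta = float(res.x)
    at_boundary = (log_delta - LOG_DELTA_BOUNDS[0] < 1e-6
                   or LOG_DELTA_BOUNDS[1] - log_delta < 1e-6)
    ll, mu, s2u = _profile_reml(log_delta, d, x, yr)
    delta = np.exp(log_delta)
    u_hat = u_mat @ (d / (d + delta) * (yr - mu * x))
    return GBLUPFit(mu=float(mu), sigma_u2=float(s2u),
                    sigma_e2=float(delta * s2u), u_hat=u_hat,
                    train_ids=list(k.line_ids), at_boundary=at_boundary,
                    reml_loglik=float(ll))


def _submatrix(k: RelationshipKernel, rows: list[str], cols: list[str]) -> np.ndarray:
    pos = {l: i for i, l in enumerate(k.line_ids)}
    ri = [pos[l] for l in rows]
    ci = [pos[l] for l in cols]
    return k.matrix[np.ix_(ri, ci)]


def predict_holdout(fit: GBLUPFit, k_full: RelationshipKernel,
                    train_ids: list[str], test_ids: list[str],
                    y_train: np.ndarray) -> np.ndarray:
    """BLUP predictions for held-out lines from kernel cross-covariances."""
    if set(train_ids) & set(test_ids):
        raise ValueError("train and test IDs overlap")
    missing = (set(train_ids) | set(test_ids)) - set(k_full.line_ids)
    if missing:
        raise ValueError(f"IDs absent from kernel: {sorted(missing)}")
    y_train = np.asarray(y_train, dtype=float)
    if fit.sigma_u2 <= 1e-12:  # no kernel variance: best prediction is mu
        return np.full(len(test_ids), fit.mu)
    ktt = _submatrix(k_full, train_ids, train_ids)
    kst = _submatrix(k_full, test_ids, train_ids)
    a = ktt + fit.delta * np.eye(len(train_ids))
    a[np.diag_indices_from(a)] += _JITTER_REL * np.mean(np.diag(ktt))
    alpha = cho_solve(cho_factor(a, lower=True), y_train - fit.mu)
    return fit.mu + kst @ alpha


def loo_predict(y: np.ndarray, k: RelationshipKernel,
                mode: str = "fixed_vc") -> np.ndarray:
    """Leave-one-observation-out predictions for every line.

    ``fixed_vc`` (default): one REML fit on all lines supplies (mu, delta),
    then each line's prediction uses the exact leave-one-out identity
    pred_i = mu + (y_i - mu) - alpha_i / A^{-1}_ii with A = K + delta I and
    alpha = A^{-1} (y - mu); identical to deleting the line and re-solving
    with those components held fixed, at one matrix inversion total.

    ``refit_vc``: the naive definition — full REML refit per fold.
    """
    y = np.asarray(y, dtype=float)
    n = k.n
    if n < 3:
        raise ValueError(f"need >= 3 lines for leave-one-out, got {n}")
    if mode == "refit_vc":
        preds = np.empty(n)
        for i in range(n):
            keep = [l for j, l in enumerate(k.line_ids) if j != i]
            sub = RelationshipKernel(keep, _submatrix(k, keep, keep), k.source_tag)
            fit = fit_gblup(np.delete(y, i), sub)
            preds[i] = predict_holdout(fit, k, keep, [k.line_ids[i]],
                                       np.delete(y, i))[0]
        return preds
    if mode != "fixed_vc":
        raise ValueError(f"unknown LOO mode {mode!r}")

    fit = fit_gblup(y, k)
    if fit.sigma_u2 <= 1e-12:
        return np.full(n, fit.mu)
    a = k.matrix + fit.delta * np.eye(n)
    a[np.diag_indices_from(a)] += _JITTER_REL * np.mean(np.diag(k.matrix))
    a_inv = np.linalg.inv(a)
    alpha = a_inv @ (y - fit.mu)
    return y - alpha / np.diag(a_inv)
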