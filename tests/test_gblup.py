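"""GBLUP tests, cross-checked against independent dense oracles.

The oracles never share code with the implementation: the restricted
likelihood is evaluated with dense determinants/solves, and held-out
predictions come from Henderson's mixed-model equations solved as one
dense block system.
"""

import numpy as np
import pytest

from hybridgp.gblup import fit_gblup, loo_predict, predict_holdout
from hybridgp.kernels import RelationshipKernel, marker_kernel, standardize_columns

JITTER_REL = 1e-8  # documented solver jitter, shared model constant


def random_kernel(seed, n, p=60):
    rng = np.random.default_rng(seed)
    feats = standardize_columns([f"L{i}" for i in range(n)],
                                rng.normal(size=(n, p)))
    return marker_kernel(feats)


def simulate_y(k, h2, seed):
    rng = np.random.default_rng(seed)
    n = k.n
    d, u = np.linalg.eigh(k.matrix)
    g = u @ (np.sqrt(np.maximum(d, 0) * h2) * rng.normal(size=n))
    return g + rng.normal(scale=np.sqrt(1 - h2), size=n)


# ---------------------------------------------------------------------------
# oracles

def dense_reml_loglik(y, K, delta):
    """Profiled restricted log-likelihood at variance ratio delta, computed
    with dense determinants and solves (no eigendecomposition)."""
    n = len(y)
    H = K + delta * np.eye(n)
    Hinv = np.linalg.inv(H)
    one = np.ones(n)
    xvx = one @ Hinv @ one
    mu = (one @ Hinv @ y) / xvx
    r = y - mu * one
    s2u = (r @ Hinv @ r) / (n - 1)
    _, logdet = np.linalg.slogdet(H)
    return -0.5 * ((n - 1) * np.log(s2u) + logdet + np.log(xvx) + (n - 1))


def mme_predict(y_train, k_full, train_idx, test_idx, sigma_u2, sigma_e2,
                mu=None):
    """Henderson MME oracle, solved in the substituted form u = G s (which
    needs no inverse of the possibly singular G = sigma_u2 K):

        [ n      (G 1)'        ] [mu]   [1'y]
        [ 1      G + sigma_e2 I] [s ] = [ y ]

    Held-out BLUPs follow as Cov(u_test, u_train) G^{-1} u = sigma_u2 K_st s.
    With ``mu`` supplied, only the random-effect block is solved at that
    fixed mean (the BLUP equations given the mean).  Near the sigma_e2 -> 0
    boundary the held-out prediction has sensitivity ~sigma_u2/sigma_e2 to
    mu, so comparisons there must fix mu rather than re-estimate it.
    """
    Ktt = k_full[np.ix_(train_idx, train_idx)]
    Kst = k_full[np.ix_(test_idx, train_idx)]
    nt = len(train_idx)
    G = sigma_u2 * (Ktt + JITTER_REL * np.mean(np.diag(Ktt)) * np.eye(nt))
    if mu is None:
        one = np.ones((nt, 1))
        C = np.block([
            [np.array([[float(nt)]]), (G @ one).T],
            [one, G + sigma_e2 * np.eye(nt)],
        ])
        rhs = np.concatenate([[y_train.sum()], y_train])
        sol = np.linalg.solve(C, rhs)
        sol += np.linalg.solve(C, rhs - C @ sol)  # one refinement step
        mu, s = sol[0], sol[1:]
    else:
        s = np.linalg.solve(G + sigma_e2 * np.eye(nt), y_train - mu)
    u_train = G @ s
    return mu, u_train, mu + sigma_u2 * (Kst @ s)


# ---------------------------------------------------------------------------

class TestREMLFit:
    @pytest.mark.parametrize("seed", range(4))
    def test_profile_likelihood_matches_dense_oracle(self, seed):
        # evaluate the fitted optimum's objective both ways
        n = 25
        k = random_kernel(seed, n)
        y = simulate_y(k, 0.5, seed + 100)
        fit = fit_gblup(y, k)
        delta = fit.sigma_e2 / fit.sigma_u2
        assert fit.reml_loglik == pytest.approx(
            dense_reml_loglik(y, k.matrix, delta), abs=1e-6)
        # and the optimum really is a maximum of the dense objective
        for factor in (0.5, 0.9, 1.1, 2.0):
            assert dense_reml_loglik(y, k.matrix, delta * factor) <= \
                fit.reml_loglik + 1e-9

    def test_variance_recovery_over_replicates(self):
        # sigma_u2 = sigma_e2 = 1 (h2=0.5): mean estimates within 3 MC SE
        n, reps = 100, 60
        k = random_kernel(1, n, p=200)
        h2s = []
        for r in range(reps):
            y = np.sqrt(2.0) * simulate_y(k, 0.5, 500 + r)  # var 1 + 1
            fit = fit_gblup(y, k)
            h2s.append(fit.h2)
        h2s = np.asarray(h2s)
        se = h2s.std(ddof=1) / np.sqrt(reps)
        assert abs(h2s.mean() - 0.5) < 3 * se

    def test_constant_response_collapses_to_mean(self):
        k = random_kernel(2, 10)
        fit = fit_gblup(np.full(10, 7.0), k)
        assert fit.mu == 7.0
        assert fit.sigma_u2 == 0.0
        assert fit.at_boundary

    def test_identity_kernel_total_variance_matches_sample_variance(self):
        # u and e are exchangeable under K = I, so REML splits the sample
        # variance between them
        rng = np.random.default_rng(3)
        n = 40
        y = rng.normal(size=n)
        k = RelationshipKernel([f"L{i}" for i in range(n)], np.eye(n), "id")
        fit = fit_gblup(y, k)
        assert fit.sigma_u2 + fit.sigma_e2 == pytest.approx(
            np.var(y, ddof=1), rel=1e-3)

    def test_translation_equivariance(self):
        k = random_kernel(4, 20)
        y = simulate_y(k, 0.5, 4)
        f1, f2 = fit_gblup(y, k), fit_gblup(y + 100.0, k)
        assert f2.mu == pytest.approx(f1.mu + 100.0, abs=1e-6)
        assert f2.sigma_u2 == pytest.approx(f1.sigma_u2, rel=1e-6)
        assert np.allclose(f2.u_hat, f1.u_hat, atol=1e-6)

    def test_scale_equivariance(self):
        k = random_kernel(5, 20)
        y = simulate_y(k, 0.5, 5)
        f1, f2 = fit_gblup(y, k), fit_gblup(3.0 * y, k)
        assert f2.sigma_u2 == pytest.approx(9.0 * f1.sigma_u2, rel=1e-5)
        assert f2.sigma_e2 == pytest.approx(9.0 * f1.sigma_e2, rel=1e-5)
        assert np.allclose(f2.u_hat, 3.0 * f1.u_hat, atol=1e-6)

    def test_too_few_lines_rejected(self):
        k = random_kernel(6, 2)
        with pytest.raises(ValueError):
            fit_gblup(np.array([1.0, 2.0]), k)


class TestHoldoutPrediction:
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_henderson_mme_oracle(self, seed):
        n = 20
        k = random_kernel(seed + 10, n)
        y = simulate_y(k, 0.6, seed + 200)
        train = list(range(15))
        test = list(range(15, 20))
        tr_ids = [k.line_ids[i] for i in train]
        te_ids = [k.line_ids[i] for i in test]
        sub = RelationshipKernel(tr_ids, k.matrix[np.ix_(train, train)], "m")
        fit = fit_gblup(y[train], sub)
        pred = predict_holdout(fit, k, tr_ids, te_ids, y[train])
        mu_o, _, pred_o = mme_predict(y[train], k.matrix, train, test,
                                      fit.sigma_u2, fit.sigma_e2)
        assert mu_o == pytest.approx(fit.mu, abs=1e-8)
        assert np.allclose(pred, pred_o, atol=1e-8)

    def test_uninformative_test_line_predicted_at_mean(self):
        n = 11
        k = random_kernel(20, n - 1)
        m = np.zeros((n, n))
        m[: n - 1, : n - 1] = k.matrix
        ids = k.line_ids + ["orphan"]
        kf = RelationshipKernel(ids, m, "m")
        y = simulate_y(k, 0.5, 21)
        fit = fit_gblup(y, RelationshipKernel(k.line_ids, k.matrix, "m"))
        pred = predict_holdout(fit, kf, k.line_ids, ["orphan"], y)
        assert pred[0] == pytest.approx(fit.mu, abs=1e-10)

    def test_near_duplicate_of_training_line_approaches_its_fit(self):
        # duplicate kernel row + tiny error variance -> prediction ~ fitted value
        n = 10
        k = random_kernel(22, n)
        m = np.zeros((n + 1, n + 1))
        m[:n, :n] = k.matrix
        m[n, :n] = k.matrix[0, :]
        m[:n, n] = k.matrix[0, :]
        m[n, n] = k.matrix[0, 0]
        ids = k.line_ids + ["twin"]
        kf = RelationshipKernel(ids, m, "m")
        y = simulate_y(k, 0.5, 23)
        fit = fit_gblup(y, k)
        fit.sigma_e2 = 1e-8 * fit.sigma_u2  # force near-interpolation
        pred = predict_holdout(fit, kf, k.line_ids, ["twin"], y)
        fitted0 = fit.mu + (k.matrix[0] @ np.linalg.solve(
            k.matrix + (fit.sigma_e2 / fit.sigma_u2 + 1e-8) * np.eye(n),
            y - fit.mu))
        assert pred[0] == pytest.approx(fitted0, abs=1e-4)

    def test_overlapping_train_test_rejected(self):
        k = random_kernel(24, 6)
        fit = fit_gblup(simulate_y(k, 0.5, 24), k)
        with pytest.raises(ValueError, match="overlap"):
            predict_holdout(fit, k, k.line_ids, [k.line_ids[0]],
                            np.zeros(6))


class TestLeaveOneOut:
    @pytest.mark.parametrize("seed", range(3))
    def test_fixed_vc_equals_naive_fixed_refits(self, seed):
        n = 20
        k = random_kernel(seed + 30, n)
        y = simulate_y(k, 0.5, seed + 300)
        fast = loo_predict(y, k, mode="fixed_vc")
        fit = fit_gblup(y, k)
        delta = fit.sigma_e2 / fit.sigma_u2
        naive = np.empty(n)
        for i in range(n):
            keep = np.r_[0:i, i + 1:n]
            A = (k.matrix[np.ix_(keep, keep)] + delta * np.eye(n - 1)
                 + JITTER_REL * np.mean(np.diag(k.matrix)) * np.eye(n - 1))
            naive[i] = fit.mu + k.matrix[i, keep] @ np.linalg.solve(
                A, y[keep] - fit.mu)
        assert np.allclose(fast, naive, atol=1e-8)

    def test_refit_vc_equals_per_fold_mme_oracle(self):
        n = 15
        k = random_kernel(40, n)
        y = simulate_y(k, 0.5, 400)
        impl = loo_predict(y, k, mode="refit_vc")
        for i in range(n):
            keep = [j for j in range(n) if j != i]
            sub = RelationshipKernel([k.line_ids[j] for j in keep],
                                     k.matrix[np.ix_(keep, keep)], "m")
            fit = fit_gblup(y[keep], sub)
            _, _, pred = mme_predict(y[keep], k.matrix, keep, [i],
                                     fit.sigma_u2, fit.sigma_e2)
            assert impl[i] == pytest.approx(pred[0], abs=1e-8)

    def test_pure_noise_predictions_in_null_band(self):
        # unrelated kernel, pure-noise response: correlations stay null
        reps, n = 30, 40
        rs = []
        for r in range(reps):
            rng = np.random.default_rng(600 + r)
            k = random_kernel(600 + r, n)
            y = rng.normal(size=n)
            pred = loo_predict(y, k)
            if np.ptp(pred) > 0:
                rs.append(np.corrcoef(y, pred)[0, 1])
        assert abs(np.mean(rs)) < 3.0 / np.sqrt(n * len(rs) / (1 + np.var(rs)))
        assert np.mean(np.abs(rs) < 3.0 / np.sqrt(n)) > 0.8

    def test_permutation_equivariance(self):
        n = 16
        k = random_kernel(50, n)
        y = simulate_y(k, 0.5, 500)
        perm = np.random.default_rng(0).permutation(n)
        kp = RelationshipKernel([k.line_ids[i] for i in perm],
                                k.matrix[np.ix_(perm, perm)], "m")
        assert np.allclose(loo_predict(y[perm], kp), loo_predict(y, k)[perm],
                           atol=1e-8)

    def test_informative_kernel_beats_permuted_kernel(self):
        # destroying kernel/line correspondence destroys predictive ability
        wins, reps, n = 0, 100, 80
        for r in range(reps):
            k = random_kernel(700 + r, n, p=100)
            y = simulate_y(k, 0.7, 700 + r)
            perm = np.random.default_rng(r).permutation(n)
            kp = RelationshipKernel(list(k.line_ids),
                                    k.matrix[np.ix_(perm, perm)], "m")
            r_true = np.corrcoef(y, loo_predict(y, k))[0, 1]
            r_perm = np.corrcoef(y, loo_predict(y, kp))[0, 1]
            wins += r_true > r_perm
        assert wins >= 0.95 * reps
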