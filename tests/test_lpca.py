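"""Logistic PCA: deviance arithmetic, MM optimiser contracts, projections."""

import numpy as np
import pytest
from scipy.optimize import minimize

from gsmm_lpca.lpca import (
    LPCAConfig,
    LPCAModel,
    bernoulli_deviance,
    fit_lpca,
    fitted_probabilities,
    saturated_parameters,
    scores,
    select_m,
)
from gsmm_lpca.reaction_matrix import BinaryReactionMatrix

from conftest import random_binary


def naive_deviance(x, theta):
    total = 0.0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            total += x[i, j] * theta[i, j] - np.log(1.0 + np.exp(theta[i, j]))
    return -2.0 * total


def brute_force_min_deviance(x, m, n_samples=2000, n_refine=10, seed=0):
    """Random-restart numeric minimisation over (mu, unit u) at k=1."""
    rng = np.random.default_rng(seed)
    n, r = x.shape
    theta = m * (2.0 * x - 1.0)

    def dev(params):
        mu, u = params[:r], params[r:]
        u = u / np.linalg.norm(u)
        th = mu + np.outer((theta - mu) @ u, u)
        return bernoulli_deviance(x, th)

    draws = []
    for _ in range(n_samples):
        mu = rng.normal(0, m, r)
        u = rng.normal(size=r)
        params = np.concatenate([mu, u / np.linalg.norm(u)])
        draws.append((dev(params), params))
    draws.sort(key=lambda t: t[0])
    best = draws[0][0]
    for _, params in draws[:n_refine]:
        res = minimize(dev, params, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        best = min(best, res.fun)
    return best


class TestSaturatedParameters:
    @pytest.mark.parametrize("x, m, expected", [(1, 4.0, 4.0), (0, 4.0, -4.0)])
    def test_entrywise(self, x, m, expected):
        assert saturated_parameters(np.array([[x]]), m)[0, 0] == expected

    def test_matrix(self):
        out = saturated_parameters(np.array([[1, 0], [0, 1]]), 2.0)
        assert out.tolist() == [[2.0, -2.0], [-2.0, 2.0]]

    def test_rejects_nonpositive_m(self):
        with pytest.raises(ValueError):
            saturated_parameters(np.array([[1]]), 0.0)


class TestBernoulliDeviance:
    def test_zero_theta_closed_form(self):
        x = random_binary(np.random.default_rng(0), 4, 6)
        assert bernoulli_deviance(x, np.zeros((4, 6))) == pytest.approx(
            2 * 4 * 6 * np.log(2), abs=1e-12
        )

    def test_confident_correct_entry(self):
        # x=1 with theta=10: contribution 2*log(1 + e^-10)
        d = bernoulli_deviance(np.array([[1]]), np.array([[10.0]]))
        assert d == pytest.approx(2 * np.log1p(np.exp(-10)), rel=1e-12)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(1)
        x = random_binary(rng, 6, 5)
        theta = rng.normal(0, 3, (6, 5))
        assert bernoulli_deviance(x, theta) == pytest.approx(
            naive_deviance(x, theta), abs=1e-12
        )

    def test_stable_at_extreme_theta(self):
        d = bernoulli_deviance(np.array([[0]]), np.array([[700.0]]))
        assert np.isfinite(d) and d == pytest.approx(1400.0, rel=1e-9)

    def test_nonfinite_theta_rejected(self):
        with pytest.raises(ValueError):
            bernoulli_deviance(np.array([[1]]), np.array([[np.inf]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bernoulli_deviance(np.zeros((2, 2)), np.zeros((2, 3)))


class TestFit:
    def test_orthonormal_and_monotone(self, canonical):
        model = canonical["model"]
        assert np.abs(model.U.T @ model.U - np.eye(model.k)).max() <= 1e-8
        trace = np.array(model.deviance_trace)
        assert (np.diff(trace) <= 1e-9).all()
        assert trace[-1] < trace[0]

    def test_score_identity_from_stored_fields(self, canonical):
        model, X = canonical["model"], canonical["matrix"]
        theta = model.m * (2.0 * X.values - 1.0)
        recomputed = (theta - model.mu) @ model.U
        assert np.abs(recomputed - model.S).max() <= 1e-10

    def test_two_block_symmetry_k1(self):
        # two groups of identical rows differing on a column subset
        row_a = [1, 1, 0, 0]
        row_b = [0, 0, 1, 1]
        x = np.array([row_a] * 3 + [row_b] * 3)
        model = fit_lpca(
            BinaryReactionMatrix(x, [f"m{i}" for i in range(6)], list("abcd")),
            k=1, m=4.0,
        )
        s = model.S[:, 0]
        assert np.ptp(s[:3]) <= 1e-6 and np.ptp(s[3:]) <= 1e-6
        assert s[0] * s[3] < 0  # blocks land on opposite sides

    @pytest.mark.parametrize("seed,shape", [(0, (5, 4)), (1, (6, 5))])
    def test_beats_random_restart_search(self, seed, shape):
        # tiny matrices expose several MM basins; restarts find the best one
        x = random_binary(np.random.default_rng(seed), *shape)
        model = fit_lpca(x, k=1, m=4.0, tol=1e-10, max_iter=5000,
                         n_restarts=30, seed=seed)
        best = brute_force_min_deviance(x, 4.0, seed=seed)
        assert model.deviance <= best + 1e-3

    def test_restarts_never_worse_than_default(self):
        x = random_binary(np.random.default_rng(4), 6, 5)
        default = fit_lpca(x, k=1, m=4.0, tol=1e-10, max_iter=5000)
        restarted = fit_lpca(x, k=1, m=4.0, tol=1e-10, max_iter=5000,
                             n_restarts=10, seed=0)
        assert restarted.deviance <= default.deviance + 1e-12

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        x = random_binary(rng, 12, 9)
        model = fit_lpca(x, k=2, m=4.0)
        perm_rows = rng.permutation(12)
        m_rows = fit_lpca(x[perm_rows], k=2, m=4.0)
        assert np.allclose(m_rows.S, model.S[perm_rows], atol=1e-8)
        perm_cols = rng.permutation(9)
        m_cols = fit_lpca(x[:, perm_cols], k=2, m=4.0)
        assert np.allclose(m_cols.mu, model.mu[perm_cols], atol=1e-8)
        assert np.allclose(m_cols.U, model.U[perm_cols], atol=1e-8)

    def test_refit_is_bit_stable(self):
        x = random_binary(np.random.default_rng(6), 10, 7)
        m1 = fit_lpca(x, k=2, m=4.0)
        m2 = fit_lpca(x, k=2, m=4.0)
        assert (m1.U == m2.U).all() and (m1.S == m2.S).all() and (m1.mu == m2.mu).all()

    def test_sign_convention(self, canonical):
        U = canonical["model"].U
        for j in range(U.shape[1]):
            assert U[np.argmax(np.abs(U[:, j])), j] >= 0

    def test_k_too_large_rejected(self):
        x = random_binary(np.random.default_rng(7), 4, 6)
        with pytest.raises(ValueError):
            fit_lpca(x, k=4)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            fit_lpca(np.ones((4, 3), dtype=int), k=1)

    def test_constant_column_warns_and_stays_finite(self):
        x = random_binary(np.random.default_rng(8), 8, 5)
        x = np.hstack([x, np.ones((8, 1), dtype=int)])
        with pytest.warns(UserWarning, match="constant"):
            model = fit_lpca(x, k=1, m=4.0)
        assert np.isfinite(model.mu).all()
        assert np.abs(model.mu[-1]) <= 40.0 + 1e-9

    def test_partial_eigen_agrees_with_dense(self):
        x = random_binary(np.random.default_rng(9), 20, 15)
        dense = fit_lpca(x, k=2, m=4.0)
        partial = fit_lpca(x, k=2, m=4.0, partial_eigen=True)
        assert partial.deviance == pytest.approx(dense.deviance, abs=1e-6)


class TestScores:
    def test_indicator_column_gives_theta_minus_mu(self):
        rng = np.random.default_rng(10)
        x = random_binary(rng, 5, 4)
        r = 2
        U = np.zeros((4, 1))
        U[r, 0] = 1.0
        mu = rng.normal(size=4)
        model = LPCAModel(mu=mu, U=U, S=np.zeros((5, 1)), m=4.0,
                          deviance_trace=[0.0], converged=True, n_iter=0)
        theta = 4.0 * (2.0 * x - 1.0)
        out = scores(model, x)
        assert np.allclose(out[:, 0], theta[:, r] - mu[r], atol=0)

    def test_training_scores_reproduced(self, canonical):
        model, X = canonical["model"], canonical["matrix"]
        assert np.abs(scores(model, X) - model.S).max() <= 1e-10

    def test_heldout_identical_row_scores_identically(self, canonical):
        model, X = canonical["model"], canonical["matrix"]
        held = X.values[[3]]
        assert np.allclose(scores(model, held)[0], model.S[3], atol=1e-12)


class TestFittedProbabilities:
    def test_in_open_unit_interval(self, canonical):
        p = fitted_probabilities(canonical["model"], canonical["matrix"])
        assert (p > 0).all() and (p < 1).all()

    def test_reconstruction_improves_with_m(self):
        x = random_binary(np.random.default_rng(12), 6, 4)
        errs = []
        for m in (2.0, 4.0, 8.0):
            model = fit_lpca(x, k=3, m=m, tol=1e-10, max_iter=5000)
            errs.append(np.abs(fitted_probabilities(model, x) - x).mean())
        assert errs[0] > errs[1] > errs[2]


class TestSelectM:
    def test_singleton_grid(self):
        x = random_binary(np.random.default_rng(13), 8, 6)
        chosen, table = select_m(x, k=1, grid=[4.0])
        assert chosen == 4.0 and len(table) == 1

    def test_matches_independent_fits(self):
        x = random_binary(np.random.default_rng(14), 10, 8)
        chosen, table = select_m(x, k=2, grid=[2.0, 4.0, 8.0])
        independent = {m: fit_lpca(x, k=2, m=m).deviance for m in (2.0, 4.0, 8.0)}
        assert chosen == min(independent, key=independent.get)
        for m, dev in independent.items():
            assert table.loc[table.m == m, "deviance"].iloc[0] == pytest.approx(dev, abs=0)

    def test_auto_mode_records_selection(self):
        x = random_binary(np.random.default_rng(15), 8, 6)
        model = fit_lpca(x, k=1, m="auto", m_grid=(2.0, 4.0))
        assert model.m in (2.0, 4.0)
        assert model.m_selection == "auto-grid"

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_m(np.eye(4, dtype=int), k=1, grid=[])
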