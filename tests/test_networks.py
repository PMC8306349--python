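"""Rank-based latent correlation, PSD repair, graphical lasso, CV and fits."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.model_selection import KFold

from _oracles import glasso_oracle, random_correlation
from conftest import make_meal_matrix
from mealnet.networks import (
    cv_select_lambda,
    edge_set,
    fit_meal_network,
    fit_trimester_networks,
    graphical_lasso,
    kendall_to_latent,
    nearest_psd,
    partial_correlations,
    rank_correlation_matrix,
    spearman_to_latent,
)
from mealnet.synthetic import generate_sparse_precision, thresholds_from_prevalence


class TestSineTransforms:
    def test_closed_form_values(self):
        assert spearman_to_latent(0.0) == 0.0
        assert spearman_to_latent(1.0) == pytest.approx(1.0, abs=1e-15)
        assert spearman_to_latent(0.5) == pytest.approx(2 * np.sin(np.pi / 12), abs=1e-15)
        assert kendall_to_latent(0.0) == 0.0
        assert kendall_to_latent(1.0) == pytest.approx(1.0, abs=1e-15)
        assert kendall_to_latent(0.5) == pytest.approx(np.sin(np.pi / 4), abs=1e-15)

    @given(st.floats(min_value=-1, max_value=1))
    @settings(max_examples=100, deadline=None)
    def test_odd_and_bounded(self, x):
        for f in (spearman_to_latent, kendall_to_latent):
            assert f(-x) == pytest.approx(-f(x), abs=1e-14)
            assert abs(f(x)) <= 1 + 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            spearman_to_latent(1.2)
        with pytest.raises(ValueError):
            kendall_to_latent(-1.2)


class TestNearestPsd:
    def test_noop_on_psd(self):
        eye = np.eye(4)
        out, adj = nearest_psd(eye)
        np.testing.assert_array_equal(out, eye)
        assert adj == 0.0
        r = np.array([[1, 0.999], [0.999, 1.0]])
        out, adj = nearest_psd(r)
        np.testing.assert_array_equal(out, r)

    def test_repairs_negative_eigenvalue(self):
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(r)[0] < 0
        out, adj = nearest_psd(r)
        assert np.linalg.eigvalsh(out)[0] >= 1e-6 - 1e-12
        np.testing.assert_allclose(np.diag(out), 1.0, atol=1e-12)
        assert adj > 0


class TestRankCorrelation:
    def test_perfect_concordance_and_diagonal(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0) ** 3 + 1])
        est = rank_correlation_matrix(x, "spearman")
        assert est.matrix[0, 1] == pytest.approx(1.0, abs=1e-4)
        np.testing.assert_allclose(np.diag(est.matrix), 1.0)
        est_k = rank_correlation_matrix(x, "kendall")
        assert est_k.matrix[0, 1] == pytest.approx(1.0, abs=1e-4)

    def test_matches_brute_force_on_toy_matrix(self):
        x = np.array([[0.0, 1.0, 2.0], [3.0, 2.0, 0.0], [1.0, 0.0, 4.0],
                      [2.0, 5.0, 1.0], [0.0, 2.0, 3.0], [4.0, 1.0, 0.0]])
        est = rank_correlation_matrix(x, "spearman")
        assert not est.psd_repaired  # entries are the raw sine-transformed ranks
        for i in range(3):
            for j in range(i + 1, 3):
                rho = stats.spearmanr(x[:, i], x[:, j]).statistic
                assert est.matrix[i, j] == pytest.approx(2 * np.sin(np.pi * rho / 6), abs=1e-12)
        est_k = rank_correlation_matrix(x, "kendall")
        for i in range(3):
            for j in range(i + 1, 3):
                tau = stats.kendalltau(x[:, i], x[:, j]).statistic
                assert est_k.matrix[i, j] == pytest.approx(np.sin(np.pi * tau / 2), abs=1e-12)

    def test_zero_variance_column_named(self):
        x = np.column_stack([np.arange(6.0), np.full(6, 2.0)])
        with pytest.raises(ValueError, match="v1"):
            rank_correlation_matrix(x)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(size=(40, 5))
        base = rank_correlation_matrix(x).matrix
        y = x.copy()
        y[:, 0] = np.expm1(y[:, 0])       # strictly increasing
        y[:, 3] = y[:, 3] * 7.0 + 2.0
        np.testing.assert_allclose(rank_correlation_matrix(y).matrix, base, atol=1e-12)

    def test_latent_recovery_without_zero_inflation(self):
        """With no hurdle, sine-transformed Spearman recovers the latent correlation."""
        rng = np.random.default_rng(8)
        theta, sigma, _ = generate_sparse_precision(8, 0.25, (0.25, 0.45), rng)
        z = rng.multivariate_normal(np.zeros(8), sigma, size=5000)
        x = np.exp(0.5 * z)  # monotone marginal transform
        est = rank_correlation_matrix(x)
        assert np.max(np.abs(est.matrix - sigma)) < 0.05


class TestGraphicalLasso:
    def test_zero_penalty_is_mle(self):
        r = random_correlation(4, np.random.default_rng(0))
        np.testing.assert_allclose(graphical_lasso(r, 0.0), np.linalg.inv(r), atol=1e-6)

    def test_matches_direct_dual_solve(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.choice([3, 4])
            r = random_correlation(int(p), rng)
            for lam in (0.05, 0.2):
                ours = graphical_lasso(r, lam, tol=1e-8, max_iter=2000)
                oracle = glasso_oracle(r, lam)
                assert np.max(np.abs(ours - oracle)) < 1e-4

    def test_full_penalty_gives_diagonal(self):
        rng = np.random.default_rng(2)
        r = random_correlation(5, rng)
        lam = np.abs(r - np.eye(5)).max()
        theta = graphical_lasso(r, lam + 1e-6)
        assert edge_set(theta) == set()

    def test_non_psd_input_rejected(self):
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="not PSD"):
            graphical_lasso(r, 0.1)

    def test_sparsity_monotone_in_lambda(self):
        rng = np.random.default_rng(3)
        r = random_correlation(8, rng)
        counts = [len(edge_set(graphical_lasso(r, lam)))
                  for lam in (0.01, 0.05, 0.1, 0.2, 0.4, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_partial_correlation_bounds_and_symmetry(self):
        rng = np.random.default_rng(5)
        theta = graphical_lasso(random_correlation(6, rng), 0.05)
        pc = partial_correlations(theta)
        np.testing.assert_allclose(pc, pc.T)
        np.testing.assert_allclose(np.diag(pc), 1.0)
        off = pc[~np.eye(6, dtype=bool)]
        assert np.all(np.abs(off) < 1.0)


class TestCrossValidation:
    def _matrix(self, n=120, p=5, seed=0):
        rng = np.random.default_rng(seed)
        theta, sigma, _ = generate_sparse_precision(p, 0.3, (0.3, 0.45), rng)
        z = rng.multivariate_normal(np.zeros(p), sigma, size=n)
        x = np.where(z > -0.3, np.exp(z), 0.0)
        return make_meal_matrix(x)

    def test_singleton_grid_returned(self):
        m = self._matrix()
        assert cv_select_lambda(m, grid=[0.2], seed=1).selected == 0.2

    def test_matches_independent_fold_loop(self):
        """The selected penalty equals a from-scratch re-implementation of the fold loop."""
        m = self._matrix(n=150, seed=2)
        grid = [0.02, 0.05, 0.1, 0.3, 0.6]
        res = cv_select_lambda(m, grid=grid, k=5, seed=7)
        x = m.values
        scores = np.zeros((5, len(grid)))
        for f, (tr, te) in enumerate(KFold(5, shuffle=True, random_state=7).split(np.arange(len(x)))):
            r_tr = rank_correlation_matrix(x.iloc[tr], allow_constant=True).matrix
            r_te = rank_correlation_matrix(x.iloc[te], allow_constant=True).matrix
            for gi, lam in enumerate(grid):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    th = graphical_lasso(r_tr, lam, tol=1e-4, max_iter=100)
                scores[f, gi] = np.linalg.slogdet(th)[1] - np.trace(r_te @ th)
        mean = scores.mean(axis=0)
        best = max(range(len(grid)), key=lambda i: (mean[i], grid[i]))
        assert res.selected == grid[best]
        np.testing.assert_allclose(res.mean_loglik, mean, atol=1e-9)

    def test_tie_prefers_larger_lambda(self):
        # duplicate grid entries force an exact tie in mean likelihood
        m = self._matrix(n=60, seed=3)
        res = cv_select_lambda(m, grid=[0.3, 0.3 + 0.0], seed=1)
        assert res.selected == 0.3

    def test_one_se_rule_is_sparser(self):
        m = self._matrix(n=150, seed=6)
        a = cv_select_lambda(m, seed=2)
        b = cv_select_lambda(m, seed=2, rule="1se")
        assert b.selected >= a.selected
        with pytest.raises(ValueError, match="rule"):
            cv_select_lambda(m, rule="median")

    def test_too_few_meals(self):
        m = self._matrix(n=4)
        with pytest.raises(ValueError, match="at least"):
            cv_select_lambda(m, k=5)


class TestFitMealNetwork:
    def _planted_matrix(self, theta_sparsity, n, seed, p=10):
        rng = np.random.default_rng(seed)
        theta, sigma, edges = generate_sparse_precision(p, theta_sparsity, (0.3, 0.45), rng)
        z = rng.multivariate_normal(np.zeros(p), sigma, size=n)
        x = np.where(z > -0.5, np.exp(0.6 * z + 3.0), 0.0)
        return make_meal_matrix(x), edges

    def test_independent_model_yields_no_edges(self):
        """Diagonal planted precision: no edges at a penalty above the noise level,
        and only weak spurious partials at the CV-selected penalty."""
        m, _ = self._planted_matrix(0.0, 800, seed=10)
        fixed = fit_meal_network(m, seed=1, lam=0.15)
        assert len(fixed.edges) == 0
        cv_model = fit_meal_network(m, seed=1)
        off = cv_model.partial_corr[~np.eye(len(cv_model.groups), dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_deterministic_given_seed(self):
        m, _ = self._planted_matrix(0.2, 300, seed=11)
        a = fit_meal_network(m, seed=5)
        b = fit_meal_network(m, seed=5)
        assert a.lam == b.lam and a.edges == b.edges
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_two_block_model_separates_blocks(self):
        """Planted two-block precision: no cross-block edges at large n (<=1 false)."""
        rng = np.random.default_rng(12)
        p = 8
        t1, s1, _ = generate_sparse_precision(4, 0.6, (0.3, 0.45), rng)
        t2, s2, _ = generate_sparse_precision(4, 0.6, (0.3, 0.45), rng)
        sigma = np.block([[s1, np.zeros((4, 4))], [np.zeros((4, 4)), s2]])
        z = rng.multivariate_normal(np.zeros(p), sigma, size=4000)
        x = np.where(z > -0.8, np.exp(z), 0.0)
        model = fit_meal_network(make_meal_matrix(x), seed=2, lam=0.2)
        cross = [(i, j) for i, j in model.edges
                 if (int(model.groups[i][1:]) < 4) != (int(model.groups[j][1:]) < 4)]
        assert len(cross) <= 1
        within = [(i, j) for i, j in model.edges if (i, j) not in cross]
        assert len(within) >= 2

    def test_save_load_roundtrip(self, tmp_path):
        m, _ = self._planted_matrix(0.2, 200, seed=13)
        model = fit_meal_network(m, meal_type="breakfast", stratum="low", seed=1)
        model.save(tmp_path / "model")
        from mealnet.networks import NetworkModel
        loaded = NetworkModel.load(tmp_path / "model")
        assert loaded.groups == model.groups
        assert loaded.edges == model.edges
        assert loaded.lam == model.lam


class TestTrimesterNetworks:
    def _matrix_with_trimesters(self, seed=20, n=300):
        rng = np.random.default_rng(seed)
        theta, sigma, _ = generate_sparse_precision(6, 0.3, (0.3, 0.45), rng)
        z = rng.multivariate_normal(np.zeros(6), sigma, size=n)
        x = np.where(z > -0.8, np.exp(z), 0.0)
        m = make_meal_matrix(x)
        m.keys["trimester"] = np.tile([1, 2, 3], n // 3 + 1)[:n]
        return m

    def test_identical_data_reproduces_pooled_edges(self):
        m = self._matrix_with_trimesters()
        pooled = fit_meal_network(m, seed=1)
        m.keys["trimester"] = 1
        (tri,) = fit_trimester_networks(m, pooled, min_meals=10)
        assert tri.edges == pooled.edges
        assert tri.lam == pooled.lam

    def test_group_below_threshold_absent_in_trimester(self):
        m = self._matrix_with_trimesters()
        # suppress group g0 in trimester 2 only
        mask = (m.keys["trimester"] == 2).to_numpy()
        m.values.loc[mask, "g0"] = 0.0
        pooled = fit_meal_network(m, seed=1)
        tris = fit_trimester_networks(m, pooled, min_meals=10)
        t2 = next(t for t in tris if t.trimester == 2)
        assert "g0" not in t2.groups
        t1 = next(t for t in tris if t.trimester == 1)
        assert "g0" in t1.groups

    def test_sparse_trimester_skipped_with_warning(self):
        m = self._matrix_with_trimesters(n=60)
        m.keys["trimester"] = np.array([1] * 50 + [2] * 10)
        pooled = fit_meal_network(m, seed=1)
        with pytest.warns(UserWarning, match="trimester 2"):
            tris = fit_trimester_networks(m, pooled, min_meals=20)
        assert [t.trimester for t in tris] == [1]
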