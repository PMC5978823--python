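import numpy as np
import pandas as pd
import pytest

from conftest import make_rating_matrix
from idnet import (
    LagNetworkEstimator,
    SyntheticSpec,
    build_lag_pairs,
    estimate_network,
    fit_node_lasso,
    simulate,
)
from oracles import ols_coefficients, soft_threshold


def _rm_with_observed_days(day_numbers, values):
    """Matrix observed only on the given 1-based day numbers."""
    n = max(day_numbers)
    p = np.asarray(values).shape[1]
    vals = np.full((n, p), np.nan)
    for row, d in enumerate(day_numbers):
        vals[d - 1] = values[row]
    return make_rating_matrix(vals)


class TestBuildLagPairs:
    def test_calendar_vs_sequential_enumeration(self):
        rng = np.random.default_rng(0)
        rm = _rm_with_observed_days([1, 2, 3, 5], rng.standard_normal((4, 2)))
        cal = build_lag_pairs(rm, policy="calendar")
        seq = build_lag_pairs(rm, policy="sequential")
        def day_nums(ps):
            return [(a.day, b.day) for a, b in ps.pairs]
        assert day_nums(cal) == [(1, 2), (2, 3)]
        assert day_nums(seq) == [(1, 2), (2, 3), (3, 5)]

    def test_fully_observed_gives_n_minus_1_pairs(self):
        rng = np.random.default_rng(1)
        rm = make_rating_matrix(rng.standard_normal((12, 3)))
        for policy in ("calendar", "sequential"):
            assert build_lag_pairs(rm, policy=policy).n_pairs == 11

    def test_diary_shaped_mask_breaks_runs(self, diary_like):
        _, rm = diary_like
        ps = build_lag_pairs(rm, policy="calendar")
        observed_days = int(rm.day_complete.sum())
        assert ps.n_pairs < observed_days - 1  # gaps cost pairs

    def test_pairs_standardized(self):
        rng = np.random.default_rng(2)
        rm = make_rating_matrix(rng.standard_normal((40, 3)) * 7 + 3)
        ps = build_lag_pairs(rm)
        np.testing.assert_allclose(ps.X.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(ps.X.std(axis=0), 1, atol=1e-10)
        np.testing.assert_allclose(ps.Y.std(axis=0), 1, atol=1e-10)

    def test_no_pairs_errors(self):
        vals = np.full((5, 2), np.nan)
        vals[0] = [1.0, 2.0]
        vals[2] = [2.0, 1.0]
        rm = make_rating_matrix(vals)
        with pytest.raises(ValueError, match="no usable"):
            build_lag_pairs(rm, policy="calendar")


class TestFitNodeLasso:
    def test_single_predictor_matches_soft_threshold(self):
        rng = np.random.default_rng(3)
        n = 200
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        r = float(x @ y / n)
        path = fit_node_lasso(y, x[:, None])
        for lam, beta in zip(path.lambdas, path.coefficients[:, 0]):
            assert beta == pytest.approx(soft_threshold(r, lam), abs=1e-8)

    def test_small_lambda_limit_matches_ols(self):
        rng = np.random.default_rng(4)
        n, p = 300, 5
        X = rng.standard_normal((n, p))
        y = X @ np.array([0.5, -0.3, 0.2, 0.0, 0.1]) + 0.5 * rng.standard_normal(n)
        X = (X - X.mean(0)) / X.std(0)
        y = (y - y.mean()) / y.std()
        path = fit_node_lasso(y, X, lambda_min_ratio=1e-6)
        np.testing.assert_allclose(
            path.coefficients[-1], ols_coefficients(X, y), atol=1e-4
        )

    def test_orthogonal_outcome_selects_empty_model(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 4))
        y = np.zeros(100)
        path = fit_node_lasso(y, X)
        assert np.count_nonzero(path.chosen_coefficients) == 0

    def test_path_invariants(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((150, 6))
        y = X @ rng.normal(0, 0.4, 6) + rng.standard_normal(150)
        X = (X - X.mean(0)) / X.std(0)
        y = (y - y.mean()) / y.std()
        path = fit_node_lasso(y, X)
        assert np.count_nonzero(path.coefficients[0]) == 0  # largest lambda
        nnz = np.count_nonzero(path.coefficients, axis=1)
        # sparsity non-increasing in lambda up to coordinate-descent slack
        assert (np.diff(nnz) >= -1).all()
        assert path.chosen_index == int(np.argmin(path.aicc))


class TestEstimateNetwork:
    def test_two_node_var_true_edges_recovered(self):
        """True lag-1 effects are always retained with the right sign; any
        spurious edge is strongly shrunk relative to the planted 0.4-0.6
        coefficients (AICc tuning is liberal, not sign-blind)."""
        A = np.array([[0.6, 0.0], [0.4, 0.5]])
        true_hits = 0
        for seed in range(20):
            rm = simulate(SyntheticSpec(p=2, A=A, n_days=301, seed=seed))
            net = estimate_network(rm)
            support = net.W != 0
            true_hits += bool(support[1, 0] and support[0, 0] and support[1, 1]
                              and net.W[1, 0] > 0)
            assert abs(net.W[0, 1]) < 0.2  # spurious edge, if kept, is shrunk
        assert true_hits >= 18

    def test_shape_is_p_squared(self, diary_network):
        assert diary_network["net"].W.size == 484

    def test_item_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        rm = simulate(SyntheticSpec(
            p=4, A=np.array([[0.5, 0.3, 0, 0], [0, 0.4, 0, 0],
                             [0, 0, 0.3, -0.3], [0.2, 0, 0, 0.4]]),
            n_days=150, seed=1))
        net = estimate_network(rm)
        perm = rng.permutation(4)
        rm_p = make_rating_matrix(rm.values[:, perm],
                                  observed=rm.observed[:, perm],
                                  items=[rm.items[i] for i in perm])
        net_p = estimate_network(rm_p)
        np.testing.assert_allclose(net_p.W, net.W[np.ix_(perm, perm)], atol=1e-10)

    def test_positive_scaling_invariance(self):
        rm = simulate(SyntheticSpec(
            p=3, A=np.array([[0.5, 0.3, 0], [0, 0.4, 0], [0, 0.2, 0.3]]),
            n_days=120, seed=2))
        net = estimate_network(rm)
        scaled = rm.values.copy()
        scaled[:, 1] *= 37.5
        net_s = estimate_network(make_rating_matrix(
            scaled, observed=rm.observed, items=rm.items))
        np.testing.assert_allclose(net_s.W, net.W, atol=1e-10)

    def test_retained_edges_bounded_by_bivariate_correlation(self):
        rm = simulate(SyntheticSpec(
            p=4, A=np.array([[0.5, 0.4, 0, 0], [0, 0.5, 0.3, 0],
                             [0, 0, 0.5, 0], [0, 0, 0, 0.5]]),
            n_days=400, seed=3))
        est = LagNetworkEstimator().fit(rm)
        ps = est.pairs_
        for i in range(4):
            for j in range(4):
                w = est.W_[i, j]
                if w != 0:
                    r = np.corrcoef(ps.X[:, i], ps.Y[:, j])[0, 1]
                    assert abs(w) <= abs(r) + 0.05

    def test_single_item_rejected(self):
        rm = make_rating_matrix(np.random.default_rng(0).standard_normal((20, 1)))
        with pytest.raises(ValueError, match="at least 2 items"):
            estimate_network(rm)
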