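import numpy as np
import pandas as pd
import pytest

from connstats import (
    EdgewiseMarginalModel,
    build_design,
    cluster_robust_se,
    edgewise_pvalues,
    fit_marginal,
    wild_bootstrap_null,
)
from connstats.design import RankDeficiencyError


def _sandwich_loop_oracle(X, resid, cluster_ids, small_sample="CR0"):
    """Literal loop-based sum over clusters (independent of the implementation)."""
    n, p = X.shape
    resid = resid.reshape(n, -1)
    A = np.linalg.inv(X.T @ X)
    groups = sorted(set(cluster_ids))
    out = np.empty((p, resid.shape[1]))
    for e in range(resid.shape[1]):
        meat = np.zeros((p, p))
        for g in groups:
            idx = [k for k in range(n) if cluster_ids[k] == g]
            s = np.zeros(p)
            for k in idx:
                s += X[k] * resid[k, e]
            meat += np.outer(s, s)
        V = A @ meat @ A
        if small_sample == "CR1":
            V *= len(groups) / (len(groups) - 1) * (n - 1) / (n - p)
        out[:, e] = np.sqrt(np.diag(V))
    return out


class TestDesign:
    def test_intercept_only(self):
        cohort = pd.DataFrame({"site_id": [0, 0, 1, 1], "y": [1.0, 2, 3, 4]})
        d = build_design(cohort, [], None)
        assert np.array_equal(d.X, np.ones((4, 1)))
        assert d.coef_names == ["intercept"]

    def test_binary_coefficient_is_group_difference(self, rng):
        g = rng.integers(0, 2, 60)
        y = 0.7 * g + rng.standard_normal(60)
        cohort = pd.DataFrame({"stimulant": g, "site_id": rng.integers(0, 4, 60)})
        d = build_design(cohort, [], "stimulant")
        beta, _ = fit_marginal(y, d.X)
        assert beta[d.interest_index, 0] == pytest.approx(
            y[g == 1].mean() - y[g == 0].mean()
        )

    def test_categorical_expansion_and_cluster_choice(self):
        cohort = pd.DataFrame(
            {
                "stimulant": [0, 1, 0, 1],
                "scanner": ["a", "b", "c", "a"],
                "site_id": [0, 0, 1, 1],
                "family_id": [0, 1, 2, 3],
            }
        )
        d = build_design(cohort, ["scanner"], "stimulant", cluster="family_id")
        assert d.coef_names == ["intercept", "stimulant", "scanner_b", "scanner_c"]
        assert np.array_equal(d.cluster_ids, cohort["family_id"])

    def test_duplicated_covariate_rejected_by_name(self):
        cohort = pd.DataFrame(
            {
                "stimulant": [0, 1, 0, 1, 1],
                "fd_copy": [0.0, 1, 0, 1, 1],
                "site_id": [0, 0, 1, 1, 1],
            }
        )
        with pytest.raises(RankDeficiencyError, match="fd_copy"):
            build_design(cohort, ["fd_copy"], "stimulant")


class TestMarginalFit:
    def test_hand_solved_normal_equations(self):
        # x = 0..4, y = [1,2,2,4,4]: slope = Sxy/Sxx = 8/10, intercept = 1.0
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        y = np.array([1.0, 2, 2, 4, 4])
        beta, resid = fit_marginal(y, X)
        assert beta[:, 0] == pytest.approx([1.0, 0.8])
        assert resid[:, 0] @ X == pytest.approx([0.0, 0.0], abs=1e-10)

    def test_exact_fit_and_orthogonality(self, rng):
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        y = X @ np.array([2.0, -1.0])
        beta, resid = fit_marginal(y, X)
        assert np.allclose(resid, 0)
        Y = rng.standard_normal((10, 4))
        _, R = fit_marginal(Y, X)
        assert np.max(np.abs(X.T @ R)) < 1e-8 * np.abs(Y).max()

    def test_permutation_invariance(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
        Y = rng.standard_normal((20, 3))
        perm = rng.permutation(20)
        b1, _ = fit_marginal(Y, X)
        b2, _ = fit_marginal(Y[perm], X[perm])
        assert np.allclose(b1, b2)

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError, match="n > p"):
            fit_marginal(rng.standard_normal(3), rng.standard_normal((3, 3)))


class TestClusterRobustSE:
    def test_singleton_clusters_reduce_to_hc0(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Y = rng.standard_normal((n, 2))
        _, resid = fit_marginal(Y, X)
        se = cluster_robust_se(X, resid, np.arange(n), "CR0")
        A = np.linalg.inv(X.T @ X)
        for e in range(2):
            V = A @ (X.T * resid[:, e] ** 2) @ X @ A
            assert np.allclose(se[:, e], np.sqrt(np.diag(V)))

    def test_three_cluster_toy_matches_loop_oracle(self, rng):
        X = np.column_stack([np.ones(9), rng.standard_normal(9)])
        Y = rng.standard_normal((9, 3))
        cl = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        _, resid = fit_marginal(Y, X)
        for ss in ("CR0", "CR1"):
            got = cluster_robust_se(X, resid, cl, ss)
            want = _sandwich_loop_oracle(X, resid, cl, ss)
            assert np.max(np.abs(got - want)) < 1e-10

    def test_matches_statsmodels_cluster_covariance(self, rng):
        import statsmodels.api as sm

        n = 50
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        cl = rng.integers(0, 6, n)
        _, resid = fit_marginal(y, X)
        res_c = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": cl, "use_correction": True}
        )
        res_n = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": cl, "use_correction": False}
        )
        assert np.allclose(cluster_robust_se(X, resid, cl, "CR1")[:, 0], res_c.bse)
        assert np.allclose(cluster_robust_se(X, resid, cl, "CR0")[:, 0], res_n.bse)

    def test_robust_close_to_classical_under_independence(self, rng):
        # homoskedastic independent data: robust and classical SE agree
        n = 2000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [0.5, 1.0] + rng.standard_normal(n)
        _, resid = fit_marginal(y, X)
        robust = cluster_robust_se(X, resid, np.arange(n), "CR0")[1, 0]
        sigma2 = (resid**2).sum() / (n - 2)
        classical = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert 0.9 < robust / classical < 1.1

    def test_single_cluster_rejected(self, rng):
        X = np.column_stack([np.ones(5), rng.standard_normal(5)])
        _, resid = fit_marginal(rng.standard_normal(5), X)
        with pytest.raises(ValueError, match="at least 2 clusters"):
            cluster_robust_se(X, resid, np.zeros(5))


class TestWildBootstrap:
    def test_identity_weights_reproduce_observed_t(self, rng):
        # v_g = +1 for all clusters makes y* identical to y, so t* must equal
        # the observed cluster-robust t of the full model
        n, m = 40, 6
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.standard_normal(n)])
        Y = rng.standard_normal((n, m))
        cl = rng.integers(0, 5, n)
        W = np.ones((1, 5))
        null_t = wild_bootstrap_null(Y, X, 1, cl, B=1, weights=W)
        beta, resid = fit_marginal(Y, X)
        se = cluster_robust_se(X, resid, cl)
        assert np.allclose(null_t[0], beta[1] / se[1])

    def test_seed_determinism_and_shape(self, rng):
        n, m = 30, 4
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        Y = rng.standard_normal((n, m))
        cl = rng.integers(0, 4, n)
        a = wild_bootstrap_null(Y, X, 1, cl, B=25, seed=3)
        b = wild_bootstrap_null(Y, X, 1, cl, B=25, seed=3)
        c = wild_bootstrap_null(Y, X, 1, cl, B=25, seed=4)
        assert a.shape == (25, m)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_shared_signs_across_edges(self, rng):
        # within a replicate every edge must see the same cluster signs:
        # computing edges jointly or one at a time with the same forced
        # weights must agree exactly
        n = 30
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        Y = rng.standard_normal((n, 3))
        cl = rng.integers(0, 4, n)
        W = rng.integers(0, 2, (5, 4)) * 2.0 - 1.0
        joint = wild_bootstrap_null(Y, X, 1, cl, B=5, weights=W)
        for e in range(3):
            single = wild_bootstrap_null(Y[:, [e]], X, 1, cl, B=5, weights=W)
            assert np.allclose(joint[:, e], single[:, 0])

    def test_null_t_centered_under_global_null(self, null_cohort_data):
        _, design, Y = null_cohort_data
        null_t = wild_bootstrap_null(
            Y[:, :100], design.X, design.interest_index, design.cluster_ids,
            B=500, seed=8,
        )
        z = null_t.mean() / (null_t.std(ddof=1) / np.sqrt(null_t.size))
        # cross-edge and cross-replicate dependence inflates the naive SE;
        # a generous 10x allowance still catches any systematic bias
        assert abs(null_t.mean()) < 10 * null_t.std(ddof=1) / np.sqrt(null_t.size)

    def test_restricted_rank_deficiency_rejected(self, rng):
        n = 20
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, x])  # removing col 1 leaves dup of nothing
        X[:, 2] = 1.0  # restricted design (cols 0,2) is rank 1
        with pytest.raises(ValueError, match="rank deficient"):
            wild_bootstrap_null(rng.standard_normal(n), X, 1, rng.integers(0, 3, n), B=2)


class TestBootstrapPValues:
    def test_counting_conventions_on_toys(self):
        null = np.array([[1.0], [2.5], [0.5], [3.0]])
        assert edgewise_pvalues(np.array([2.0]), null)[0] == 0.5
        assert edgewise_pvalues(np.array([0.0]), null)[0] == 1.0
        assert edgewise_pvalues(np.array([4.0]), null)[0] == 0.0
        assert edgewise_pvalues(np.array([4.0]), null, "plus-one")[0] == pytest.approx(
            1 / 5
        )

    def test_estimator_end_to_end(self, null_cohort_data):
        _, design, Y = null_cohort_data
        model = EdgewiseMarginalModel(B=50, random_state=1).fit(design, Y[:, :60])
        assert model.coef_.shape == (60,)
        assert model.null_t_.shape == (50, 60)
        assert np.all((model.pvalues_ >= 0) & (model.pvalues_ <= 1))
        assert np.allclose(model.t_, model.coef_ / model.se_)
        # sklearn param plumbing
        params = model.get_params()
        assert params["B"] == 50
        clone_like = EdgewiseMarginalModel(**params)
        assert clone_like.random_state == 1
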