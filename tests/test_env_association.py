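"""Environment association battery: VIF, PCA, KW, GLM, logistic, dbRDA, Mantel."""

import numpy as np
import pandas as pd
import pytest

from ecodiverge.env_association import (
    dbrda, glm_on_axis, kw_species_test, logistic_species, mantel_test,
    pca_env, vif_prune,
)


def gauss_frame(n=60, p=5, seed=0, corr=0.0, names=None):
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p))
    if corr:
        common = rng.standard_normal((n, 1))
        Z = np.sqrt(1 - corr) * Z + np.sqrt(corr) * common
    names = names or [f"v{i}" for i in range(p)]
    return pd.DataFrame(Z, columns=names)


class TestVifPrune:
    def test_orthogonal_columns_kept(self):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.standard_normal((40, 5)))
        Q = Q - Q.mean(axis=0)
        Q, _ = np.linalg.qr(Q)                 # orthogonal after centring
        env = pd.DataFrame(Q[:, :4], columns=list("abcd"))
        keep, log = vif_prune(env)
        assert keep == list("abcd")
        assert (log["vif"] < 1.5).all()

    def test_duplicated_column_dropped_once(self):
        env = gauss_frame(30, 3)
        env["dup"] = env["v0"]
        keep, _ = vif_prune(env)
        assert ("v0" in keep) != ("dup" in keep)
        assert len(keep) == 3

    def test_matches_explicit_regression_oracle(self):
        env = gauss_frame(50, 5, seed=3, corr=0.5)
        X = env.to_numpy()
        import statsmodels.api as sm
        vifs = []
        for j in range(5):
            others = sm.add_constant(np.delete(X, j, axis=1))
            r2 = sm.OLS(X[:, j], others).fit().rsquared
            vifs.append(1 / (1 - r2))
        from ecodiverge.env_association import _vif
        np.testing.assert_allclose(_vif(X), vifs, rtol=1e-8)

    def test_terminates_with_all_vif_below_threshold(self):
        env = gauss_frame(50, 6, seed=9, corr=0.9)
        env["mix"] = env.iloc[:, :3].sum(axis=1) + 0.01 * env["v4"]
        keep, log = vif_prune(env, threshold=5.0)
        from ecodiverge.env_association import _vif
        assert (_vif(env[keep].to_numpy()) < 5.0).all()
        assert len(log) <= env.shape[1]

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            vif_prune(gauss_frame(4, 5))


class TestPcaEnv:
    def test_perfectly_correlated_pair_gives_single_axis(self):
        x = np.random.default_rng(0).standard_normal(30)
        env = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_env(env)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_loadings_orthonormal_and_percents_sum_to_100(self):
        env = gauss_frame(40, 4, seed=5, corr=0.3)
        res = pca_env(env)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-9)
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_eigenvalues_match_direct_decomposition(self):
        env = gauss_frame(35, 4, seed=6, corr=0.4)
        res = pca_env(env)
        Z = (env - env.mean()) / env.std(ddof=1)
        evals = np.sort(np.linalg.eigvalsh(np.corrcoef(Z.T)))[::-1]
        np.testing.assert_allclose(
            res.percent_variance, 100 * evals / evals.sum(), atol=1e-8)

    def test_constant_column_named_in_error(self):
        env = gauss_frame(20, 2)
        env["flat"] = 3.0
        with pytest.raises(ValueError, match="flat"):
            pca_env(env)


class TestKruskalWallis:
    def test_perfect_separation_closed_form(self):
        # two groups of 10 with disjoint supports: H = 12*500/420
        x = np.concatenate([np.arange(10), 100 + np.arange(10)]).astype(float)
        scores = pd.DataFrame({"PC1": x})
        labels = ["a"] * 10 + ["b"] * 10
        res = kw_species_test(scores, labels)
        assert res.loc["PC1", "statistic"] == pytest.approx(14.2857, abs=1e-3)
        assert res.loc["PC1", "df"] == 1

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(200):
            scores = pd.DataFrame({"PC1": rng.standard_normal(30)})
            labels = rng.permutation(["a"] * 15 + ["b"] * 15)
            ps.append(kw_species_test(scores, labels).loc["PC1", "p"])
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 1e-3

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            kw_species_test(pd.DataFrame({"PC1": [1.0, 2.0]}), ["a", "a"])

    def test_all_tied_warns_p_one(self):
        scores = pd.DataFrame({"PC1": np.ones(10)})
        with pytest.warns(UserWarning, match="tied"):
            res = kw_species_test(scores, ["a"] * 5 + ["b"] * 5)
        assert res.loc["PC1", "p"] == 1.0


class TestGlmOnAxis:
    def test_variable_identical_to_axis(self):
        ax = pd.DataFrame({"a1": np.arange(10.0), "a2": np.zeros(10) + np.random.default_rng(1).standard_normal(10)})
        env = pd.DataFrame({"v": ax["a1"]})
        res = glm_on_axis(env, ax)
        assert res.loc["v", "adj_r2"] == pytest.approx(1.0)
        assert res.loc["v", "a1_p"] < 1e-10

    def test_orthogonal_variable_has_null_slope(self):
        rng = np.random.default_rng(2)
        ax = pd.DataFrame(rng.standard_normal((200, 2)), columns=["a1", "a2"])
        env = pd.DataFrame({"v": rng.standard_normal(200)})
        res = glm_on_axis(env, ax)
        assert abs(res.loc["v", "a1_estimate"]) < 0.2
        assert res.loc["v", "p"] > 0.01 or res.loc["v", "adj_r2"] < 0.05

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        ax = pd.DataFrame(rng.standard_normal((25, 2)), columns=["a1", "a2"])
        env = pd.DataFrame({"v": 1.5 * ax["a1"] - 0.5 * ax["a2"]
                            + rng.standard_normal(25)})
        res = glm_on_axis(env, ax)
        D = np.column_stack([np.ones(25), ax.to_numpy()])
        beta = np.linalg.solve(D.T @ D, D.T @ env["v"].to_numpy())
        assert res.loc["v", "a1_estimate"] == pytest.approx(beta[1])
        assert res.loc["v", "a2_estimate"] == pytest.approx(beta[2])


class TestLogistic:
    def test_null_labels_rarely_significant(self):
        rng = np.random.default_rng(4)
        n_sig = 0
        for r in range(60):
            X = pd.DataFrame(rng.standard_normal((40, 2)),
                             columns=["x1", "x2"])
            y = rng.permutation(["a"] * 20 + ["b"] * 20)
            res = logistic_species(X, y)
            n_sig += int((res.loc[["x1", "x2"], "p"] < 0.05).any())
        assert n_sig <= 12       # ~2 * nominal 5% per test, two predictors

    def test_planted_axis_has_largest_z(self):
        rng = np.random.default_rng(5)
        pc1 = rng.standard_normal(80)
        X = pd.DataFrame({"PC1": pc1,
                          "PC2": rng.standard_normal(80),
                          "PC3": rng.standard_normal(80)})
        y = np.where(pc1 + 0.8 * rng.standard_normal(80) > 0, "a", "b")
        res = logistic_species(X, y)
        z = res.loc[["PC1", "PC2", "PC3"], "z"].abs()
        assert z.idxmax() == "PC1"
        assert res.loc["PC1", "p"] < 0.01

    def test_duplicated_predictor_errors(self):
        X = gauss_frame(30, 2)
        X["dup"] = X["v0"]
        with pytest.raises(ValueError, match="rank"):
            logistic_species(X, ["a"] * 15 + ["b"] * 15)

    def test_perfect_separation_flagged(self):
        x = np.concatenate([-1 - np.arange(10.0), 1 + np.arange(10.0)])
        X = pd.DataFrame({"x": x})
        res = logistic_species(X, ["a"] * 10 + ["b"] * 10)
        assert bool(res["separation"].iloc[0])


class TestDbrda:
    def _data(self, n=30, seed=0, link=1.0, noise=0.0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["e1", "e2", "e3"])
        B = rng.standard_normal((3, 2))
        Y = link * (X.to_numpy() @ B) + noise * rng.standard_normal((n, 2))
        return pd.DataFrame(Y, columns=["PC1", "PC2"]), X

    def test_exact_linear_response_fully_constrained(self):
        Y, X = self._data(noise=0.0)
        res = dbrda(Y, X, n_perm=99, seed=1)
        assert res.r_squared == pytest.approx(1.0)
        assert res.unconstrained_inertia == pytest.approx(0.0, abs=1e-9)
        assert (res.anova["p"] < 0.05).all()

    def test_inertia_conservation(self):
        Y, X = self._data(seed=3, noise=1.0)
        res = dbrda(Y, X, n_perm=49, seed=2)
        assert (res.constrained_inertia + res.unconstrained_inertia
                == pytest.approx(res.total_inertia, abs=1e-9))
        assert res.adj_r_squared <= res.r_squared

    def test_null_predictors_give_uniform_p(self):
        rng = np.random.default_rng(6)
        ps = []
        for r in range(60):
            Y = pd.DataFrame(rng.standard_normal((25, 2)))
            X = pd.DataFrame(rng.standard_normal((25, 2)), columns=["a", "b"])
            res = dbrda(Y, X, n_perm=99, seed=r)
            ps.extend(res.anova["p"].tolist())
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 1e-3

    def test_tiny_case_matches_explicit_projection_oracle(self):
        """6x2 response, 1 predictor: RDA recomputed by hand algebra."""
        rng = np.random.default_rng(9)
        Y = pd.DataFrame(rng.standard_normal((6, 2)), columns=["PC1", "PC2"])
        X = pd.DataFrame({"e": rng.standard_normal(6)})
        res = dbrda(Y, X, n_perm=0, seed=0)
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        x = X["e"].to_numpy()
        x = (x - x.mean()) / x.std(ddof=1)
        beta = (x @ Yc) / (x @ x)
        Yhat = np.outer(x, beta)
        assert res.constrained_inertia == pytest.approx(
            (Yhat ** 2).sum() / 5)
        evals = np.linalg.svd(Yhat, compute_uv=False) ** 2 / 5
        np.testing.assert_allclose(res.eigenvalues, evals[:len(res.eigenvalues)])

    def test_too_many_predictors_rejected(self):
        Y, X = self._data(n=4)
        with pytest.raises(ValueError, match="predictors"):
            dbrda(Y.iloc[:3], X.iloc[:3], n_perm=0)

    def test_permutation_reproducible(self):
        Y, X = self._data(seed=5, noise=1.0)
        a = dbrda(Y, X, n_perm=99, seed=7)
        b = dbrda(Y, X, n_perm=99, seed=7)
        pd.testing.assert_frame_equal(a.anova, b.anova)


class TestMantel:
    def _dist(self, n, seed):
        rng = np.random.default_rng(seed)
        p = rng.standard_normal((n, 2))
        d = np.linalg.norm(p[:, None] - p[None, :], axis=2)
        return d

    def test_self_correlation_is_one(self):
        d = self._dist(8, 0)
        r, p = mantel_test(d, d, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_affine_invariance(self):
        d = self._dist(8, 2)
        r, _ = mantel_test(d, 2 * d + 3 - 3 * np.eye(8), n_perm=9, seed=1)
        assert r == pytest.approx(1.0)

    def test_independent_matrices_null_p(self):
        from scipy.stats import kstest
        ps = [mantel_test(self._dist(12, s), self._dist(12, 1000 + s),
                          n_perm=199, seed=s)[1] for s in range(40)]
        assert kstest(ps, "uniform").pvalue > 1e-3

    def test_constant_matrix_errors(self):
        d = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(d, d * 0, n_perm=9)
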