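"""ABC machinery: summary statistics, transforms, rejection, GLM, summaries."""

import numpy as np
import pandas as pd
import pytest

from ecodiverge.abc_infer import (
    ReferenceTable, abc_reject, boxcox_pls, glm_adjust, model_choice,
    posterior_summarize, summary_stats,
)

from conftest import make_dataset


class TestSummaryStats:
    def test_monomorphic_dataset(self):
        a = np.full((6, 2, 2), 100, dtype=np.int32)
        ds = make_dataset(a, ["A"] * 3 + ["B"] * 3,
                          ["s1"] * 3 + ["s2"] * 3)
        with pytest.warns(UserWarning, match="F_ST undefined"):
            s = summary_stats(ds)
        assert s["K_A"] == 1 and s["He_A"] == 0 and s["V_A"] == 0
        assert s["dmu2_A_B"] == 0 and s["fst_A_B"] == 0

    def test_fixed_difference_pair(self):
        a = np.concatenate([np.full((3, 1, 2), 100, dtype=np.int32),
                            np.full((3, 1, 2), 110, dtype=np.int32)])
        ds = make_dataset(a, ["A"] * 3 + ["B"] * 3,
                          ["s1"] * 3 + ["s2"] * 3)
        s = summary_stats(ds)
        assert s["dmu2_A_B"] == pytest.approx(100.0)
        assert s["shared_A_B"] == 0.0
        assert s["fst_A_B"] == pytest.approx(1.0)

    def test_against_per_definition_oracle(self, random_dataset):
        s = summary_stats(random_dataset)
        ds = random_dataset
        for pop in ("A", "B"):
            sub = ds.alleles[ds.population == pop]
            ks, hs, vs, gw = [], [], [], []
            for l in range(ds.n_loci):
                c = sub[:, l, :].reshape(-1).astype(float)
                vals, cnt = np.unique(c, return_counts=True)
                p = cnt / cnt.sum()
                ks.append(len(vals))
                hs.append(1 - (p ** 2).sum())
                vs.append(np.var(c, ddof=1))
                gw.append(len(vals) / (vals.max() - vals.min() + 1))
            assert s[f"K_{pop}"] == pytest.approx(np.mean(ks))
            assert s[f"He_{pop}"] == pytest.approx(np.mean(hs))
            assert s[f"V_{pop}"] == pytest.approx(np.mean(vs))
            assert s[f"GW_{pop}"] == pytest.approx(np.mean(gw))
        # pair statistics
        da, db = ds.alleles[:5], ds.alleles[5:]
        dmu2, shared = [], []
        for l in range(ds.n_loci):
            ca = da[:, l, :].reshape(-1).astype(float)
            cb = db[:, l, :].reshape(-1).astype(float)
            dmu2.append((ca.mean() - cb.mean()) ** 2)
            sa, sb = set(ca), set(cb)
            shared.append(len(sa & sb) / len(sa | sb))
        assert s["dmu2_A_B"] == pytest.approx(np.mean(dmu2))
        assert s["shared_A_B"] == pytest.approx(np.mean(shared))

    def test_single_population_rejected(self):
        ds = make_dataset(np.ones((3, 1, 2), dtype=np.int32), ["A"] * 3)
        with pytest.raises(ValueError):
            summary_stats(ds)


def _linear_reference(n=600, seed=0, noise=0.0):
    """Reference whose statistic is an exact linear map of one parameter."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 10, n)
    stats = pd.DataFrame({
        "s1": 2.0 * theta + 1.0 + noise * rng.standard_normal(n),
        "s2": rng.standard_normal(n),        # pure noise statistic
    })
    tab = pd.concat(
        [pd.DataFrame({"model": "M", "t2": theta}), stats], axis=1)
    return ReferenceTable(tab, ["t2"], ["s1", "s2"]), theta


class TestBoxcoxPls:
    def test_planted_linear_map_recovered(self):
        from scipy.stats import spearmanr
        # statistic exactly linear in the parameter: the single component
        # is a monotone (Box-Cox) image of it - rank correlation is exact
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 10, 600)
        tab = pd.DataFrame({"model": "M", "t2": theta,
                            "s1": 2.0 * theta + 1.0})
        ref = ReferenceTable(tab, ["t2"], ["s1"])
        scores, obs_s, tf = boxcox_pls(ref, pd.Series({"s1": 11.0}),
                                       n_components=1)
        assert abs(spearmanr(scores[:, 0], theta).statistic) > 0.999
        assert abs(np.corrcoef(scores[:, 0], theta)[0, 1]) > 0.99
        # with an extra pure-noise statistic the recovery stays near-exact
        ref2, theta2 = _linear_reference()
        scores2, _, _ = boxcox_pls(ref2, pd.Series({"s1": 11.0, "s2": 0.0}),
                                   n_components=1)
        assert abs(np.corrcoef(scores2[:, 0], theta2)[0, 1]) > 0.99

    def test_observed_equal_to_reference_row(self):
        ref, _ = _linear_reference()
        row = ref.table.iloc[37]
        obs = pd.Series({"s1": row["s1"], "s2": row["s2"]})
        scores, obs_s, _ = boxcox_pls(ref, obs, n_components=2)
        np.testing.assert_allclose(obs_s, scores[37], atol=1e-8)

    def test_too_many_components(self):
        ref, _ = _linear_reference()
        with pytest.raises(ValueError, match="n_components"):
            boxcox_pls(ref, pd.Series({"s1": 0.0, "s2": 0.0}), n_components=5)

    def test_constant_statistic_dropped(self):
        ref, _ = _linear_reference()
        ref.table["s3"] = 7.0
        ref.stat_cols.append("s3")
        obs = pd.Series({"s1": 1.0, "s2": 0.0, "s3": 7.0})
        with pytest.warns(UserWarning, match="constant"):
            scores, obs_s, tf = boxcox_pls(ref, obs, n_components=2)
        assert "s3" in tf.dropped


class TestAbcReject:
    def test_keep_all_is_identity(self):
        x = np.random.default_rng(1).standard_normal((50, 3))
        idx = abc_reject(x, np.zeros(3), n_keep=50)
        assert sorted(idx) == list(range(50))

    def test_exact_match_retained_first(self):
        x = np.random.default_rng(2).standard_normal((50, 3))
        idx = abc_reject(x, x[13], n_keep=5)
        assert idx[0] == 13

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((100, 4))
        obs = rng.standard_normal(4)
        idx = abc_reject(x, obs, n_keep=20)
        d = np.linalg.norm(x - obs, axis=1)
        expect = np.argsort(d, kind="stable")[:20]
        np.testing.assert_array_equal(idx, expect)

    def test_invalid_n_keep(self):
        x = np.zeros((5, 2))
        with pytest.raises(ValueError):
            abc_reject(x, np.zeros(2), 0)
        with pytest.raises(ValueError):
            abc_reject(x, np.zeros(2), 6)


class TestGlmAdjust:
    def test_noiseless_linear_map_recovers_parameter(self):
        ref, theta = _linear_reference(noise=0.05)
        obs = pd.Series({"s1": 2.0 * 4.2 + 1.0, "s2": 0.0})
        scores, obs_s, _ = boxcox_pls(ref, obs, n_components=2)
        idx = abc_reject(scores, obs_s, n_keep=300)
        post = glm_adjust(ref.table.iloc[idx][["t2"]], scores[idx], obs_s,
                          n_total=len(scores))
        summ = posterior_summarize(post.params["t2"].to_numpy(), post.weights)
        assert summ["mode"] == pytest.approx(4.2, abs=0.1)   # 1% of range

    def test_density_monotone_in_distance(self):
        ref, _ = _linear_reference(noise=0.05)
        scores, obs_near, _ = boxcox_pls(
            ref, pd.Series({"s1": 9.0, "s2": 0.0}), n_components=2)
        idx = abc_reject(scores, obs_near, n_keep=300)
        params = ref.table.iloc[idx][["t2"]]
        near = glm_adjust(params, scores[idx], obs_near, n_total=len(scores))
        far = glm_adjust(params, scores[idx],
                         obs_near + 10 * scores.std(axis=0),
                         n_total=len(scores))
        assert far.log_marginal_density < near.log_marginal_density

    def test_two_identical_models_split_evenly(self):
        ref, _ = _linear_reference()
        obs = pd.Series({"s1": 9.0, "s2": 0.0})
        scores, obs_s, _ = boxcox_pls(ref, obs, n_components=2)
        idx = abc_reject(scores, obs_s, n_keep=300)
        p = glm_adjust(ref.table.iloc[idx][["t2"]], scores[idx], obs_s,
                       n_total=len(scores))
        res = model_choice({"A": p.log_marginal_density,
                            "B": p.log_marginal_density})
        assert res.relative_density["A"] == pytest.approx(50.0)
        assert res.bayes_factors.loc["A", "B"] == pytest.approx(1.0)


class TestModelChoice:
    def test_ratio_arithmetic(self):
        res = model_choice({"A": np.log(3.0), "B": np.log(1.0)})
        assert res.relative_density["A"] == pytest.approx(75.0)
        assert res.relative_density["B"] == pytest.approx(25.0)
        assert res.bayes_factors.loc["A", "B"] == pytest.approx(3.0)
        assert res.bayes_factors.loc["B", "A"] == pytest.approx(1 / 3)
        assert res.best_model == "A"
        assert sum(res.relative_density.values()) == pytest.approx(100.0,
                                                                   abs=0.01)

    def test_single_model_errors(self):
        with pytest.raises(ValueError):
            model_choice({"A": 0.0})

    def test_all_zero_densities_error(self):
        with pytest.raises(ValueError, match="zero"):
            model_choice({"A": -np.inf, "B": -np.inf})


class TestPosteriorSummaries:
    def test_point_mass(self):
        s = posterior_summarize(np.full(200, 3.3))
        assert s["mode"] == s["median"] == 3.3
        assert s["hpd95"] == (3.3, 3.3)

    def test_symmetric_sample_mode_near_median(self):
        x = np.random.default_rng(5).normal(2.0, 1.0, 20_000)
        s = posterior_summarize(x)
        assert abs(s["mode"] - s["median"]) < 0.1

    def test_beta_mode_analytic(self):
        x = np.random.default_rng(6).beta(2, 5, 100_000)
        s = posterior_summarize(x)
        assert s["mode"] == pytest.approx(0.2, abs=0.02)   # (a-1)/(a+b-2)
        lo, hi = s["hpd95"]
        inside = ((x >= lo) & (x <= hi)).mean()
        assert inside == pytest.approx(0.95, abs=0.01)
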