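"""Diversity statistics and hierarchical AMOVA."""

import itertools

import numpy as np
import pytest

from ecodiverge.genodata import MISSING
from ecodiverge.popgen_stats import (
    amova, amova_from_components, diversity_table, pairwise_fst, unbiased_he,
)

from conftest import make_dataset


class TestUnbiasedHe:
    def test_small_sample_correction_formula(self):
        assert unbiased_he(0.5, 10) == pytest.approx(20 / 19 * 0.5)

    def test_zero_he_stays_zero(self):
        assert unbiased_he(0.0, 7) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            unbiased_he(0.5, 0)
        with pytest.raises(ValueError):
            unbiased_he(1.2, 5)


class TestDiversityTable:
    def test_all_heterozygotes_closed_form(self):
        # one locus, two alleles at 0.5/0.5, every individual heterozygous
        a = np.array([[[1, 2]], [[1, 2]], [[1, 2]], [[1, 2]]], dtype=np.int32)
        ds = make_dataset(a, ["A"] * 4)
        row = diversity_table(ds).loc["A"]
        assert row.Ne == pytest.approx(2.0)
        assert row.He == pytest.approx(0.5)
        assert row.Ho == pytest.approx(1.0)
        assert row.F == pytest.approx(-1.0)

    def test_monomorphic_dataset(self):
        ds = make_dataset(np.full((5, 2, 2), 3, dtype=np.int32), ["A"] * 5)
        row = diversity_table(ds).loc["A"]
        assert row.Na == 1 and row.Ne == 1
        assert row.I == 0 and row.He == 0
        assert np.isnan(row.F)          # no polymorphic locus

    def test_against_per_formula_oracle(self, random_dataset):
        """Every column re-derived independently from allele frequencies."""
        ds = random_dataset
        tab = diversity_table(ds)
        for pop in ("A", "B"):
            sub = ds.alleles[ds.population == pop]
            na, ne, sh, ho, he, uhe, fs = [], [], [], [], [], [], []
            for l in range(ds.n_loci):
                copies = sub[:, l, :].reshape(-1)
                vals, cnt = np.unique(copies, return_counts=True)
                p = cnt / cnt.sum()
                na.append(len(vals))
                ne.append(1 / (p ** 2).sum())
                sh.append(-(p * np.log(p)).sum())
                h = (sub[:, l, 0] != sub[:, l, 1]).mean()
                ho.append(h)
                e = 1 - (p ** 2).sum()
                he.append(e)
                n = len(sub)
                uhe.append(2 * n / (2 * n - 1) * e)
                if e > 0:
                    fs.append(1 - h / e)
            row = tab.loc[pop]
            assert row.Na == pytest.approx(np.mean(na))
            assert row.Ne == pytest.approx(np.mean(ne))
            assert row.I == pytest.approx(np.mean(sh))
            assert row.Ho == pytest.approx(np.mean(ho))
            assert row.He == pytest.approx(np.mean(he))
            assert row.uHe == pytest.approx(np.mean(uhe))
            assert row.F == pytest.approx(np.mean(fs))
            # internal identities: He = 1 - 1/Ne per locus carries to means
            assert np.allclose(np.asarray(he), 1 - 1 / np.asarray(ne))
            assert np.allclose(np.asarray(uhe) / np.asarray(he),
                               2 * len(sub) / (2 * len(sub) - 1))


class TestAmovaFromComponents:
    def test_arithmetic(self):
        pct, f_ct, f_sc, f_st = amova_from_components(2.0, 1.0, 1.0)
        assert pct["among_species"] == pytest.approx(50.0)
        assert f_ct == pytest.approx(0.5)
        assert f_sc == pytest.approx(0.5)
        assert f_st == pytest.approx(0.75)

    def test_within_only(self):
        pct, f_ct, f_sc, f_st = amova_from_components(0.0, 0.0, 5.0)
        assert pct["within_pops"] == 100.0
        assert f_ct == f_sc == f_st == 0.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            amova_from_components(0, 0, 0)


class TestAmova:
    def test_complete_fixation_between_species(self, two_pop_fixed):
        res = amova(two_pop_fixed, n_perm=0)
        assert res.f_st == pytest.approx(1.0)
        assert res.percent["within_pops"] == pytest.approx(0.0)

    def test_null_case_identical_populations(self):
        # four pops with identical genotype compositions; the among-group
        # components estimate near zero (slightly negative, the standard
        # finite-sample artifact, reported raw)
        block = np.array([[1, 2], [1, 1], [2, 2], [1, 2],
                          [3, 1], [2, 3], [3, 3], [1, 2]], dtype=np.int32)
        a = np.tile(block[:, None, :], (4, 1, 1)).reshape(32, 1, 2)
        pops = sum([[p] * 8 for p in "ABCD"], [])
        species = ["sp1"] * 16 + ["sp2"] * 16
        ds = make_dataset(a, pops, species)
        res = amova(ds, n_perm=199, seed=1)
        sc = res.components["sigma_c"]
        assert abs(res.components["sigma_a"]) < 0.15 * sc
        assert abs(res.components["sigma_b"]) < 0.15 * sc
        assert res.p_values["among_species"] > 0.5

    def test_sums_of_squares_match_pairwise_distance_oracle(self, random_dataset):
        """SS terms recomputed from explicit pairwise copy distances."""
        ds = random_dataset
        res = amova(ds, n_perm=0)

        def ss_of(copies):
            d = sum(1.0 for x, y in itertools.combinations(copies, 2)
                    if x != y)
            return d / len(copies)

        ss_t = ss_w = 0.0
        for l in range(ds.n_loci):
            all_copies = ds.alleles[:, l, :].reshape(-1)
            ss_t += ss_of(all_copies)
            for pop in ("A", "B"):
                ss_w += ss_of(ds.alleles[ds.population == pop, l, :].reshape(-1))
        assert res.ss["total"] == pytest.approx(ss_t)
        assert res.ss["within_pops"] == pytest.approx(ss_w)

    def test_df_structure_for_study_design(self, study_fixture):
        ds = study_fixture.dataset
        res = amova(ds, n_perm=0)
        assert res.df == {"among_species": 1,
                          "among_pops_within_species": 3,
                          "within_pops": 157, "total": 161}
        assert (res.df["among_species"]
                + res.df["among_pops_within_species"]
                + res.df["within_pops"]) == res.df["total"]
        assert sum(res.percent.values()) == pytest.approx(100.0, abs=0.01)

    def test_permutation_p_values_on_grid_and_reproducible(self, study_fixture):
        ds = study_fixture.dataset
        r1 = amova(ds, n_perm=99, seed=5)
        r2 = amova(ds, n_perm=99, seed=5)
        assert r1.p_values == r2.p_values
        for p in r1.p_values.values():
            assert (p * 100) == pytest.approx(round(p * 100))
            assert 1 / 100 <= p <= 1.0


class TestPairwiseFst:
    def test_fixed_difference_pair(self, two_pop_fixed):
        m = pairwise_fst(two_pop_fixed)
        assert m.loc["A", "B"] == pytest.approx(1.0)
        assert m.loc["A", "A"] == 0.0

    def test_identical_pair_is_near_zero(self):
        # identical compositions: estimate ~ -1/(n-1), approaching 0 with n
        block = np.array([[1, 2], [1, 1], [2, 2], [1, 2]], dtype=np.int32)
        big = np.tile(block[:, None, :], (8, 1, 1)).reshape(32, 1, 2)
        a = np.concatenate([big, big])
        ds = make_dataset(a, ["A"] * 32 + ["B"] * 32)
        m = pairwise_fst(ds)
        assert abs(m.loc["A", "B"]) < 0.03

    def test_two_allele_case_against_variance_partition(self):
        """2-pop, 2-allele F_ST re-derived from the component algebra."""
        a = np.array([[[1, 1]], [[1, 2]], [[1, 1]],
                      [[2, 2]], [[2, 2]], [[1, 2]]], dtype=np.int32)
        ds = make_dataset(a, ["A"] * 3 + ["B"] * 3)
        m = pairwise_fst(ds)
        copies_a = a[:3].reshape(-1)
        copies_b = a[3:].reshape(-1)
        na, nb = 6.0, 6.0
        n = na + nb

        def ss(c):
            _, cnt = np.unique(c, return_counts=True)
            return 0.5 * (len(c) - (cnt.astype(float) ** 2).sum() / len(c))

        ssw = ss(copies_a) + ss(copies_b)
        sst = ss(np.concatenate([copies_a, copies_b]))
        sw = ssw / (n - 2)
        nc = n - (na ** 2 + nb ** 2) / n
        sa = ((sst - ssw) - sw) / nc
        assert m.loc["A", "B"] == pytest.approx(sa / (sa + sw))
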