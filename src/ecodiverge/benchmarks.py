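"""Standardised validation runs used by the acceptance checks.

Each function runs one self-contained benchmark of the pipeline at a
reduced but statistically meaningful scale and returns plain dictionaries
of computed quantities.  The printed study inputs (per-population expected
heterozygosities and sample sizes; AMOVA variance components for the
total, neutral and positive-outlier locus sets) are data inputs to the
worked-example checks, not expected values: the checks recompute the
derived quantities from them through the package's own arithmetic.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import abc_infer, coalsim, env_association, outlier_scan
from . import popgen_stats, structure_dapc, synthdata

#: per-population (He, N) inputs of the study's diversity table
STUDY_HE_N = {
    "wutai": (0.340, 10),
    "wulu_pla": (0.231, 19),
    "wulu_tas": (0.259, 22),
    "lanyu": (0.253, 15),
    "taroko": (0.317, 15),
}

#: AMOVA variance components (among-species, among-pops-within, within)
STUDY_VARIANCE_COMPONENTS = {
    "total": (3.669, 1.423, 2.666),
    "neutral": (2.331, 1.198, 2.316),
    "positive": (1.325, 0.139, 0.0),
}


def table_checks() -> dict:
    """Worked-example arithmetic: uHe per population and F statistics."""
    out = {}
    for pop, (he, n) in STUDY_HE_N.items():
        out[f"uhe_{pop}"] = round(popgen_stats.unbiased_he(he, n), 3)
    for name, (sa, sb, sc) in STUDY_VARIANCE_COMPONENTS.items():
        pct, f_ct, f_sc, f_st = popgen_stats.amova_from_components(sa, sb, sc)
        out[f"fct_{name}"] = f_ct
        out[f"fsc_{name}"] = f_sc
        out[f"fst_{name}"] = f_st
        out[f"pct_among_species_{name}"] = pct["among_species"]
        out[f"pct_among_pops_{name}"] = pct["among_pops_within_species"]
        out[f"pct_within_{name}"] = pct["within_pops"]
    return out


# ---------------------------------------------------------------------------
# scenario recovery (ABC)
# ---------------------------------------------------------------------------

#: generating parameters of the pseudo-observed datasets
PSEUDO_OBS = dict(n1=800.0, n2=800.0, n_anc=800.0, t2=1.1e5, mu=3e-4)


def scenario_recovery(seed: int, n_per_model: int = 5000, n_reps: int = 10,
                      n_loci: int = 15, n_keep: int = 1000) -> dict:
    """Isolation-vs-gene-flow recovery on the distinguishable extremes.

    Builds one {CI, CM} reference table and scores `n_reps` pseudo-observed
    datasets per generating scenario (CI with m = 0; CM with m = 0.1).
    Returns per-scenario win counts (highest relative density assigned to
    the generating model).
    """
    seed = int(seed) % (2 ** 31)
    ref = abc_infer.build_reference_table(["CI", "CM"], n_per_model,
                                          n_loci, seed=seed)
    wins = {"CI": 0, "CM": 0}
    for gen, m in (("CI", 0.0), ("CM", 0.1)):
        for r in range(n_reps):
            spec = coalsim.ScenarioSpec(model=gen, t1=0.0, m12=m, m21=m,
                                        **PSEUDO_OBS)
            ds = coalsim.simulate_dataset(
                spec, n_loci, seed=(seed + 77_001 + 1000 * r
                                    + (0 if gen == "CI" else 500)) % (2 ** 31))
            res = abc_infer.abc_analysis(ref, abc_infer.summary_stats(ds),
                                         n_keep=n_keep, summarize_best=False)
            wins[gen] += int(res.best_model == gen)
    return {"ci_recovery_wins": wins["CI"], "cm_recovery_wins": wins["CM"],
            "n_reps": n_reps}


def am_sc_distinguishability(seed: int, n_per_model: int = 3000,
                             n_reps: int = 5, n_loci: int = 15) -> dict:
    """Ancestral-migration vs secondary-contact recovery at t1 << t2, m large."""
    seed = int(seed) % (2 ** 31)
    base = coalsim.ScenarioSpec()
    ref = abc_infer.build_reference_table(["AM", "SC"], n_per_model,
                                          n_loci, seed=seed + 13)
    wins = {"AM": 0, "SC": 0}
    for gen in ("AM", "SC"):
        for r in range(n_reps):
            spec = coalsim.ScenarioSpec(model=gen, t1=0.15 * PSEUDO_OBS["t2"],
                                        m12=0.1, m21=0.1, **PSEUDO_OBS)
            ds = coalsim.simulate_dataset(
                spec, n_loci, seed=(seed + 88_001 + 1000 * r
                                    + (0 if gen == "AM" else 500)) % (2 ** 31))
            res = abc_infer.abc_analysis(ref, abc_infer.summary_stats(ds),
                                         n_keep=600, summarize_best=False)
            wins[gen] += int(res.best_model == gen)
    return {"am_recovery_wins": wins["AM"], "sc_recovery_wins": wins["SC"],
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# simulator calibration
# ---------------------------------------------------------------------------

def smm_calibration(seed: int, n_loci: int = 8000, n_copies: int = 50,
                    n_diploid: float = 1000.0, mu: float = 5e-4) -> dict:
    """Single-deme strict-SMM check: mean allele-size variance vs theta/2."""
    seed = int(seed) % (2 ** 31)
    spec = coalsim.ScenarioSpec(
        model="CI", t2=0.0, t1=0.0, n_anc=n_diploid, mu=mu,
        samples=(("p1", "sp", 0, n_copies // 2),))
    ds = coalsim.simulate_dataset(spec, n_loci, seed)
    v = np.array([
        np.var(ds.alleles[:, l, :].reshape(-1).astype(float), ddof=1)
        for l in range(n_loci)])
    expected = 2.0 * n_diploid * mu
    return {"mean_variance": float(v.mean()), "expected": expected,
            "ratio": float(v.mean() / expected), "n_loci": n_loci}


def scenario_equivalence(seed: int, n_reps: int = 1000) -> dict:
    """Degenerate-window scenarios match complete isolation.

    Two layers: (a) with shared seeds the degenerate scenarios produce
    bit-identical datasets to CI; (b) with independent seeds, two-sample
    KS tests on the between-deme F_ST distribution do not reject at
    alpha = 0.01.
    """
    seed = int(seed) % (2 ** 31)
    small = (("a", "sp1", 0, 8), ("b", "sp2", 1, 8))
    base = dict(n1=400.0, n2=400.0, n_anc=400.0, t2=4e4, mu=5e-4,
                samples=small)
    variants = {
        "am_t1_eq_t2": coalsim.ScenarioSpec(model="AM", t1=4e4, m12=0.1,
                                            m21=0.1, **base),
        "sc_t1_zero": coalsim.ScenarioSpec(model="SC", t1=0.0, m12=0.1,
                                           m21=0.1, **base),
        "cm_m_zero": coalsim.ScenarioSpec(model="CM", t1=0.0, m12=0.0,
                                          m21=0.0, **base),
    }
    ci = coalsim.ScenarioSpec(model="CI", t1=0.0, **base)

    out = {}
    # (a) bit-identity under shared seeds
    for name, spec in variants.items():
        a = coalsim.simulate_dataset(ci, 5, seed + 5)
        b = coalsim.simulate_dataset(spec, 5, seed + 5)
        out[f"identical_{name}"] = bool(np.array_equal(a.alleles, b.alleles))
    # (b) distributional KS with independent seed streams
    def fst_sample(spec, offset):
        vals = np.empty(n_reps)
        for r in range(n_reps):
            ds = coalsim.simulate_dataset(spec, 3,
                                          (seed + offset + r) % (2 ** 31))
            vals[r] = abc_infer.summary_stats(ds)["fst_a_b"]
        return vals

    ci_vals = fst_sample(ci, 10_000)
    for i, (name, spec) in enumerate(variants.items()):
        vals = fst_sample(spec, 20_000 + 10_000 * i)
        out[f"ks_p_{name}"] = float(sps.ks_2samp(ci_vals, vals).pvalue)
    return out


# ---------------------------------------------------------------------------
# outlier scan
# ---------------------------------------------------------------------------

def outlier_benchmark(seed: int, n_neutral: int = 50, n_pops: int = 5,
                      n_copies: int = 40, fst: float = 0.05,
                      iterations: int = 2500, thinning: int = 5,
                      burn_in: int = 500) -> dict:
    """Neutral false-positive count and planted-outlier recovery.

    Neutral loci follow a multinomial island model (population frequencies
    Dirichlet-dispersed around ancestral ones at the target F_ST); one
    extra locus carries fixed differences between two population groups.
    """
    seed = int(seed) % (2 ** 31)
    rng = np.random.default_rng(seed)
    theta = 1.0 / fst - 1.0
    names, counts = [], []
    for i in range(n_neutral):
        p = rng.dirichlet(np.full(5, 2.0))
        mat = np.zeros((n_pops, 5), dtype=np.int64)
        for j in range(n_pops):
            mat[j] = rng.multinomial(n_copies, rng.dirichlet(theta * p))
        names.append(f"neutral{i:02d}")
        counts.append(mat)
    planted = np.zeros((n_pops, 2), dtype=np.int64)
    planted[: n_pops // 2 + 1, 0] = n_copies
    planted[n_pops // 2 + 1:, 1] = n_copies
    names.append("planted")
    counts.append(planted)
    pops = [f"pop{j}" for j in range(n_pops)]
    chain = outlier_scan.fit_outlier_scan(
        (names, pops, counts), iterations=iterations, thinning=thinning,
        burn_in=burn_in, seed=seed + 1)
    report = outlier_scan.classify_outliers(chain)
    tab = report.table
    neutral_po = tab.loc[tab.index != "planted", "PO"]
    return {
        "neutral_loci_above_po10": int((neutral_po > 10).sum()),
        "planted_is_top": int(tab["PO"].idxmax() == "planted"),
        "planted_mean_alpha": float(tab.loc["planted", "mean_alpha"]),
        "planted_flagged_positive": int("planted" in report.positive),
    }


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def clustering_benchmark(seed: int, n_loci: int = 12, n_per_deme: int = 15,
                         n_runs: int = 10, burn_in: int = 200,
                         iterations: int = 500) -> dict:
    """Two-deme fixture: membership accuracy, Evanno best K, DAPC accuracy."""
    seed = int(seed) % (2 ** 31)
    spec = coalsim.ScenarioSpec(
        model="CI", n1=400, n2=400, n_anc=400, t2=8e4, t1=0, mu=4e-4,
        samples=(("a", "sp1", 0, n_per_deme), ("b", "sp2", 1, n_per_deme)))
    ds = coalsim.simulate_dataset(spec, n_loci, seed)
    fst = float(popgen_stats.pairwise_fst(ds).iloc[0, 1])

    runs_k2 = [structure_dapc.admixture_mcmc(
        ds, 2, burn_in=burn_in, iterations=iterations,
        seed=(seed + 300 + r) % (2 ** 31)) for r in range(n_runs)]
    _, _, mean_q = structure_dapc.align_runs(runs_k2)
    own = np.where(np.asarray(ds.species) == "sp1", 0, 1)
    q_own = mean_q[np.arange(len(own)), own]
    if q_own.mean() < 0.5:
        q_own = 1.0 - q_own
    accuracy = float(q_own.mean())

    runs = list(runs_k2)
    for K in (1, 3, 4):
        for r in range(n_runs):
            runs.append(structure_dapc.admixture_mcmc(
                ds, K, burn_in=burn_in, iterations=iterations,
                seed=(seed + 300 + 1000 * K + r) % (2 ** 31)))
    best_k = structure_dapc.evanno_deltaK(runs).best_k

    dapc = structure_dapc.dapc_fit(ds, "species", n_pcs=2)
    dapc_acc = float((dapc.assignments.to_numpy()
                      == np.asarray(ds.species)).mean())
    return {"fixture_fst": fst, "mean_membership_accuracy": accuracy,
            "evanno_best_k": int(best_k), "dapc_accuracy": dapc_acc}


# ---------------------------------------------------------------------------
# environment association
# ---------------------------------------------------------------------------

def env_benchmark(seed: int, n_fixtures: int = 5, n_null: int = 50,
                  n_perm: int = 99) -> dict:
    """Planted-pattern recovery, dbRDA inertia conservation, null p-values."""
    seed = int(seed) % (2 ** 31)
    hits = 0
    inertia_gap = 0.0
    for i in range(n_fixtures):
        fx = synthdata.make_env_fixture(seed=seed + i)
        occ = fx["occurrences"]
        v = fx["truth"]["variables"]
        pca = env_association.pca_env(occ, v)
        kw = env_association.kw_species_test(pca.scores.iloc[:, :3],
                                             occ["species"])
        raw = env_association.logistic_species(occ[v], occ["species"])
        pcs = env_association.logistic_species(pca.scores.iloc[:, :3],
                                               occ["species"])
        hits += int(
            kw.loc["PC1", "p"] < 0.01
            and (kw.loc[["PC2", "PC3"], "p"] > 0.05).all()
            and (raw.loc[v, "p"] > 0.05).all()
            and pcs.loc["PC1", "p"] < 0.05)
        # inertia conservation on a dbRDA of this fixture
        import pandas as pd
        rng = np.random.default_rng(seed + 900 + i)
        resp = pd.DataFrame(rng.standard_normal((len(occ), 2)),
                            columns=["PC1", "PC2"])
        ordi = env_association.dbrda(resp, occ[v], n_perm=0, seed=0)
        inertia_gap = max(inertia_gap, abs(
            ordi.constrained_inertia + ordi.unconstrained_inertia
            - ordi.total_inertia))
    # null calibration of the type-II permutation p-values
    rng = np.random.default_rng(seed + 4242)
    import pandas as pd
    ps = []
    for r in range(n_null):
        Y = pd.DataFrame(rng.standard_normal((25, 2)))
        X = pd.DataFrame(rng.standard_normal((25, 2)), columns=["a", "b"])
        res = env_association.dbrda(Y, X, n_perm=n_perm,
                                    seed=(seed + r) % (2 ** 31))
        ps.extend(res.anova["p"].tolist())
    ks_p = float(sps.kstest(ps, "uniform").pvalue)
    return {"pattern_hits": hits, "n_fixtures": n_fixtures,
            "max_inertia_gap": float(inertia_gap),
            "null_p_ks_pvalue": ks_p}


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def determinism_check(seed: int) -> dict:
    """Bit-reproducibility of every stochastic stage under a fixed seed."""
    seed = int(seed) % (2 ** 31)
    fx1 = synthdata.make_genotype_fixture(seed=seed)
    fx2 = synthdata.make_genotype_fixture(seed=seed)
    sim_ok = np.array_equal(fx1.dataset.alleles, fx2.dataset.alleles)

    ds = fx1.dataset.subset_loci(sorted(fx1.partition.neutral)[:6])
    a1 = popgen_stats.amova(ds, n_perm=49, seed=seed)
    a2 = popgen_stats.amova(ds, n_perm=49, seed=seed)
    amova_ok = a1.p_values == a2.p_values and a1.f_st == a2.f_st

    r1 = structure_dapc.admixture_mcmc(ds, 2, burn_in=30, iterations=60,
                                       seed=seed)
    r2 = structure_dapc.admixture_mcmc(ds, 2, burn_in=30, iterations=60,
                                       seed=seed)
    mcmc_ok = np.array_equal(r1.Q, r2.Q) and r1.ln_prob == r2.ln_prob

    ref1 = abc_infer.build_reference_table(["CI", "CM"], 100, 4, seed=seed)
    ref2 = abc_infer.build_reference_table(["CI", "CM"], 100, 4, seed=seed)
    obs = abc_infer.summary_stats(ds)
    m1 = abc_infer.abc_analysis(ref1, obs, n_components=4, n_keep=40,
                                summarize_best=False).log_marginal
    m2 = abc_infer.abc_analysis(ref2, obs, n_components=4, n_keep=40,
                                summarize_best=False).log_marginal
    abc_ok = ref1.table.equals(ref2.table) and m1 == m2

    import pandas as pd
    rng = np.random.default_rng(seed)
    Y = pd.DataFrame(rng.standard_normal((20, 2)))
    X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
    d1 = env_association.dbrda(Y, X, n_perm=99, seed=seed).anova
    d2 = env_association.dbrda(Y, X, n_perm=99, seed=seed).anova
    perm_ok = d1.equals(d2)

    return {"simulator": int(sim_ok), "amova_permutations": int(amova_ok),
            "admixture_mcmc": int(mcmc_ok), "abc_pipeline": int(abc_ok),
            "dbrda_permutations": int(perm_ok),
            "all_bit_reproducible": int(sim_ok and amova_ok and mcmc_ok
                                        and abc_ok and perm_ok)}
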