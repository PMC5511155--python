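"""Per-population diversity statistics and hierarchical AMOVA.

Diversity follows the classic per-locus definitions (Na, Ne = 1/sum p^2,
Shannon I, Ho, He = 1 - sum p^2, unbiased He, fixation index F) averaged
across loci with across-locus standard errors.

AMOVA is the gene-copy-level nested analysis of molecular variance: sums of
squares from pairwise copy distances (identity distance by default, squared
allele-size optionally), variance components sigma_a (among species),
sigma_b (among populations within species), sigma_c (within populations),
and the hierarchical fixation indices

    F_CT = sigma_a / sigma_tot
    F_SC = sigma_b / (sigma_b + sigma_c)
    F_ST = (sigma_a + sigma_b) / sigma_tot

with permutation p-values (populations among species; individuals among
populations within species; individuals among all populations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, MicrosatDataset

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def unbiased_he(he: float, n: int) -> float:
    """Small-sample corrected expected heterozygosity, (2n / (2n - 1)) * He."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if not 0.0 <= he <= 1.0:
        raise ValueError("He must lie in [0, 1]")
    return (2.0 * n) / (2.0 * n - 1.0) * he


def _locus_stats(copies: np.ndarray, n_ind: int):
    """Per-locus statistics from the non-missing gene copies of one population.

    ``copies`` is the flat array of scored copies; ``n_ind`` is the number of
    individuals with at least one scored copy (used for the uHe correction).
    """
    vals, cnt = np.unique(copies, return_counts=True)
    p = cnt / copies.size
    na = len(vals)
    sp2 = float((p ** 2).sum())
    ne = 1.0 / sp2
    shannon = float(-(p * np.log(p)).sum())
    he = 1.0 - sp2
    return na, ne, shannon, he, unbiased_he(he, n_ind)


def diversity_table(ds: MicrosatDataset) -> pd.DataFrame:
    """Per-population diversity summary (mean and SE across loci).

    Columns: N, Na, Ne, I, Ho, He, uHe, F plus ``<stat>_se``.  The fixation
    index ``F = 1 - Ho/He`` is averaged over polymorphic loci only
    (monomorphic loci leave it undefined and are logged).
    """
    rows = []
    for pop in ds.populations:
        sub = ds.alleles[ds.pop_indices(pop)]
        per_locus = {k: [] for k in ("Na", "Ne", "I", "Ho", "He", "uHe")}
        f_vals = []
        for l in range(ds.n_loci):
            g = sub[:, l, :]
            scored = (g != MISSING)
            copies = g[scored]
            if copies.size == 0:
                continue
            n_ind = int(scored.any(axis=1).sum())
            na, ne, shannon, he, uhe = _locus_stats(copies, n_ind)
            full = scored.all(axis=1)
            ho = float((g[full, 0] != g[full, 1]).mean()) if full.any() else np.nan
            for k, v in zip(("Na", "Ne", "I", "Ho", "He", "uHe"),
                            (na, ne, shannon, ho, he, uhe)):
                per_locus[k].append(v)
            if he > 0:
                f_vals.append(1.0 - ho / he)
            else:
                log.debug("population %s locus %s monomorphic: F undefined",
                          pop, ds.locus_names[l])
        row = {"population": pop,
               "species": ds.species[ds.pop_indices(pop)[0]],
               "N": int(len(sub))}
        for k, v in per_locus.items():
            v = np.asarray(v, dtype=float)
            row[k] = float(np.nanmean(v))
            row[f"{k}_se"] = float(np.nanstd(v, ddof=1) / np.sqrt(len(v))) \
                if len(v) > 1 else 0.0
        f = np.asarray(f_vals, dtype=float)
        row["F"] = float(np.nanmean(f)) if f.size else np.nan
        row["F_se"] = float(np.nanstd(f, ddof=1) / np.sqrt(f.size)) \
            if f.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Two-level nested AMOVA table with permutation p-values."""

    df: dict
    ss: dict
    components: dict          # sigma_a, sigma_b, sigma_c
    percent: dict
    f_ct: float
    f_sc: float
    f_st: float
    p_values: dict = field(default_factory=dict)
    n_permutations: int = 0
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        lev = ["among_species", "among_pops_within_species", "within_pops"]
        comp = [self.components["sigma_a"], self.components["sigma_b"],
                self.components["sigma_c"]]
        return pd.DataFrame({
            "df": [self.df[k] for k in lev] + [self.df["total"]],
            "SS": [self.ss[k] for k in lev] + [self.ss["total"]],
            "var_comp": comp + [sum(comp)],
            "pct_var": [self.percent[k] for k in lev] + [100.0],
            "F": [self.f_ct, self.f_sc, self.f_st, np.nan],
            "P": [self.p_values.get(k, np.nan) for k in lev] + [np.nan],
        }, index=lev + ["total"])


def amova_from_components(sigma_a: float, sigma_b: float, sigma_c: float):
    """Percent-of-total and fixation indices from given variance components.

    Returns ``(percent dict, F_CT, F_SC, F_ST)``; useful for re-deriving the
    published arithmetic from a printed table.
    """
    tot = sigma_a + sigma_b + sigma_c
    if tot == 0:
        raise ValueError("all variance components are zero")
    pct = {
        "among_species": 100.0 * sigma_a / tot,
        "among_pops_within_species": 100.0 * sigma_b / tot,
        "within_pops": 100.0 * sigma_c / tot,
    }
    f_ct = sigma_a / tot
    f_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else 0.0
    f_st = (sigma_a + sigma_b) / tot
    return pct, f_ct, f_sc, f_st


def _locus_blocks(ds: MicrosatDataset, distance: str):
    """Per-individual allele-count blocks and per-locus state values.

    Returns ``C`` (n_ind x total_states count matrix, missing copies simply
    absent), per-locus column slices, and per-locus state arrays.
    """
    blocks, slices, states_l = [], [], []
    start = 0
    for l in range(ds.n_loci):
        col = ds.alleles[:, l, :]
        obs = col[col != MISSING]
        states = np.unique(obs)
        B = np.zeros((ds.n_individuals, len(states)))
        for si, s in enumerate(states):
            B[:, si] = (col == s).sum(axis=1)
        blocks.append(B)
        slices.append(slice(start, start + len(states)))
        states_l.append(states.astype(float))
        start += len(states)
    return np.concatenate(blocks, axis=1), slices, states_l


def _ss_within(group_counts: np.ndarray, slices, states_l, distance: str) -> float:
    """Sum over loci of the within-set SS for one set of gene copies.

    ``group_counts`` is the per-state copy-count vector of the set.  With the
    identity distance SS = (n - sum c^2 / n) / 2; with the squared-size
    distance SS = sum a^2 - (sum a)^2 / n (ordinary ANOVA form).
    """
    ss = 0.0
    for sl, states in zip(slices, states_l):
        c = group_counts[sl]
        n = c.sum()
        if n <= 1:
            continue
        if distance == "identity":
            ss += 0.5 * (n - (c ** 2).sum() / n)
        else:
            s1 = (c * states).sum()
            s2 = (c * states ** 2).sum()
            ss += s2 - s1 ** 2 / n
    return ss


def _amova_core(C, slices, states_l, pop_idx, sp_of_pop, n_pops, n_sp, distance):
    """Variance components given an individual->population assignment."""
    n_ind = C.shape[0]
    # copy counts per population (rows) per state (cols)
    M = np.zeros((n_ind, n_pops))
    M[np.arange(n_ind), pop_idx] = 1.0
    pop_counts = M.T @ C                      # n_pops x states
    ss_wp = sum(_ss_within(pop_counts[p], slices, states_l, distance)
                for p in range(n_pops))
    sp_counts = np.zeros((n_sp, pop_counts.shape[1]))
    for p in range(n_pops):
        sp_counts[sp_of_pop[p]] += pop_counts[p]
    ss_wg = sum(_ss_within(sp_counts[s], slices, states_l, distance)
                for s in range(n_sp))
    tot_counts = pop_counts.sum(axis=0)
    ss_t = _ss_within(tot_counts, slices, states_l, distance)
    return ss_wp, ss_wg - ss_wp, ss_t - ss_wg, ss_t


def amova(ds: MicrosatDataset, distance: str = "identity",
          n_perm: int = 999, seed: int = 0) -> AmovaResult:
    """Two-level nested AMOVA (species / populations / within populations).

    Degrees of freedom use the nominal gene-copy counts (2 per individual
    per locus); per-locus sums of squares drop missing copies.  Negative
    variance components are reported raw and flagged, never truncated.
    """
    if distance not in ("identity", "squared_size"):
        raise ValueError("distance must be 'identity' or 'squared_size'")
    pops = ds.populations
    if len(pops) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    sps = ds.species_levels
    flags = []
    pop_sizes = np.array([2 * len(ds.pop_indices(p)) for p in pops], dtype=float)
    sp_of_pop = np.array([sps.index(ds.species[ds.pop_indices(p)[0]]) for p in pops])
    for s in range(len(sps)):
        if (sp_of_pop == s).sum() == 1:
            flags.append(f"species {sps[s]!r} has a single population")
    N = pop_sizes.sum()
    G, P = len(sps), len(pops)
    sp_sizes = np.array([pop_sizes[sp_of_pop == s].sum() for s in range(G)])

    C, slices, states_l = _locus_blocks(ds, distance)
    pop_idx = np.array([pops.index(p) for p in ds.population])

    ss_wp, ss_ap, ss_ag, ss_t = _amova_core(
        C, slices, states_l, pop_idx, sp_of_pop, P, G, distance)

    if G < 2:
        raise ValueError("AMOVA needs >= 2 species for the two-level design")
    df = {"among_species": G - 1,
          "among_pops_within_species": P - G,
          "within_pops": int(N - P),
          "total": int(N - 1)}
    # unequal-size coefficients of the expected mean squares
    sum_np2_over_ng = sum((pop_sizes[sp_of_pop == s] ** 2).sum() / sp_sizes[s]
                          for s in range(G))
    n2 = (sum_np2_over_ng - (pop_sizes ** 2).sum() / N) / (G - 1)
    n3 = (N - (sp_sizes ** 2).sum() / N) / (G - 1)

    msd_wp = ss_wp / df["within_pops"]
    msd_ag = ss_ag / df["among_species"]
    sigma_c = msd_wp
    if P == G:
        # every species holds a single population: no among-pop level
        sigma_b = 0.0
    else:
        n1 = (N - sum_np2_over_ng) / (P - G)
        sigma_b = (ss_ap / df["among_pops_within_species"] - sigma_c) / n1
    sigma_a = (msd_ag - sigma_c - n2 * sigma_b) / n3
    for nm, v in (("sigma_a", sigma_a), ("sigma_b", sigma_b)):
        if v < 0:
            flags.append(f"negative variance component {nm} = {v:.4g}")
    pct, f_ct, f_sc, f_st = amova_from_components(sigma_a, sigma_b, sigma_c)

    rng = np.random.default_rng(seed)
    p_values = {}
    if n_perm > 0:
        stats_obs = {"among_species": f_ct,
                     "among_pops_within_species": f_sc,
                     "within_pops": f_st}
        hits = {k: 0 for k in stats_obs}
        for _ in range(n_perm):
            # (a) populations among species
            perm_sp = rng.permutation(sp_of_pop)
            r = _perm_components(C, slices, states_l, pop_idx, perm_sp,
                                 P, G, distance, pop_sizes, N)
            if r[0] >= stats_obs["among_species"] - 1e-12:
                hits["among_species"] += 1
            # (b) individuals among populations within species
            perm_idx = pop_idx.copy()
            for s in range(G):
                mask = np.isin(pop_idx, np.flatnonzero(sp_of_pop == s))
                perm_idx[mask] = rng.permutation(pop_idx[mask])
            r = _perm_components(C, slices, states_l, perm_idx, sp_of_pop,
                                 P, G, distance, pop_sizes, N)
            if r[1] >= stats_obs["among_pops_within_species"] - 1e-12:
                hits["among_pops_within_species"] += 1
            # (c) individuals among all populations
            perm_idx = rng.permutation(pop_idx)
            r = _perm_components(C, slices, states_l, perm_idx, sp_of_pop,
                                 P, G, distance, pop_sizes, N)
            if r[2] >= stats_obs["within_pops"] - 1e-12:
                hits["within_pops"] += 1
        p_values = {k: (hits[k] + 1) / (n_perm + 1) for k in hits}

    return AmovaResult(
        df=df,
        ss={"among_species": ss_ag, "among_pops_within_species": ss_ap,
            "within_pops": ss_wp, "total": ss_t},
        components={"sigma_a": sigma_a, "sigma_b": sigma_b, "sigma_c": sigma_c},
        percent=pct, f_ct=f_ct, f_sc=f_sc, f_st=f_st,
        p_values=p_values, n_permutations=n_perm, flags=flags,
    )


def _perm_components(C, slices, states_l, pop_idx, sp_of_pop, P, G,
                     distance, pop_sizes, N):
    """(F_CT, F_SC, F_ST) for one permuted assignment (nominal-size coefficients)."""
    ss_wp, ss_ap, ss_ag, _ = _amova_core(
        C, slices, states_l, pop_idx, sp_of_pop, P, G, distance)
    sp_sizes = np.array([pop_sizes[sp_of_pop == s].sum() for s in range(G)])
    sum_np2_over_ng = sum((pop_sizes[sp_of_pop == s] ** 2).sum() / sp_sizes[s]
                          for s in range(G))
    n2 = (sum_np2_over_ng - (pop_sizes ** 2).sum() / N) / (G - 1)
    n3 = (N - (sp_sizes ** 2).sum() / N) / (G - 1)
    sigma_c = ss_wp / (N - P)
    if P == G:
        sigma_b = 0.0
    else:
        n1 = (N - sum_np2_over_ng) / (P - G)
        sigma_b = (ss_ap / (P - G) - sigma_c) / n1
    sigma_a = (ss_ag / (G - 1) - sigma_c - n2 * sigma_b) / n3
    tot = sigma_a + sigma_b + sigma_c
    if tot == 0:
        return 0.0, 0.0, 0.0
    f_ct = sigma_a / tot
    f_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else 0.0
    f_st = (sigma_a + sigma_b) / tot
    return f_ct, f_sc, f_st


def pairwise_fst(ds: MicrosatDataset, distance: str = "identity") -> pd.DataFrame:
    """Population-pair F_ST matrix by one-level copy-distance AMOVA per pair."""
    pops = ds.populations
    K = len(pops)
    out = np.zeros((K, K))
    C, slices, states_l = _locus_blocks(ds, distance)
    pop_idx = np.array([pops.index(p) for p in ds.population])
    for i in range(K):
        for j in range(i + 1, K):
            mask = np.isin(pop_idx, [i, j])
            sub = C[mask]
            sub_idx = (pop_idx[mask] == j).astype(int)
            n_a = 2.0 * (sub_idx == 0).sum()
            n_b = 2.0 * (sub_idx == 1).sum()
            n = n_a + n_b
            cnt_a = sub[sub_idx == 0].sum(axis=0)
            cnt_b = sub[sub_idx == 1].sum(axis=0)
            ss_w = (_ss_within(cnt_a, slices, states_l, distance)
                    + _ss_within(cnt_b, slices, states_l, distance))
            ss_t = _ss_within(cnt_a + cnt_b, slices, states_l, distance)
            ss_a = ss_t - ss_w
            if ss_t == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            sigma_w = ss_w / (n - 2)
            n_c = (n - (n_a ** 2 + n_b ** 2) / n)  # / (P - 1) with P = 2
            sigma_a = (ss_a / 1.0 - sigma_w) / n_c
            fst = sigma_a / (sigma_a + sigma_w) if (sigma_a + sigma_w) > 0 else 0.0
            out[i, j] = out[j, i] = fst
    return pd.DataFrame(out, index=pops, columns=pops)
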