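"""Bayesian admixture clustering, Evanno Delta-K, run alignment, and DAPC.

The admixture sampler follows the classic population-model-based approach:
each gene copy carries a latent cluster assignment; cluster allele
frequencies follow the correlated-frequency prior (Dirichlet around the
ancestral frequencies with cluster-specific drift F_k, concentration
(1 - F_k)/F_k); individual membership vectors Q_i are Dirichlet(alpha +
copy counts) with the admixture parameter alpha sampled by a Metropolis
step under a uniform prior on (0, 10).

The model-selection input lnP(K) is estimated as mean(log L) -
var(log L)/2 over the post-burn-in trace (the standard deviance-based
estimator), and the Evanno table turns a set of replicate runs per K into
ln'(K), |ln''(K)| and Delta-K = |ln''(K)| / sd(lnP(K)).

DAPC reduces the centred allele-count matrix by PCA and applies linear
discriminant analysis to the retained components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genodata import MISSING, MicrosatDataset, genotype_matrix


@dataclass
class StructureRun:
    """One admixture-MCMC run at a fixed K."""

    K: int
    Q: np.ndarray                     # individuals x K posterior mean memberships
    cluster_freqs: list[np.ndarray]   # per locus: K x n_alleles posterior mean
    drift: np.ndarray                 # posterior mean F_k
    ln_prob: float                    # lnP(K) estimate for Evanno input
    seed: int
    individual_ids: list[str] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")


def _encode(ds: MicrosatDataset):
    """Per-locus integer allele codes (-1 for missing) and allele counts."""
    codes, n_alleles = [], []
    for l in range(ds.n_loci):
        col = ds.alleles[:, l, :]
        obs = col[col != MISSING]
        states = np.unique(obs)
        lut = {s: i for i, s in enumerate(states)}
        c = np.full(col.shape, -1, dtype=np.int64)
        for s, i in lut.items():
            c[col == s] = i
        codes.append(c)
        n_alleles.append(len(states))
    return codes, n_alleles


def admixture_mcmc(ds: MicrosatDataset, K: int, burn_in: int = 5000,
                   iterations: int = 20000, seed: int = 0,
                   lambda_freq: float = 1.0) -> StructureRun:
    """Gibbs sampler for the admixture model with correlated frequencies.

    Returns posterior-mean memberships and frequencies plus the lnP(K)
    estimate.  ``iterations`` counts post-burn-in sweeps.  A monotone trend
    in the post-burn-in log-likelihood trace (Spearman |rho| > 0.5 with
    p < 0.01) marks the run as non-converged.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    codes, n_alleles = _encode(ds)
    n, L = ds.n_individuals, ds.n_loci
    if K > max(n_alleles):
        warnings.warn("K exceeds the largest allele count at every locus")

    # ancestral frequencies: empirical Dirichlet-smoothed point estimate
    anc = []
    for l in range(L):
        c = codes[l]
        cnt = np.bincount(c[c >= 0], minlength=n_alleles[l]).astype(float)
        cnt += lambda_freq
        anc.append(cnt / cnt.sum())

    Q = np.full((n, K), 1.0 / K)
    drift = np.full(K, 0.05)
    alpha = 1.0
    freqs = [np.tile(anc[l], (K, 1)) for l in range(L)]
    Z = [rng.integers(0, K, size=codes[l].shape) for l in range(L)]

    Q_sum = np.zeros((n, K))
    F_sum = [np.zeros((K, n_alleles[l])) for l in range(L)]
    drift_sum = np.zeros(K)
    ll_trace = np.empty(iterations)

    total = burn_in + iterations
    for it in range(total):
        # (i) copy assignments given Q and frequencies
        counts_if = np.zeros((n, K))
        counts_kla = [np.zeros((K, n_alleles[l])) for l in range(L)]
        for l in range(L):
            c = codes[l]                       # n x 2
            for copy in (0, 1):
                a = c[:, copy]
                ok = a >= 0
                pr = Q.copy()
                pr[ok] = Q[ok] * freqs[l][:, a[ok]].T
                tot = pr.sum(axis=1, keepdims=True)
                tot[tot == 0] = 1.0
                pr = pr / tot
                u = rng.random(n)
                z = (pr.cumsum(axis=1) < u[:, None]).sum(axis=1)
                z = np.minimum(z, K - 1)
                Z[l][:, copy] = z
                np.add.at(counts_if, (np.arange(n), z), 1.0)
                zz, aa = z[ok], a[ok]
                np.add.at(counts_kla[l], (zz, aa), 1.0)
        # (ii) cluster frequencies under the correlated prior
        for l in range(L):
            for k in range(K):
                conc = anc[l] * (1.0 - drift[k]) / drift[k] + counts_kla[l][k]
                freqs[l][k] = rng.dirichlet(conc)
            np.clip(freqs[l], 1e-12, None, out=freqs[l])
            freqs[l] /= freqs[l].sum(axis=1, keepdims=True)
        # drift Metropolis step (uniform prior on (0.001, 0.99))
        for k in range(K):
            f_new = drift[k] * np.exp(rng.normal(0.0, 0.2))
            if not 0.001 < f_new < 0.99:
                continue
            r_old = (1.0 - drift[k]) / drift[k]
            r_new = (1.0 - f_new) / f_new
            lp_old = lp_new = 0.0
            for l in range(L):
                lf = np.log(freqs[l][k])
                c_old = anc[l] * r_old
                c_new = anc[l] * r_new
                lp_old += (gammaln(c_old.sum()) - gammaln(c_old).sum()
                           + ((c_old - 1.0) * lf).sum())
                lp_new += (gammaln(c_new.sum()) - gammaln(c_new).sum()
                           + ((c_new - 1.0) * lf).sum())
            # log-scale proposal Jacobian
            if np.log(rng.random()) < lp_new - lp_old + np.log(f_new / drift[k]):
                drift[k] = f_new
        # (iii) memberships
        Q = rng.gamma(alpha + counts_if)
        Q /= Q.sum(axis=1, keepdims=True)
        # admixture alpha Metropolis (uniform prior on (0, 10))
        a_new = alpha + rng.normal(0.0, 0.1)
        if 0.0 < a_new < 10.0:
            lq = np.log(np.clip(Q, 1e-300, None)).sum()
            lp = (n * (gammaln(K * a_new) - K * gammaln(a_new))
                  + (a_new - 1.0) * lq)
            lp0 = (n * (gammaln(K * alpha) - K * gammaln(alpha))
                   + (alpha - 1.0) * lq)
            if np.log(rng.random()) < lp - lp0:
                alpha = a_new
        if it >= burn_in:
            Q_sum += Q
            drift_sum += drift
            ll = 0.0
            for l in range(L):
                c = codes[l]
                for copy in (0, 1):
                    a = c[:, copy]
                    ok = a >= 0
                    mix = (Q[ok] * freqs[l][:, a[ok]].T).sum(axis=1)
                    ll += np.log(np.clip(mix, 1e-300, None)).sum()
            for l in range(L):
                F_sum[l] += freqs[l]
            ll_trace[it - burn_in] = ll

    Q_mean = Q_sum / iterations
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    ln_prob = float(ll_trace.mean() - ll_trace.var() / 2.0)
    converged = True
    if iterations >= 10:
        rho, pval = sps.spearmanr(np.arange(iterations), ll_trace)
        if abs(rho) > 0.5 and pval < 0.01:
            converged = False
    return StructureRun(
        K=K, Q=Q_mean,
        cluster_freqs=[f / iterations for f in F_sum],
        drift=drift_sum / iterations, ln_prob=ln_prob, seed=seed,
        individual_ids=list(ds.individual_ids), converged=converged,
    )


# ---------------------------------------------------------------------------
# Evanno Delta-K
# ---------------------------------------------------------------------------

@dataclass
class DeltaKTable:
    table: pd.DataFrame

    @property
    def best_k(self) -> int:
        t = self.table.dropna(subset=["delta_k"])
        return int(t["delta_k"].idxmax())


def evanno_deltaK(runs: list[StructureRun]) -> DeltaKTable:
    """Evanno table from replicate runs over a consecutive K range.

    ln'(K) = mean lnP(K) - mean lnP(K-1); |ln''(K)| = |ln'(K+1) - ln'(K)|;
    Delta-K = |ln''(K)| / sd(lnP(K)), defined for interior K only.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.ln_prob)
    ks = sorted(by_k)
    if len(ks) < 3:
        raise ValueError("need a consecutive K range of length >= 3")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"missing K in range: have {ks}")
    for k in ks:
        if len(by_k[k]) < 2:
            raise ValueError(f"need >= 2 runs per K (K={k} has {len(by_k[k])})")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    lp1 = {k: mean[k] - mean[k - 1] for k in ks[1:]}
    rows = []
    for k in ks:
        lp2 = abs(lp1[k + 1] - lp1[k]) if (k in lp1 and k + 1 in lp1) else np.nan
        if not np.isnan(lp2):
            if sd[k] == 0:
                warnings.warn(f"sd(lnP) = 0 at K={k}; Delta-K infinite")
                dk = np.inf
            else:
                dk = lp2 / sd[k]
        else:
            dk = np.nan
        rows.append({"K": k, "mean_lnP": mean[k], "sd_lnP": sd[k],
                     "lnP1": lp1.get(k, np.nan), "lnP2": lp2, "delta_k": dk})
    return DeltaKTable(pd.DataFrame(rows).set_index("K"))


# ---------------------------------------------------------------------------
# multi-run alignment (CLUMPP-style greedy)
# ---------------------------------------------------------------------------

def align_runs(runs: list[StructureRun]):
    """Greedy column-permutation alignment of same-K runs to the first run.

    Maximises the sum of matched-column dot products against the reference
    (the G'-statistic contract).  Returns ``(aligned Q list, permutations,
    mean Q)``.
    """
    if not runs:
        raise ValueError("no runs to align")
    K = runs[0].K
    ids = runs[0].individual_ids
    for r in runs[1:]:
        if r.K != K:
            raise ValueError("all runs must share K")
        if r.individual_ids != ids:
            raise ValueError("inconsistent individual ordering across runs")
    ref = runs[0].Q
    aligned, perms = [], []
    for r in runs:
        sim = r.Q.T @ ref                     # K x K column similarity
        perm = np.full(K, -1, dtype=int)
        used_rows, used_cols = set(), set()
        for _ in range(K):
            best, bi, bj = -np.inf, -1, -1
            for i in range(K):
                if i in used_rows:
                    continue
                for j in range(K):
                    if j in used_cols:
                        continue
                    if sim[i, j] > best:
                        best, bi, bj = sim[i, j], i, j
            perm[bi] = bj
            used_rows.add(bi)
            used_cols.add(bj)
        Qa = np.empty_like(r.Q)
        Qa[:, perm] = r.Q
        aligned.append(Qa)
        perms.append(perm)
    mean_q = np.mean(aligned, axis=0)
    mean_q /= mean_q.sum(axis=1, keepdims=True)
    return aligned, perms, mean_q


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

@dataclass
class DapcResult:
    n_pcs: int
    coordinates: pd.DataFrame       # individuals x discriminant axes
    memberships: pd.DataFrame       # individuals x groups (probabilities)
    group_means: pd.DataFrame
    assignments: pd.Series
    explained_variance: np.ndarray  # PCA stage, fraction per retained PC


def dapc_fit(ds: MicrosatDataset, groups: str = "species",
             n_pcs: int = 2) -> DapcResult:
    """Discriminant analysis of principal components on allele counts.

    PCA on the centred individuals-by-alleles count matrix, retention of
    ``n_pcs`` components, then linear discriminant analysis on the group
    labels.  Groups with a single member leave the within-group scatter
    undefined and raise.
    """
    labels = ds.species if groups == "species" else ds.population
    labels = pd.Series(labels, index=ds.individual_ids)
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"group with a single individual: "
                         f"{list(sizes.index[sizes < 2])}")
    n_groups = sizes.size
    if n_pcs < n_groups - 1:
        warnings.warn("n_pcs below the recommended (groups - 1)")
    X = genotype_matrix(ds)
    X = X - X.mean(axis=0)
    pca = PCA(n_components=min(n_pcs, min(X.shape) - 1), svd_solver="full")
    scores = pca.fit_transform(X)
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores, labels.to_numpy())
    n_axes = min(n_groups - 1, scores.shape[1])
    coords = lda.transform(scores)[:, :n_axes]
    proba = lda.predict_proba(scores)
    idx = pd.Index(ds.individual_ids, name="individual")
    axes = [f"LD{i + 1}" for i in range(coords.shape[1])]
    coord_df = pd.DataFrame(coords, index=idx, columns=axes)
    memb = pd.DataFrame(proba, index=idx, columns=lda.classes_)
    gm = coord_df.groupby(labels.to_numpy()).mean()
    return DapcResult(
        n_pcs=scores.shape[1],
        coordinates=coord_df,
        memberships=memb,
        group_means=gm,
        assignments=pd.Series(lda.predict(scores), index=idx),
        explained_variance=pca.explained_variance_ratio_,
    )
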