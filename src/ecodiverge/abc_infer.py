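"""ABC model choice and parameter estimation for divergence scenarios.

The workflow mirrors the standard microsatellite ABC stack:

1. summary statistics per population (mean allele count, expected
   heterozygosity, allele-size variance, Garza-Williamson M) and per
   population pair (F_ST, (delta mu)^2, shared-allele proportion);
2. Box-Cox transformation and standardisation of every statistic, then
   partial least-squares reduction to a few components (fitted on the
   pooled reference table so all models live in one comparison space);
3. rejection: the Euclidean-closest simulations to the observed projection;
4. a multivariate linear model (GLM) of the transformed statistics on the
   parameters, fitted on the retained simulations, giving a Gaussian
   likelihood of the observed statistics at any parameter value;
5. the marginal density of each model = the average of that likelihood
   over the model's full prior sample (non-retained draws contribute
   nothing, which preserves the Occam penalty for models that spread
   their prior over parameter regions that cannot produce the data);
6. relative densities, Bayes factors, and weighted posterior summaries
   (KDE mode, median, HPD intervals).

Reference tables for competing models are built with common random
numbers: every model re-uses the same underlying parameter draws and
per-row simulation seeds, so that models differing only on a rarely
exercised epoch produce bit-identical rows where they are equivalent and
the model comparison is decided by the rows where they genuinely differ,
not by Monte-Carlo noise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp
from sklearn.cross_decomposition import PLSRegression

from .genodata import MISSING, MicrosatDataset
from .coalsim import MODELS, PriorSpec, ScenarioSpec, draw_from_priors, simulate_dataset

PARAM_COLS = ["n1", "n2", "n_anc", "t2", "t1", "m12", "m21", "mu"]


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summary_stat_names(pops: list) -> list[str]:
    names = []
    for p in pops:
        names += [f"K_{p}", f"He_{p}", f"V_{p}", f"GW_{p}"]
    for a, b in itertools.combinations(pops, 2):
        names += [f"fst_{a}_{b}", f"dmu2_{a}_{b}", f"shared_{a}_{b}"]
    return names


def summary_stats(ds: MicrosatDataset) -> pd.Series:
    """Deterministic summary-statistic vector of a microsatellite dataset.

    Undefined entries (monomorphic pairs give an undefined F_ST) are
    replaced by 0 with a warning.
    """
    pops = ds.populations
    if len(pops) < 2:
        raise ValueError("summary statistics need >= 2 populations")
    P = len(pops)
    pop_idx = np.array([pops.index(p) for p in ds.population])
    L = ds.n_loci
    K = np.zeros((P, L)); He = np.zeros((P, L)); V = np.zeros((P, L))
    GW = np.zeros((P, L))
    pairs = list(itertools.combinations(range(P), 2))
    dmu2 = np.zeros((len(pairs), L)); shared = np.zeros((len(pairs), L))
    fst_num = np.zeros(len(pairs)); fst_den = np.zeros(len(pairs))
    any_fst = np.zeros(len(pairs), dtype=bool)
    for l in range(L):
        col = ds.alleles[:, l, :]
        copy_pop = np.repeat(pop_idx, 2)
        copies = col.reshape(-1)
        ok = copies != MISSING
        copies, copy_pop = copies[ok], copy_pop[ok]
        states, inv = np.unique(copies, return_inverse=True)
        A = len(states)
        cnt = np.zeros((P, A))
        np.add.at(cnt, (copy_pop, inv), 1.0)
        n_g = cnt.sum(axis=1)
        sf = states.astype(float)
        for g in range(P):
            n = n_g[g]
            if n == 0:
                continue
            row = cnt[g]
            present = row > 0
            K[g, l] = present.sum()
            p = row / n
            He[g, l] = 1.0 - (p ** 2).sum()
            mean = (row * sf).sum() / n
            if n > 1:
                V[g, l] = ((row * sf ** 2).sum() - n * mean ** 2) / (n - 1)
            lo, hi = sf[present].min(), sf[present].max()
            GW[g, l] = present.sum() / (hi - lo + 1.0)
        means = (cnt * sf).sum(axis=1) / np.where(n_g > 0, n_g, 1)
        for pi, (a, b) in enumerate(pairs):
            dmu2[pi, l] = (means[a] - means[b]) ** 2
            pa, pb = cnt[a] > 0, cnt[b] > 0
            union = (pa | pb).sum()
            shared[pi, l] = (pa & pb).sum() / union if union else 0.0
            na, nb = n_g[a], n_g[b]
            n = na + nb
            if na < 2 or nb < 2:
                continue
            ssw = 0.5 * ((na - (cnt[a] ** 2).sum() / na)
                         + (nb - (cnt[b] ** 2).sum() / nb))
            tot = cnt[a] + cnt[b]
            sst = 0.5 * (n - (tot ** 2).sum() / n)
            ssa = sst - ssw
            if sst == 0:
                continue
            sw = ssw / (n - 2)
            nc = n - (na ** 2 + nb ** 2) / n
            sa = (ssa - sw) / nc
            fst_num[pi] += sa
            fst_den[pi] += sa + sw
            any_fst[pi] = True
    vals, names = [], summary_stat_names(pops)
    for g in range(P):
        vals += [K[g].mean(), He[g].mean(), V[g].mean(), GW[g].mean()]
    for pi, (a, b) in enumerate(pairs):
        if not any_fst[pi] or fst_den[pi] <= 0:
            warnings.warn(f"F_ST undefined for pair {pops[a]}/{pops[b]}; set to 0")
            fst = 0.0
        else:
            fst = fst_num[pi] / fst_den[pi]
        vals += [fst, dmu2[pi].mean(), shared[pi].mean()]
    return pd.Series(vals, index=names)


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Parameter draws + summary statistics from batched simulations."""

    table: pd.DataFrame
    param_cols: list[str]
    stat_cols: list[str]

    def rows_of(self, model: str) -> pd.DataFrame:
        return self.table[self.table["model"] == model]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        tab = pd.read_csv(path, sep="\t")
        stat_cols = [c for c in tab.columns
                     if c not in PARAM_COLS and c != "model"]
        return cls(tab, [c for c in PARAM_COLS if c in tab.columns], stat_cols)


def build_reference_table(models, n_per_model: int, n_loci: int, seed: int,
                          priors: PriorSpec | None = None,
                          base: ScenarioSpec | None = None) -> ReferenceTable:
    """Simulate the ABC substrate: `n_per_model` draws per scenario.

    Common random numbers across models: each model uses the same prior
    stream and the same per-row simulation seeds.
    """
    rows = []
    stat_cols = None
    for model in models:
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}")
        specs = draw_from_priors(model, n_per_model, seed, priors, base)
        for i, spec in enumerate(specs):
            ds = simulate_dataset(spec, n_loci, seed=(seed * 1000003 + i) % (2 ** 31))
            s = summary_stats(ds)
            if stat_cols is None:
                stat_cols = list(s.index)
            rec = {"model": model}
            for c in PARAM_COLS:
                rec[c] = getattr(spec, c)
            rec.update(s.to_dict())
            rows.append(rec)
    tab = pd.DataFrame(rows)
    return ReferenceTable(tab, PARAM_COLS, stat_cols)


# ---------------------------------------------------------------------------
# Box-Cox + PLS
# ---------------------------------------------------------------------------

@dataclass
class StatTransform:
    """Frozen Box-Cox/standardise/PLS transformation fitted on a reference."""

    stat_cols: list[str]
    shifts: np.ndarray
    lams: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    pls: PLSRegression
    dropped: list[str]

    def apply(self, stats: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(stats, dtype=float))
        Z = np.empty_like(X)
        for j in range(X.shape[1]):
            x = X[:, j] + self.shifts[j]
            x = np.maximum(x, 1e-12)
            lam = self.lams[j]
            z = np.log(x) if abs(lam) < 1e-12 else (x ** lam - 1.0) / lam
            Z[:, j] = (z - self.means[j]) / self.sds[j]
        return self.pls.transform(Z)


def boxcox_pls(reference: ReferenceTable, observed: pd.Series,
               n_components: int = 5):
    """Fit Box-Cox + PLS on the pooled reference; project reference and observed.

    Returns ``(scores, obs_scores, transform)`` where ``scores`` has one row
    per reference row.  Constant statistic columns are dropped with a
    warning before the transform.
    """
    stat_cols = list(reference.stat_cols)
    S = reference.table[stat_cols].to_numpy(dtype=float)
    sd0 = S.std(axis=0)
    keep = sd0 > 1e-12
    dropped = [c for c, k in zip(stat_cols, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant statistics: {dropped}")
    stat_cols = [c for c, k in zip(stat_cols, keep) if k]
    S = S[:, keep]
    if n_components > S.shape[1]:
        raise ValueError("n_components exceeds the number of usable statistics")
    if len(S) < 10 * n_components:
        raise ValueError("reference table too small for the requested components")
    shifts = np.zeros(S.shape[1])
    lams = np.ones(S.shape[1])
    Z = np.empty_like(S)
    for j in range(S.shape[1]):
        x = S[:, j]
        mn = x.min()
        if mn <= 0:
            shifts[j] = 1e-6 - mn
        xs = x + shifts[j]
        try:
            z, lam = sps.boxcox(xs)
        except Exception:
            z, lam = np.log(xs), 0.0
        lams[j] = lam
        Z[:, j] = z
    means = Z.mean(axis=0)
    sds = Z.std(axis=0)
    sds[sds < 1e-12] = 1.0
    Z = (Z - means) / sds
    # PLS of parameters on statistics (standardised targets)
    P = reference.table[reference.param_cols].to_numpy(dtype=float)
    Pm, Psd = P.mean(axis=0), P.std(axis=0)
    Psd[Psd < 1e-12] = 1.0
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Z, (P - Pm) / Psd)
    tf = StatTransform(stat_cols, shifts, lams, means, sds, pls, dropped)
    obs = observed[stat_cols].to_numpy(dtype=float)
    return pls.transform(Z), tf.apply(obs)[0], tf


def abc_reject(scores: np.ndarray, obs_scores: np.ndarray,
               n_keep: int = 5000) -> np.ndarray:
    """Indices of the `n_keep` Euclidean-closest rows (ties by row order)."""
    if n_keep <= 0:
        raise ValueError("n_keep must be positive")
    if n_keep > len(scores):
        raise ValueError("n_keep exceeds the number of rows")
    d = np.sqrt(((scores - obs_scores) ** 2).sum(axis=1))
    order = np.lexsort((np.arange(len(d)), d))
    return order[:n_keep]


# ---------------------------------------------------------------------------
# GLM adjustment and marginal density
# ---------------------------------------------------------------------------

@dataclass
class GlmPosterior:
    """Gaussian GLM likelihood of the observed statistics over retained draws."""

    params: pd.DataFrame          # retained parameter draws
    log_weights: np.ndarray       # log N(obs; c + B theta_i, Sigma)
    log_marginal_density: float
    n_total: int
    ridge_used: float = 0.0

    @property
    def weights(self) -> np.ndarray:
        w = np.exp(self.log_weights - self.log_weights.max())
        return w / w.sum()


def glm_adjust(retained_params: pd.DataFrame, retained_scores: np.ndarray,
               obs_scores: np.ndarray, n_total: int | None = None) -> GlmPosterior:
    """ABC-GLM: linear model of component scores on parameters.

    Fits ``scores = c + B.params + eps`` on the retained rows, with the
    residual covariance as the Gaussian error; the marginal density is the
    average of ``N(obs; c + B theta_i, Sigma)`` over the model's full prior
    sample of size ``n_total`` (non-retained draws contribute zero).
    """
    P = retained_params.to_numpy(dtype=float)
    n, p = P.shape
    if n < 10 * max(p, 1):
        warnings.warn("few retained rows relative to parameter count")
    # standardise parameters for the regression only
    Pm, Psd = P.mean(axis=0), P.std(axis=0)
    Psd[Psd < 1e-12] = 1.0
    D = np.column_stack([np.ones(n), (P - Pm) / Psd])
    coef, *_ = np.linalg.lstsq(D, retained_scores, rcond=None)
    resid = retained_scores - D @ coef
    dof = max(n - D.shape[1], 1)
    Sigma = resid.T @ resid / dof
    ridge = 0.0
    while True:
        try:
            chol = np.linalg.cholesky(Sigma + ridge * np.eye(len(Sigma)))
            break
        except np.linalg.LinAlgError:
            ridge = 1e-10 if ridge == 0 else ridge * 10
    if ridge:
        warnings.warn(f"singular residual covariance; ridge jitter {ridge:g}")
        Sigma = Sigma + ridge * np.eye(len(Sigma))
    mu = D @ coef                              # fitted stats per retained draw
    diff = obs_scores - mu
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol ** 2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    k = len(obs_scores)
    log_w = -0.5 * (maha + logdet + k * np.log(2 * np.pi))
    n_tot = n_total if n_total is not None else n
    log_md = logsumexp(log_w) - np.log(n_tot)
    return GlmPosterior(retained_params.reset_index(drop=True), log_w,
                        float(log_md), n_tot, ridge)


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------

@dataclass
class AbcModelResult:
    """Marginal/relative densities, Bayes factors and posterior summaries."""

    log_marginal: dict
    relative_density: dict        # percent, sums to 100
    bayes_factors: pd.DataFrame
    best_model: str
    posteriors: dict = field(default_factory=dict)      # model -> GlmPosterior
    posterior_summary: dict = field(default_factory=dict)

    @property
    def marginal_density(self) -> dict:
        return {m: float(np.exp(v)) for m, v in self.log_marginal.items()}


def model_choice(log_marginal: dict) -> AbcModelResult:
    """Relative densities (percent) and the Bayes-factor matrix from log MDs."""
    if len(log_marginal) < 2:
        raise ValueError("model choice needs >= 2 models")
    models = list(log_marginal)
    lm = np.array([log_marginal[m] for m in models], dtype=float)
    if not np.isfinite(lm).any():
        raise ValueError("all marginal densities are zero; "
                         "check the reference table and observed statistics")
    rel = np.exp(lm - logsumexp(lm))
    bf = pd.DataFrame(np.exp(lm[:, None] - lm[None, :]),
                      index=models, columns=models)
    best = models[int(np.argmax(lm))]
    return AbcModelResult(
        log_marginal=dict(log_marginal),
        relative_density={m: 100.0 * r for m, r in zip(models, rel)},
        bayes_factors=bf, best_model=best,
    )


def abc_analysis(reference: ReferenceTable, observed: pd.Series,
                 n_components: int = 5, n_keep: int = 5000,
                 summarize_best: bool = True) -> AbcModelResult:
    """Full ABC model choice on a mixed-model reference table.

    Per model: rejection of the closest ``min(n_keep, rows)`` simulations in
    the pooled component space, GLM adjustment, marginal density; then
    relative densities and Bayes factors across models, plus posterior
    summaries for the best model's free parameters.
    """
    scores, obs_scores, _tf = boxcox_pls(reference, observed, n_components)
    models = list(pd.unique(reference.table["model"]))
    log_md, posts = {}, {}
    for m in models:
        mask = (reference.table["model"] == m).to_numpy()
        sc = scores[mask]
        params = reference.table.loc[mask, reference.param_cols]
        free = [c for c in reference.param_cols
                if params[c].std() > 1e-12 * (abs(params[c].mean()) + 1)]
        keep = min(n_keep, len(sc))
        idx = abc_reject(sc, obs_scores, keep)
        post = glm_adjust(params.iloc[idx][free], sc[idx], obs_scores,
                          n_total=len(sc))
        log_md[m] = post.log_marginal_density
        posts[m] = post
    res = model_choice(log_md)
    res.posteriors = posts
    if summarize_best:
        best = posts[res.best_model]
        res.posterior_summary = {
            c: posterior_summarize(best.params[c].to_numpy(), best.weights)
            for c in best.params.columns
        }
    return res


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def posterior_summarize(samples: np.ndarray, weights: np.ndarray | None = None,
                        grid_size: int = 512) -> dict:
    """Weighted posterior summaries: KDE mode, median, 50%/95% HPD intervals."""
    x = np.asarray(samples, dtype=float)
    if weights is None:
        weights = np.full(len(x), 1.0 / len(x))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    if len(x) < 100:
        warnings.warn("fewer than 100 posterior draws; summaries are coarse")
    if np.ptp(x) < 1e-300 or (w > 0).sum() < 2:
        v = float(np.average(x, weights=w))
        return {"mode": v, "median": v, "hpd50": (v, v), "hpd95": (v, v)}
    try:
        # Scott's factor with a floor: very large samples otherwise get a
        # bandwidth narrow enough that the argmax wanders between noise peaks
        neff = 1.0 / float((w ** 2).sum())
        bw = max(neff ** (-1.0 / 5.0), 0.2)
        kde = sps.gaussian_kde(x, weights=w, bw_method=bw)
        grid = np.linspace(x.min(), x.max(), grid_size)
        mode = float(grid[np.argmax(kde(grid))])
    except np.linalg.LinAlgError:
        mode = float(np.average(x, weights=w))
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    median = float(xs[np.searchsorted(cw, 0.5)])
    return {"mode": mode, "median": median,
            "hpd50": _hpd(xs, cw, 0.5), "hpd95": _hpd(xs, cw, 0.95)}


def _hpd(xs: np.ndarray, cw: np.ndarray, mass: float) -> tuple[float, float]:
    """Minimal-width interval holding `mass` of a sorted weighted sample."""
    lo_best, hi_best = xs[0], xs[-1]
    width = hi_best - lo_best
    j = 0
    for i in range(len(xs)):
        left = cw[i - 1] if i > 0 else 0.0
        target = left + mass
        j = np.searchsorted(cw, min(target, cw[-1]))
        j = min(j, len(xs) - 1)
        if xs[j] - xs[i] <= width:
            width = xs[j] - xs[i]
            lo_best, hi_best = xs[i], xs[j]
        if cw[i] + mass > cw[-1]:
            break
    return float(lo_best), float(hi_best)
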