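"""Genotype-environment and niche-differentiation statistics.

Covers the environmental side of the pipeline: variance-inflation-factor
pruning of collinear predictors, PCA of the retained variables (the niche
space), Kruskal-Wallis tests of species differences along principal
components, per-variable GLMs along ordination axes, multivariate logistic
regression of species on predictors, distance-based redundancy analysis
(dbRDA) with marginal (type II) permutation tests, and Mantel tests
between distance matrices.

dbRDA here means: Euclidean distances on the (already reduced) genetic
response, principal-coordinate decomposition, redundancy analysis on the
standardised predictors.  For a Euclidean distance this is algebraically
identical to an RDA on the response matrix itself, which is how it is
implemented (and tested).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


# ---------------------------------------------------------------------------
# collinearity pruning
# ---------------------------------------------------------------------------

def _vif(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1 - R^2_j) from regressing column j on the others."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_prune(env: pd.DataFrame, threshold: float = 10.0):
    """Iteratively drop the largest-VIF variable until all VIF < threshold.

    Exactly collinear variables (infinite VIF) are dropped first; ties
    break deterministically by column order.  Returns ``(retained column
    list, step log DataFrame)``.
    """
    num = env.select_dtypes(include=[np.number])
    cols = list(num.columns)
    if len(cols) < 2:
        raise ValueError("need >= 2 numeric variables")
    if len(num) <= len(cols):
        raise ValueError("need more rows than variables for VIF")
    logrows = []
    while len(cols) > 1:
        X = num[cols].to_numpy(dtype=float)
        vifs = _vif(X)
        worst = int(np.argmax(vifs))
        logrows.append({"step": len(logrows), "variable": cols[worst],
                        "vif": vifs[worst],
                        "n_remaining": len(cols)})
        if vifs[worst] < threshold:
            break
        cols.pop(worst)
    return cols, pd.DataFrame(logrows)


# ---------------------------------------------------------------------------
# environmental PCA
# ---------------------------------------------------------------------------

@dataclass
class EnvPca:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    percent_variance: np.ndarray


def pca_env(env: pd.DataFrame, variables: list[str] | None = None) -> EnvPca:
    """PCA on the correlation matrix of the named environmental variables."""
    if variables is None:
        variables = list(env.select_dtypes(include=[np.number]).columns)
    variables = list(variables)
    X = env[variables].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    for v, s in zip(variables, sd):
        if s == 0:
            raise ValueError(f"constant environmental column: {v!r}")
    Z = (X - X.mean(axis=0)) / sd
    n = len(Z)
    cov = Z.T @ Z / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    # sign convention: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    pcs = [f"PC{i + 1}" for i in range(len(evals))]
    scores = pd.DataFrame(Z @ evecs, index=env.index, columns=pcs)
    loadings = pd.DataFrame(evecs, index=variables, columns=pcs)
    pct = 100.0 * evals / evals.sum()
    return EnvPca(scores, loadings, pct)


def kw_species_test(scores: pd.DataFrame, species) -> pd.DataFrame:
    """Kruskal-Wallis rank-sum test of group differences per column.

    Returns chi2, df and p per score column (tie-corrected H statistic).
    """
    species = np.asarray(species)
    groups = pd.unique(species)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if (species == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    rows = []
    for col in scores.columns:
        samples = [scores.loc[species == g, col].to_numpy() for g in groups]
        allv = np.concatenate(samples)
        if np.ptp(allv) == 0:
            warnings.warn(f"all values tied in {col}; p set to 1")
            rows.append({"statistic": 0.0, "df": len(groups) - 1, "p": 1.0})
            continue
        h, p = sps.kruskal(*samples)
        rows.append({"statistic": h, "df": len(groups) - 1, "p": p})
    return pd.DataFrame(rows, index=scores.columns)


def glm_on_axis(env: pd.DataFrame, axes: pd.DataFrame,
                variables: list[str] | None = None) -> pd.DataFrame:
    """Per-variable OLS of the environmental variable on the ordination axes.

    Fits ``variable ~ axis1 + axis2 (+ ...)`` and reports per-axis slope,
    SE, t and p plus the model's adjusted R^2, F and overall p.
    """
    if variables is None:
        variables = list(env.select_dtypes(include=[np.number]).columns)
    variables = list(variables)
    if len(env) < 3:
        raise ValueError("need n >= 3")
    A = axes.to_numpy(dtype=float)
    if (A.std(axis=0) == 0).any():
        raise ValueError("zero-variance ordination axis")
    X = sm.add_constant(A)
    rows = []
    for v in variables:
        res = sm.OLS(env[v].to_numpy(dtype=float), X).fit()
        row = {}
        for i, ax in enumerate(axes.columns, start=1):
            row[f"{ax}_estimate"] = res.params[i]
            row[f"{ax}_se"] = res.bse[i]
            row[f"{ax}_t"] = res.tvalues[i]
            row[f"{ax}_p"] = res.pvalues[i]
        row["adj_r2"] = res.rsquared_adj
        row["F"] = res.fvalue
        row["p"] = res.f_pvalue
        rows.append(row)
    return pd.DataFrame(rows, index=variables)


def logistic_species(table: pd.DataFrame, species,
                     predictors: list[str] | None = None) -> pd.DataFrame:
    """Multivariate logistic regression of a binary species label.

    Maximum-likelihood fit (IRLS); reports coefficient, SE, Wald Z and p
    per predictor.  Perfect separation is flagged in a ``separation``
    column rather than silently returned.
    """
    if predictors is None:
        predictors = list(table.select_dtypes(include=[np.number]).columns)
    species = np.asarray(species)
    levels = pd.unique(species)
    if len(levels) != 2:
        raise ValueError("species label must be binary")
    y = (species == levels[1]).astype(float)
    X = table[predictors].to_numpy(dtype=float)
    if len(y) <= len(predictors):
        raise ValueError("need more observations than predictors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) \
            < len(predictors) + 1:
        raise ValueError("rank-deficient design (duplicated predictor?)")
    Xc = sm.add_constant(X)
    separation = False
    coefs = bse = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            coefs = np.asarray(res.params)
            bse = np.asarray(res.bse)
            if not (np.isfinite(coefs).all() and np.isfinite(bse).all()):
                raise np.linalg.LinAlgError
        except Exception:
            separation = True
            coefs, bse = _ridge_logit(y, Xc, alpha=1e-4)
    if np.abs(coefs).max() > 50:
        separation = True
    z = coefs / bse
    p = 2.0 * sps.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "coefficient": coefs, "se": bse, "z": z, "p": p,
        "separation": separation,
    }, index=["intercept"] + list(predictors))
    return out


def _ridge_logit(y, X, alpha=1e-4, maxiter=100):
    """Ridge-stabilised IRLS fallback for (near-)separated logistic fits."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = X.T @ (w[:, None] * X) + alpha * np.eye(p)
        g = X.T @ (y - mu) - alpha * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv(X.T @ (w[:, None] * X) + alpha * np.eye(p))
    return beta, np.sqrt(np.diag(cov))


# ---------------------------------------------------------------------------
# dbRDA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Constrained ordination output with the inertia partition."""

    eigenvalues: np.ndarray              # constrained axes
    residual_eigenvalues: np.ndarray     # unconstrained axes
    site_scores: pd.DataFrame            # rows x constrained axes
    biplot_scores: pd.DataFrame          # predictor correlations with axes
    total_inertia: float
    constrained_inertia: float
    unconstrained_inertia: float
    r_squared: float
    adj_r_squared: float
    anova: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_permutations: int = 0


def _rda_fit(Y: np.ndarray, X: np.ndarray):
    """Fitted values and residuals of the RDA projection.

    Least-squares (min-norm) projection, robust to rank-deficient
    predictor sets such as site-level variables repeated per individual.
    """
    n = len(Y)
    D = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    Yhat = D @ coef
    return Yhat, Y - Yhat


def dbrda(response: pd.DataFrame, predictors: pd.DataFrame,
          n_perm: int = 9999, seed: int = 0) -> OrdinationResult:
    """Distance-based redundancy analysis with marginal permutation tests.

    ``response`` holds the genetic response (e.g. the first two PCs of the
    allele-count matrix), ``predictors`` the standardisable environmental
    columns.  Euclidean response distances make the principal-coordinate
    step the identity up to rotation, so the analysis is an RDA of the
    centred response on the standardised predictors.  Per-variable type II
    (marginal) tests permute the residuals of the reduced model lacking
    that variable, under ``n_perm`` permutations.
    """
    if len(response) != len(predictors):
        raise ValueError("response and predictors must have aligned rows")
    n = len(response)
    pred_cols = list(predictors.select_dtypes(include=[np.number]).columns)
    if len(pred_cols) > n - 1:
        raise ValueError("more predictors than rows - 1")
    Y = response.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    X = predictors[pred_cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant predictor column")
    X = (X - X.mean(axis=0)) / sd

    Yhat, resid = _rda_fit(Y, X)
    tot = float((Y ** 2).sum()) / (n - 1)
    con = float((Yhat ** 2).sum()) / (n - 1)
    unc = float((resid ** 2).sum()) / (n - 1)
    p = len(pred_cols)
    r2 = con / tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan

    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = (S ** 2) / (n - 1)
    k = int((eig > 1e-12 * max(eig.max(), 1.0)).sum())
    axes = [f"dbRDA{i + 1}" for i in range(k)]
    sites = pd.DataFrame((U[:, :k] * S[:k]), index=response.index,
                         columns=axes)
    bip = np.zeros((p, k))
    for j in range(p):
        for a in range(k):
            sa = sites.iloc[:, a].to_numpy()
            bip[j, a] = np.corrcoef(X[:, j], sa)[0, 1] if sa.std() > 0 else 0.0
    _, Sr, _ = np.linalg.svd(resid, full_matrices=False)
    res_eig = (Sr ** 2) / (n - 1)
    res_eig = res_eig[res_eig > 1e-12 * max(tot, 1.0)]

    rng = np.random.default_rng(seed)
    rows = []
    df_res = n - p - 1
    ss_res_full = float((resid ** 2).sum())
    for j, v in enumerate(pred_cols):
        X_red = np.delete(X, j, axis=1)
        Yhat_red, resid_red = _rda_fit(Y, X_red)
        ss_gain = float((Yhat ** 2).sum()) - float((Yhat_red ** 2).sum())
        f_obs = (ss_gain / 1.0) / (ss_res_full / df_res)
        hits = 0
        for _ in range(n_perm):
            Y_star = Yhat_red + resid_red[rng.permutation(n)]
            Yh_f, rs_f = _rda_fit(Y_star, X)
            Yh_r, _ = _rda_fit(Y_star, X_red)
            gain = float((Yh_f ** 2).sum()) - float((Yh_r ** 2).sum())
            f_star = gain / (float((rs_f ** 2).sum()) / df_res)
            if f_star >= f_obs - 1e-12:
                hits += 1
        rows.append({"variable": v, "F": f_obs,
                     "p": (hits + 1) / (n_perm + 1)})
    anova = pd.DataFrame(rows).set_index("variable")

    return OrdinationResult(
        eigenvalues=eig[:k], residual_eigenvalues=res_eig,
        site_scores=sites,
        biplot_scores=pd.DataFrame(bip, index=pred_cols, columns=axes),
        total_inertia=tot, constrained_inertia=con,
        unconstrained_inertia=unc, r_squared=r2, adj_r_squared=adj,
        anova=anova, n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def mantel_test(dist_a: np.ndarray, dist_b: np.ndarray,
                n_perm: int = 9999, seed: int = 0) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    Pearson r over off-diagonal entries; the p-value permutes the rows and
    columns of the second matrix jointly.
    """
    A = np.asarray(dist_a, dtype=float)
    B = np.asarray(dist_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrices must be square and equal-sized")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise ValueError("distance matrices must be symmetric")
    if np.any(np.abs(np.diag(A)) > 1e-12) or np.any(np.abs(np.diag(B)) > 1e-12):
        raise ValueError("distance matrices must have zero diagonals")
    iu = np.triu_indices_from(A, k=1)
    a, b = A[iu], B[iu]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant distance matrix")
    r = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    n = A.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = B[np.ix_(perm, perm)][iu]
        if np.corrcoef(a, bp)[0, 1] >= r - 1e-12:
            hits += 1
    return r, (hits + 1) / (n_perm + 1)
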