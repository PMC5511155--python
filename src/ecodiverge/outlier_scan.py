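"""FST outlier detection by reversible-jump MCMC on a multinomial-Dirichlet model.

Each locus *l* in each population *j* has a locus-by-population divergence
parameter on the logit scale,

    logit(F_lj) = alpha_l * delta_l + beta_j,        theta_lj = 1/F_lj - 1,

where ``beta_j`` captures the population's shared drift from the common
ancestral gene pool, ``alpha_l`` is a locus-specific selection effect and
``delta_l`` is a binary inclusion indicator explored by reversible jump.
Observed allele counts are multinomial draws from population frequencies
that are themselves Dirichlet(theta_lj * p_l) around the ancestral
frequencies ``p_l``, so the marginal likelihood of the counts ``n_lj`` is
the multinomial-Dirichlet (Polya) form

    log L_lj = ln G(theta) - ln G(theta + n) + sum_a [ln G(theta p_a + n_a)
               - ln G(theta p_a)].

A positive posterior-mean alpha marks diversifying (positive) selection, a
negative one balancing selection.  Evidence per locus is the posterior
odds PO = P(delta=1)/(1 - P(delta=1)), and the q-value is the cumulative
mean of the posterior neutrality probabilities of all loci at least as
extreme (an FDR analogue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .genodata import MicrosatDataset, allele_count_table

PO_CAP = 9999.0


@dataclass
class OutlierChain:
    """Thinned rjMCMC output for the outlier scan."""

    locus_names: list[str]
    populations: list[str]
    alpha: np.ndarray            # retained x loci (alpha * delta)
    delta: np.ndarray            # retained x loci, 0/1
    beta: np.ndarray             # retained x pops
    loglik: np.ndarray           # retained
    acceptance: dict
    excluded: list[str]

    @property
    def inclusion_prob(self) -> np.ndarray:
        return self.delta.mean(axis=0)

    @property
    def mean_alpha(self) -> np.ndarray:
        return self.alpha.mean(axis=0)


@dataclass
class OutlierReport:
    """Per-locus evidence table and classes from a fitted chain."""

    table: pd.DataFrame          # locus, PO, mean_alpha, q_value, class

    @property
    def positive(self) -> list[str]:
        t = self.table
        return list(t.index[t["class"] == "positive"])

    @property
    def balancing(self) -> list[str]:
        t = self.table
        return list(t.index[t["class"] == "balancing"])

    @property
    def neutral(self) -> list[str]:
        t = self.table
        return list(t.index[t["class"] == "neutral"])


def _polya_loglik(counts, theta, p):
    """Multinomial-Dirichlet log likelihood for one locus across populations.

    ``counts``: (J, A) observed allele counts; ``theta``: (J,) precision;
    ``p``: (A,) ancestral frequencies.
    """
    n = counts.sum(axis=1)
    tp = theta[:, None] * p[None, :]
    return (gammaln(theta) - gammaln(theta + n)
            + (gammaln(tp + counts) - gammaln(tp)).sum(axis=1))


def _theta(alpha_eff, beta):
    """theta_lj from locus effects (L,) and population effects (J,)."""
    f = expit(alpha_eff[:, None] + beta[None, :])
    f = np.clip(f, 1e-12, 1.0 - 1e-12)
    return 1.0 / f - 1.0


def fit_outlier_scan(ds_or_counts, iterations: int = 100_000,
                     thinning: int = 1000, burn_in: int | None = None,
                     prior_odds: float = 10.0, seed: int = 0,
                     alpha_sd: float = 1.0, beta_sd: float = 1.0) -> OutlierChain:
    """Run the reversible-jump outlier scan.

    Parameters
    ----------
    ds_or_counts
        A :class:`MicrosatDataset`, or a ``(locus_names, populations,
        counts)`` triple with one (J, A_l) count matrix per locus.
    iterations, thinning
        Total MCMC iterations and the thinning interval for retained states.
    burn_in
        Iterations discarded before thinning (default ``iterations // 10``).
    prior_odds
        Prior odds for neutrality (10 means P(delta=1) = 1/11 a priori).
    alpha_sd, beta_sd
        Scales of the Normal(0, sd) priors on alpha and beta.

    Loci monomorphic across all populations carry no information on
    divergence and are excluded with a warning.
    """
    if isinstance(ds_or_counts, MicrosatDataset):
        pops, counts = allele_count_table(ds_or_counts, by="population")
        locus_names = list(ds_or_counts.locus_names)
    else:
        locus_names, pops, counts = ds_or_counts
        locus_names = list(locus_names)
    if len(pops) < 2:
        raise ValueError("outlier scan needs >= 2 populations (F_ST undefined)")
    if prior_odds <= 0:
        raise ValueError("prior_odds must be positive")
    keep_idx, excluded = [], []
    for l, c in enumerate(counts):
        if c.shape[1] < 2:
            excluded.append(locus_names[l])
        else:
            keep_idx.append(l)
    if excluded:
        warnings.warn(f"excluding monomorphic loci: {excluded}")
    counts = [np.asarray(counts[l], dtype=float) for l in keep_idx]
    locus_names = [locus_names[l] for l in keep_idx]
    L, J = len(counts), len(pops)
    if L < 2:
        raise ValueError("outlier scan needs >= 2 informative loci")
    if burn_in is None:
        burn_in = iterations // 10

    rng = np.random.default_rng(seed)
    log_incl = np.log(1.0 / prior_odds)      # prior log odds of inclusion

    # state
    p = [c.sum(axis=0) + 1.0 for c in counts]
    p = [v / v.sum() for v in p]
    alpha = np.zeros(L)
    delta = np.zeros(L, dtype=bool)
    beta = np.full(J, -1.0)

    def row_ll(l, p_l=None, a_eff=None, b=None):
        p_l = p[l] if p_l is None else p_l
        a = (alpha[l] if delta[l] else 0.0) if a_eff is None else a_eff
        b = beta if b is None else b
        f = np.clip(expit(a + b), 1e-12, 1 - 1e-12)
        return _polya_loglik(counts[l], 1.0 / f - 1.0, p_l).sum()

    ll = np.array([row_ll(l) for l in range(L)])
    prop_conc = 60.0
    acc = {"p": 0, "alpha": 0, "rj": 0, "beta": 0}
    tries = {"p": 0, "alpha": 0, "rj": 0, "beta": 0}

    n_keep = max((iterations - burn_in) // thinning, 1)
    alpha_out = np.zeros((n_keep, L))
    delta_out = np.zeros((n_keep, L), dtype=np.int8)
    beta_out = np.zeros((n_keep, J))
    ll_out = np.zeros(n_keep)
    k_out = 0

    from scipy.stats import dirichlet as _dir

    for it in range(iterations):
        # ancestral frequencies, one Dirichlet-proposal MH step per locus
        for l in range(L):
            conc_fwd = prop_conc * p[l] + 0.5
            p_new = rng.dirichlet(conc_fwd)
            p_new = np.clip(p_new, 1e-12, None)
            p_new = p_new / p_new.sum()
            conc_rev = prop_conc * p_new + 0.5
            ll_new = row_ll(l, p_l=p_new)
            log_h = (_dir.logpdf(p[l], conc_rev)
                     - _dir.logpdf(p_new, conc_fwd))
            tries["p"] += 1
            if np.log(rng.random()) < ll_new - ll[l] + log_h:
                p[l] = p_new
                ll[l] = ll_new
                acc["p"] += 1
        # alpha random walk (included loci only)
        for l in range(L):
            if not delta[l]:
                continue
            a_new = alpha[l] + rng.normal(0.0, 0.4)
            ll_new = row_ll(l, a_eff=a_new + 0.0)
            lp = -0.5 * (a_new ** 2 - alpha[l] ** 2) / alpha_sd ** 2
            tries["alpha"] += 1
            if np.log(rng.random()) < ll_new - ll[l] + lp:
                alpha[l] = a_new
                ll[l] = ll_new
                acc["alpha"] += 1
        # reversible jump: toggle inclusion, proposing alpha from its prior
        for l in range(L):
            tries["rj"] += 1
            if delta[l]:
                ll_new = row_ll(l, a_eff=0.0)
                if np.log(rng.random()) < ll_new - ll[l] - log_incl:
                    delta[l] = False
                    ll[l] = ll_new
                    acc["rj"] += 1
            else:
                a_new = rng.normal(0.0, alpha_sd)
                ll_new = row_ll(l, a_eff=a_new)
                if np.log(rng.random()) < ll_new - ll[l] + log_incl:
                    delta[l] = True
                    alpha[l] = a_new
                    ll[l] = ll_new
                    acc["rj"] += 1
        # beta random walk, one population at a time
        for j in range(J):
            b_new = beta.copy()
            b_new[j] += rng.normal(0.0, 0.25)
            ll_new = np.array([row_ll(l, b=b_new) for l in range(L)])
            lp = -0.5 * (b_new[j] ** 2 - beta[j] ** 2) / beta_sd ** 2
            tries["beta"] += 1
            if np.log(rng.random()) < ll_new.sum() - ll.sum() + lp:
                beta = b_new
                ll = ll_new
                acc["beta"] += 1
        if not np.isfinite(ll).all():
            raise FloatingPointError(
                f"non-finite likelihood at iteration {it}: "
                f"alpha={alpha}, beta={beta}")
        if it >= burn_in and (it - burn_in) % thinning == thinning - 1 \
                and k_out < n_keep:
            alpha_out[k_out] = np.where(delta, alpha, 0.0)
            delta_out[k_out] = delta
            beta_out[k_out] = beta
            ll_out[k_out] = ll.sum()
            k_out += 1

    rates = {k: acc[k] / max(tries[k], 1) for k in acc}
    return OutlierChain(locus_names, list(pops),
                        alpha_out[:k_out], delta_out[:k_out],
                        beta_out[:k_out], ll_out[:k_out], rates, excluded)


def classify_outliers(chain: OutlierChain, po_threshold: float = 10.0,
                      q_threshold: float = 0.05) -> OutlierReport:
    """Posterior odds, q-values and selection classes from a fitted chain.

    A locus is flagged when PO exceeds ``po_threshold`` and its q-value is
    below ``q_threshold``; the sign of the posterior mean alpha separates
    positive (diversifying) from balancing selection.
    """
    if not po_threshold > 0:
        raise ValueError("po_threshold must be in (0, inf)")
    if not 0 < q_threshold < 1:
        raise ValueError("q_threshold must be in (0, 1)")
    if chain.delta.shape[0] < 2:
        raise ValueError("need >= 2 retained states to classify")
    p_incl = chain.inclusion_prob
    with np.errstate(divide="ignore"):
        po = np.where(p_incl >= 1.0, PO_CAP,
                      p_incl / np.where(p_incl >= 1.0, 1.0, 1.0 - p_incl))
    po = np.minimum(po, PO_CAP)
    p_neutral = 1.0 - p_incl
    order = np.argsort(p_neutral, kind="stable")
    q = np.empty_like(p_neutral)
    q[order] = np.cumsum(p_neutral[order]) / np.arange(1, len(order) + 1)
    q = np.minimum(q, 1.0)
    mean_a = chain.mean_alpha
    cls = np.where((po > po_threshold) & (q < q_threshold),
                   np.where(mean_a > 0, "positive", "balancing"),
                   "neutral")
    tab = pd.DataFrame({
        "PO": po, "mean_alpha": mean_a, "q_value": q, "class": cls,
    }, index=pd.Index(chain.locus_names, name="locus"))
    return OutlierReport(tab)
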