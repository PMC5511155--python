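"""Two-deme structured-coalescent simulator for microsatellite loci.

The demographic model is a pair of present-day demes (sizes ``n1``, ``n2``
diploids) that merge, backwards in time, into a single ancestral deme of
size ``n_anc`` at the split time ``t2`` generations before present.  Gene
flow between the demes is active on a scenario-dependent backward-time
window:

* ``CI``  complete isolation - no migration at any time;
* ``AM``  ancestral migration - gene flow only early in divergence,
  i.e. on the backward window ``[t1, t2]``;
* ``SC``  secondary contact - gene flow only late in divergence,
  backward window ``[0, t1]``;
* ``CM``  continuous migration - window ``[0, t2]``.

Migration parameters ``m12``/``m21`` are forward-time immigrant fractions
(the fraction of a deme's individuals that are new immigrants each
generation); the backward lineage-migration rate is set equal to the
forward fraction (the standard low-migration identification).  Time is in
generations throughout (the study species are annual herbs, so generations
and years coincide).

Mutation follows the generalised stepwise model: per-branch mutation
counts are Poisson(mu * branch length) and each mutation shifts the allele
state by +-k, with k geometric with parameter ``p_geom`` (``p_geom = 0``
is the strict single-step model).  The allele ladder is unbounded; states
start from 100 repeat units at the root.

Inbreeding is emulated at the sampling stage: with probability ``f_is`` an
individual's second gene copy is replaced by a duplicate of its first at
all loci, mimicking the excess homozygosity of selfing lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .genodata import MicrosatDataset

MODELS = ("CI", "AM", "SC", "CM")

#: study-shaped sampling design: (population, species, deme index, diploids)
DEFAULT_SAMPLES = (
    ("wutai", "pla", 0, 10),
    ("wulu_pla", "pla", 0, 19),
    ("wulu_tas", "tas", 1, 22),
    ("lanyu", "tas", 1, 15),
    ("taroko", "tas", 1, 15),
)


@dataclass
class ScenarioSpec:
    """One divergence scenario with demographic and mutational parameters."""

    model: str = "AM"
    n1: float = 1000.0            # diploid effective size, deme 0
    n2: float = 1000.0            # diploid effective size, deme 1
    n_anc: float = 1000.0
    t2: float = 1.1e5             # split time, generations
    t1: float = 5e4               # migration-epoch boundary, generations
    m12: float = 0.0              # immigrant fraction into deme 0
    m21: float = 0.0              # immigrant fraction into deme 1
    mu: float = 3e-4              # per-locus mutation rate
    p_geom: float = 0.0           # geometric step parameter (0 = strict SMM)
    f_is: float = 0.0             # within-individual inbreeding probability
    samples: tuple = DEFAULT_SAMPLES

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if not 0.0 <= self.t1 <= self.t2:
            raise ValueError("need 0 <= t1 <= t2")
        if min(self.m12, self.m21, self.mu) < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.p_geom < 1.0:
            raise ValueError("p_geom must lie in [0, 1)")
        if not 0.0 <= self.f_is <= 1.0:
            raise ValueError("f_is must lie in [0, 1]")
        for _, _, deme, n in self.samples:
            if deme not in (0, 1):
                raise ValueError("deme index must be 0 or 1")
            if n < 1:
                raise ValueError("zero sample size in a sampled deme")

    def copies_per_deme(self) -> tuple[int, int]:
        n0 = sum(2 * n for _, _, d, n in self.samples if d == 0)
        n1 = sum(2 * n for _, _, d, n in self.samples if d == 1)
        return n0, n1


def migration_epochs(spec: ScenarioSpec):
    """Backward-time migration windows as (start, end, m_into_deme0, m_into_deme1).

    An empty window (start == end) is dropped, so AM with t1 = t2, SC with
    t1 = 0 and CM with zero rates all reduce to the CI event schedule.
    """
    if spec.model == "CI":
        win = None
    elif spec.model == "AM":
        win = (spec.t1, spec.t2)
    elif spec.model == "SC":
        win = (0.0, spec.t1)
    else:  # CM
        win = (0.0, spec.t2)
    if win is None or win[0] >= win[1]:
        return []
    return [(win[0], win[1], spec.m12, spec.m21)]


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _pick_in_deme(act_deme, k, deme, j):
    """Index of the j-th active lineage currently in `deme`."""
    c = -1
    for i in range(k):
        if act_deme[i] == deme:
            c += 1
            if c == j:
                return i
    return -1


@njit(cache=True)
def _simulate_locus(n0, n1, N1, N2, Nanc, t2, w_lo, w_hi, mb0, mb1,
                    mu, p_geom):
    """One locus: coalescent with piecewise migration, then GSM mutations.

    Returns the allele states of the n0 + n1 sampled gene copies (deme-0
    copies first).
    """
    n = n0 + n1
    n_nodes = 2 * n - 1
    time = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    act_node = np.empty(n_nodes, dtype=np.int64)
    act_deme = np.empty(n_nodes, dtype=np.int8)
    for i in range(n0):
        act_node[i] = i
        act_deme[i] = 0
    for i in range(n1):
        act_node[n0 + i] = n0 + i
        act_deme[n0 + i] = 1
    k = n
    nxt = n
    t = 0.0
    merged = False
    while k > 1:
        if not merged and t >= t2:
            for i in range(k):
                act_deme[i] = 0
            merged = True
        if merged:
            rate = k * (k - 1) / 2.0 / (2.0 * Nanc)
            t += np.random.exponential(1.0 / rate)
            # coalesce two uniform lineages
            i1 = np.random.randint(k)
            i2 = np.random.randint(k - 1)
            if i2 >= i1:
                i2 += 1
            ev_deme = 0
        else:
            k0 = 0
            for i in range(k):
                if act_deme[i] == 0:
                    k0 += 1
            k1 = k - k0
            mig_on = (t >= w_lo) and (t < w_hi)
            # next schedule boundary
            tb = t2
            if t < w_lo and w_lo < tb:
                tb = w_lo
            if mig_on and w_hi < tb:
                tb = w_hi
            c0 = k0 * (k0 - 1) / 2.0 / (2.0 * N1)
            c1 = k1 * (k1 - 1) / 2.0 / (2.0 * N2)
            mA = k0 * mb0 if mig_on else 0.0
            mB = k1 * mb1 if mig_on else 0.0
            tot = c0 + c1 + mA + mB
            if tot == 0.0:
                t = tb
                continue
            dt = np.random.exponential(1.0 / tot)
            if t + dt >= tb:
                t = tb
                continue
            t += dt
            u = np.random.random() * tot
            if u < mA:
                j = np.random.randint(k0)
                act_deme[_pick_in_deme(act_deme, k, 0, j)] = 1
                continue
            elif u < mA + mB:
                j = np.random.randint(k1)
                act_deme[_pick_in_deme(act_deme, k, 1, j)] = 0
                continue
            elif u < mA + mB + c0:
                ev_deme = 0
                kd = k0
            else:
                ev_deme = 1
                kd = k1
            j1 = np.random.randint(kd)
            j2 = np.random.randint(kd - 1)
            if j2 >= j1:
                j2 += 1
            i1 = _pick_in_deme(act_deme, k, ev_deme, j1)
            i2 = _pick_in_deme(act_deme, k, ev_deme, j2)
        # coalescence of active slots i1, i2
        time[nxt] = t
        parent[act_node[i1]] = nxt
        parent[act_node[i2]] = nxt
        lo, hi = (i1, i2) if i1 < i2 else (i2, i1)
        act_node[lo] = nxt
        act_deme[lo] = np.int8(ev_deme)
        act_node[hi] = act_node[k - 1]
        act_deme[hi] = act_deme[k - 1]
        k -= 1
        nxt += 1
    # mutation pass, root down (parent index always exceeds child index)
    state = np.empty(n_nodes, dtype=np.int64)
    state[n_nodes - 1] = 100
    for j in range(n_nodes - 2, -1, -1):
        lam = mu * (time[parent[j]] - time[j])
        nm = np.random.poisson(lam)
        net = 0
        for _ in range(nm):
            if p_geom > 0.0:
                step = np.random.geometric(1.0 - p_geom)
            else:
                step = 1
            if np.random.random() < 0.5:
                net += step
            else:
                net -= step
        state[j] = state[parent[j]] + net
    return state[:n]


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_locus_states(spec: ScenarioSpec, seed: int) -> np.ndarray:
    """Allele states of all sampled gene copies at a single locus."""
    n0, n1 = spec.copies_per_deme()
    epochs = migration_epochs(spec)
    if epochs:
        w_lo, w_hi, m12, m21 = epochs[0]
    else:
        w_lo = w_hi = m12 = m21 = 0.0
    _seed(int(seed) % (2 ** 31))
    return _simulate_locus(n0, n1, spec.n1, spec.n2, spec.n_anc,
                           spec.t2, w_lo, w_hi, m12, m21,
                           spec.mu, spec.p_geom)


def simulate_dataset(spec: ScenarioSpec, n_loci: int, seed: int,
                     locus_names=None) -> MicrosatDataset:
    """Simulate a diploid microsatellite dataset under one scenario.

    Deterministic given ``(spec, n_loci, seed)``.  Copies are paired into
    diploids within demes; inbred individuals (probability ``f_is``) carry
    a duplicated first copy at every locus.
    """
    if spec.mu < 0:
        raise ValueError("mu must be >= 0")
    n0, n1 = spec.copies_per_deme()
    if n0 + n1 < 2:
        raise ValueError("need at least 2 sampled copies")
    epochs = migration_epochs(spec)
    if epochs:
        w_lo, w_hi, m12, m21 = epochs[0]
    else:
        w_lo = w_hi = m12 = m21 = 0.0
    _seed(int(seed) % (2 ** 31))
    n_ind = sum(n for _, _, _, n in spec.samples)
    alleles = np.empty((n_ind, n_loci, 2), dtype=np.int32)
    # assemble individual metadata in deme order (deme-0 copies come first)
    order = sorted(range(len(spec.samples)), key=lambda i: spec.samples[i][2])
    ids, pops, sps = [], [], []
    for i in order:
        pop, sp, _, nn = spec.samples[i]
        for j in range(nn):
            ids.append(f"{pop}_{j + 1:02d}")
            pops.append(pop)
            sps.append(sp)
    for l in range(n_loci):
        states = _simulate_locus(n0, n1, spec.n1, spec.n2, spec.n_anc,
                                 spec.t2, w_lo, w_hi, m12, m21,
                                 spec.mu, spec.p_geom)
        alleles[:, l, 0] = states[0::2]
        alleles[:, l, 1] = states[1::2]
    if spec.f_is > 0:
        rng = np.random.default_rng(int(seed) % (2 ** 31))
        inbred = rng.random(n_ind) < spec.f_is
        alleles[inbred, :, 1] = alleles[inbred, :, 0]
    names = list(locus_names) if locus_names is not None else \
        [f"loc{l + 1:02d}" for l in range(n_loci)]
    return MicrosatDataset(ids, np.array(pops, dtype=object),
                           np.array(sps, dtype=object), names, alleles)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Declared priors for scenario parameters.

    Each entry is ``(kind, lo, hi)`` with kind in {"uniform", "loguniform",
    "point"}; ``t1`` uses kind "frac_of_t2" (uniform fraction of the drawn
    t2, enforcing t1 <= t2).
    """

    params: dict = field(default_factory=lambda: dict(DEFAULT_PRIORS))

    def __post_init__(self) -> None:
        for name, (kind, lo, hi) in self.params.items():
            if kind not in ("uniform", "loguniform", "point", "frac_of_t2"):
                raise ValueError(f"unknown prior kind {kind!r} for {name}")
            if kind != "point" and lo > hi:
                raise ValueError(f"inverted bounds for {name}")
            if kind == "loguniform" and lo <= 0:
                raise ValueError(f"log-uniform bounds must be positive ({name})")


DEFAULT_PRIORS = {
    "n1": ("loguniform", 100.0, 2000.0),
    "n2": ("loguniform", 100.0, 2000.0),
    "n_anc": ("loguniform", 100.0, 2000.0),
    "t2": ("uniform", 2e4, 4e5),
    "t1": ("frac_of_t2", 0.0, 1.0),
    "m12": ("loguniform", 1e-3, 0.15),
    "m21": ("loguniform", 1e-3, 0.15),
    "mu": ("loguniform", 1e-4, 1e-3),
}


def draw_from_priors(model: str, n_draws: int, seed: int,
                     priors: PriorSpec | None = None,
                     base: ScenarioSpec | None = None) -> list[ScenarioSpec]:
    """Reproducible i.i.d. scenario draws for one model.

    CI draws force ``m12 = m21 = 0`` and ``t1 = 0``; migration models draw
    the rates from their priors and t1 as a uniform fraction of t2.
    """
    if priors is None:
        priors = PriorSpec()
    if base is None:
        base = ScenarioSpec(model=model)
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    out = []
    for _ in range(n_draws):
        vals = {}
        for name, (kind, lo, hi) in priors.params.items():
            if kind == "point":
                vals[name] = lo
            elif kind == "uniform":
                vals[name] = rng.uniform(lo, hi)
            elif kind == "loguniform":
                vals[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            elif kind == "frac_of_t2":
                vals[name] = rng.uniform(lo, hi)  # fraction; resolved below
        t2 = vals.get("t2", base.t2)
        t1 = vals.get("t1", 0.5) * t2
        if model == "CI":
            m12 = m21 = 0.0
            t1 = 0.0
        else:
            m12 = vals.get("m12", base.m12)
            m21 = vals.get("m21", base.m21)
        if model == "CM":
            t1 = 0.0  # unused by the CM window
        out.append(replace(
            base, model=model,
            n1=vals.get("n1", base.n1), n2=vals.get("n2", base.n2),
            n_anc=vals.get("n_anc", base.n_anc),
            t2=t2, t1=t1, m12=m12, m21=m21,
            mu=vals.get("mu", base.mu),
        ))
    return out
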