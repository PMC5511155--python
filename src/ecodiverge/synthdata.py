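"""Study-shaped synthetic fixtures with known ground truth.

Generates the three data products the pipeline consumes:

* a genotype fixture: two species, five populations (10, 19, 22, 15, 15
  diploids), coalescent-simulated neutral loci plus planted outlier loci
  (positive outliers get a species-specific allele-size offset creating
  near-fixed differences; balancing outliers get their copies shuffled
  across all individuals, erasing structure).  Outliers are planted by
  frequency manipulation, not by simulating selection - they are labels
  with known truth, not a biological claim;
* an environment fixture: correlated Gaussian variables whose species
  difference lies along one declared linear combination, so that no single
  variable separates the species but the first principal component does;
* an occurrence fixture: point records with planted within-grid-cell
  duplicates and a deduplication operation.

Every fixture is a pure function of (config, seed) and serialises its
ground truth alongside the data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coalsim import ScenarioSpec, simulate_dataset
from .genodata import LocusPartition, MicrosatDataset
from .popgen_stats import diversity_table


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeFixtureConfig:
    """Configuration of the genotype fixture.

    The default scenario is ancestral migration at the printed scale of the
    study system: split ~1.1e5 generations ago, gene flow of ~0.1
    immigrants per individual per generation during the early window, and
    mutation/drift scaled to give expected heterozygosity in the 0.23-0.37
    band with fixation indices in the 0.39-0.73 band.
    """

    scenario: ScenarioSpec = field(default_factory=lambda: ScenarioSpec(
        model="AM", n1=1000.0, n2=1000.0, n_anc=1000.0,
        t2=1.1e5, t1=5.5e4, m12=0.1, m21=0.1,
        mu=1.5e-4, p_geom=0.0, f_is=0.6,
    ))
    n_neutral: int = 15
    positive_outliers: tuple = ("aus9-2", "aus9-3", "aus9-5")
    balancing_outliers: tuple = ("aus9-4",)
    outlier_offset: int = 12          # repeat-unit shift planted in species 2
    he_band: tuple = (0.23, 0.37)
    f_band: tuple = (0.39, 0.73)
    max_retries: int = 5


@dataclass
class StudyFixture:
    """A generated dataset plus its serialised ground truth."""

    dataset: MicrosatDataset
    partition: LocusPartition
    scenario: ScenarioSpec
    truth: dict
    env_populations: pd.DataFrame | None = None
    env_occurrences: pd.DataFrame | None = None

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=2, default=str)


def make_genotype_fixture(config: GenotypeFixtureConfig | None = None,
                          seed: int = 0) -> StudyFixture:
    """Coalescent genotypes with planted outlier loci and diversity checks.

    Neutral loci come straight from the scenario; positive outliers add a
    fixed allele-size offset to all copies of the second species; the
    balancing outlier's copies are shuffled across all individuals.  If the
    realised neutral He or F falls outside the configured bands the fixture
    is re-drawn (up to ``max_retries``), then errors with the realised
    values.
    """
    cfg = config or GenotypeFixtureConfig()
    n_out = len(cfg.positive_outliers) + len(cfg.balancing_outliers)
    names = ([f"loc{i + 1:02d}" for i in range(cfg.n_neutral)]
             + list(cfg.positive_outliers) + list(cfg.balancing_outliers))
    last = None
    for attempt in range(cfg.max_retries):
        sub_seed = (seed + attempt * 10007) % (2 ** 31)
        ds = simulate_dataset(cfg.scenario, cfg.n_neutral + n_out, sub_seed,
                              locus_names=names)
        rng = np.random.default_rng(sub_seed + 1)
        sp2 = ds.species == ds.species_levels[1]
        for j, nm in enumerate(cfg.positive_outliers):
            # species-private fixed homozygous alleles (maximal divergence,
            # matching the all-homozygous outliers the scan should flag)
            l = cfg.n_neutral + j
            ds.alleles[:, l, :] = 100 + j
            ds.alleles[sp2, l, :] = 100 + j + cfg.outlier_offset
        for j, nm in enumerate(cfg.balancing_outliers):
            l = cfg.n_neutral + len(cfg.positive_outliers) + j
            flat = ds.alleles[:, l, :].reshape(-1)
            ds.alleles[:, l, :] = rng.permutation(flat).reshape(-1, 2)
        neutral = ds.subset_loci(names[:cfg.n_neutral])
        div = diversity_table(neutral)
        he, f = float(div["He"].mean()), float(div["F"].mean())
        last = (he, f)
        if cfg.he_band[0] <= he <= cfg.he_band[1] \
                and cfg.f_band[0] <= f <= cfg.f_band[1]:
            break
        warnings.warn(f"fixture attempt {attempt}: He={he:.3f} F={f:.3f} "
                      "outside bands; redrawing")
    else:
        raise RuntimeError(
            f"diversity band unreachable after {cfg.max_retries} tries: "
            f"realised He={last[0]:.3f}, F={last[1]:.3f}")
    part = LocusPartition(
        neutral=set(names[:cfg.n_neutral]),
        positive_outliers=set(cfg.positive_outliers),
        balancing_outliers=set(cfg.balancing_outliers),
    )
    truth = {
        "scenario": asdict(cfg.scenario),
        "neutral_loci": sorted(part.neutral),
        "positive_outliers": sorted(part.positive_outliers),
        "balancing_outliers": sorted(part.balancing_outliers),
        "realised_mean_He": last[0], "realised_mean_F": last[1],
        "seed": seed,
    }
    return StudyFixture(ds, part, cfg.scenario, truth)


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

#: realistic scales for the study's five retained variables
ENV_SCALES = {
    "alt": (600.0, 350.0),     # elevation, m
    "AET": (950.0, 120.0),     # actual evapotranspiration, mm/yr
    "bio3": (58.0, 4.0),       # isothermality, %
    "bio13": (480.0, 90.0),    # precipitation of wettest month, mm
    "bio14": (35.0, 18.0),     # precipitation of driest month, mm
}


@dataclass
class EnvFixtureConfig:
    variables: tuple = ("alt", "AET", "bio3", "bio13", "bio14")
    #: unit-norm direction of the species mean shift (standardised space)
    shift_direction: tuple = (1.0, -1.0, 1.0, -1.0, 1.0)
    #: separation along the direction, in latent sd units.  The factor
    #: loading sets how much within-species variance the shared axis
    #: carries: the species separation on that axis is
    #: shift_size/sqrt(1 + factor_loading) (~1.85 sd here, enough to power
    #: a rank test at n ~ 39), while each variable's partial effect scales
    #: as shift_size/(1 + factor_loading) and stays individually
    #: undetectable - the planted "integrated niche axis" pattern.
    shift_size: float = 11.0
    factor_loading: float = 35.0
    n_occ: tuple = (23, 16)            # records per species
    species: tuple = ("pla", "tas")
    populations: tuple = ("wutai", "wulu_pla", "wulu_tas", "lanyu", "taroko")
    pop_species: tuple = ("pla", "pla", "tas", "tas", "tas")
    pop_jitter: float = 0.5
    decoy_duplicate: str | None = None  # name of a variable to duplicate

    def direction(self) -> np.ndarray:
        w = np.asarray(self.shift_direction, dtype=float)
        if len(w) != len(self.variables):
            raise ValueError("shift_direction length must match variables")
        return w / np.linalg.norm(w)


def _env_cov(cfg: EnvFixtureConfig) -> np.ndarray:
    w = cfg.direction()
    cov = np.eye(len(cfg.variables)) + cfg.factor_loading * np.outer(w, w)
    evals = np.linalg.eigvalsh(cov)
    if evals.min() <= 0:
        raise ValueError("non-positive-definite covariance target")
    return cov


def make_env_fixture(config: EnvFixtureConfig | None = None,
                     seed: int = 0) -> dict:
    """Environmental tables with a planted species shift along one axis.

    Returns a dict with ``occurrences`` (one row per occurrence record),
    ``populations`` (one row per sampled population) and ``truth``.
    """
    cfg = config or EnvFixtureConfig()
    if len(cfg.variables) < 5:
        raise ValueError("need >= 5 configured variables")
    rng = np.random.default_rng(seed)
    w = cfg.direction()
    cov = _env_cov(cfg)
    chol = np.linalg.cholesky(cov)
    half = cfg.shift_size / 2.0

    def draw(n, sign):
        z = rng.standard_normal((n, len(cfg.variables))) @ chol.T
        return z + sign * half * w

    occ_rows = []
    for sp, n, sign in zip(cfg.species, cfg.n_occ, (-1.0, 1.0)):
        Z = draw(n, sign)
        for i in range(n):
            row = {"species": sp}
            for j, v in enumerate(cfg.variables):
                mu, sd = ENV_SCALES.get(v, (0.0, 1.0))
                row[v] = mu + sd * Z[i, j]
            occ_rows.append(row)
    occurrences = pd.DataFrame(occ_rows)

    pop_rows = []
    for pop, sp in zip(cfg.populations, cfg.pop_species):
        sign = -1.0 if sp == cfg.species[0] else 1.0
        z = (rng.standard_normal(len(cfg.variables)) @ chol.T) \
            * cfg.pop_jitter + sign * half * w
        row = {"population": pop, "species": sp}
        for j, v in enumerate(cfg.variables):
            mu, sd = ENV_SCALES.get(v, (0.0, 1.0))
            row[v] = mu + sd * z[j]
        pop_rows.append(row)
    populations = pd.DataFrame(pop_rows).set_index("population")

    if cfg.decoy_duplicate is not None:
        occurrences[cfg.decoy_duplicate + "_dup"] = \
            occurrences[cfg.decoy_duplicate]
        populations[cfg.decoy_duplicate + "_dup"] = \
            populations[cfg.decoy_duplicate]

    truth = {
        "shift_direction": list(w), "shift_size": cfg.shift_size,
        "variables": list(cfg.variables), "seed": seed,
        "decoy_duplicate": cfg.decoy_duplicate,
    }
    return {"occurrences": occurrences, "populations": populations,
            "truth": truth}


def env_for_individuals(ds: MicrosatDataset,
                        env_pop: pd.DataFrame) -> pd.DataFrame:
    """Individuals inherit their population's environmental values."""
    missing = [p for p in ds.populations if p not in env_pop.index]
    if missing:
        raise ValueError(f"populations missing from env table: {missing}")
    rows = env_pop.loc[list(ds.population)].reset_index(drop=True)
    rows.index = pd.Index(ds.individual_ids, name="individual")
    return rows


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceFixtureConfig:
    n_points: int = 100
    n_duplicate_clusters: int = 10
    lon_range: tuple = (120.0, 122.0)
    lat_range: tuple = (21.8, 25.3)
    grid: float = 0.0083              # ~1 km in degrees
    species: tuple = ("pla", "tas")

    def __post_init__(self) -> None:
        if self.grid <= 0:
            raise ValueError("grid size must be > 0")


def make_occurrence_fixture(config: OccurrenceFixtureConfig | None = None,
                            seed: int = 0) -> pd.DataFrame:
    """Occurrence records with planted within-cell duplicates."""
    cfg = config or OccurrenceFixtureConfig()
    rng = np.random.default_rng(seed)
    lon = rng.uniform(*cfg.lon_range, cfg.n_points)
    lat = rng.uniform(*cfg.lat_range, cfg.n_points)
    sp = rng.choice(list(cfg.species), cfg.n_points)
    rows = pd.DataFrame({"species": sp, "lon": lon, "lat": lat})
    dups = []
    for _ in range(cfg.n_duplicate_clusters):
        i = int(rng.integers(cfg.n_points))
        jitter = (rng.random(2) - 0.5) * cfg.grid * 0.5
        dups.append({"species": rows.species[i],
                     "lon": rows.lon[i] + jitter[0],
                     "lat": rows.lat[i] + jitter[1]})
    return pd.concat([rows, pd.DataFrame(dups)], ignore_index=True)


def dedup_occurrences(occ: pd.DataFrame, grid: float = 0.0083) -> pd.DataFrame:
    """Keep one record per species per grid cell (first record wins)."""
    if grid <= 0:
        raise ValueError("grid size must be > 0")
    out = occ.copy()
    cx = np.floor(out["lon"].to_numpy() / grid).astype(int)
    cy = np.floor(out["lat"].to_numpy() / grid).astype(int)
    key = pd.Series(list(zip(out["species"], cx, cy)), index=out.index)
    out["retained"] = ~key.duplicated()
    return out
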