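"""Data model and text I/O for diploid microsatellite genotypes.

Allele states are small positive integers in repeat-count units; the
downstream statistics and the coalescent simulator only ever use allele
identities and differences, so fragment lengths and repeat counts are
interchangeable up to a per-locus offset.  Missing gene copies are stored
as the sentinel :data:`MISSING` (a reserved negative state).

Supported text formats: GenePop (3-digit diploid codes, ``000`` missing),
STRUCTURE matrices (one or two rows per individual, ``-9`` missing), and a
grouping CSV (individual, population, species) that supplies the species
level GenePop lacks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel allele state for a missing gene copy.
MISSING: int = -9


class GenotypeParseError(ValueError):
    """Raised when a genotype file is malformed; the message names the line."""


@dataclass
class MicrosatDataset:
    """Diploid allele-size matrix with individual/population/species labels.

    Parameters
    ----------
    individual_ids
        One label per sampled individual.
    population
        Population label per individual.
    species
        Species label per individual.  Every population must map to exactly
        one species.
    locus_names
        One name per locus.
    alleles
        Integer array of shape ``(n_individuals, n_loci, 2)``; non-missing
        states are positive integers, missing copies are :data:`MISSING`.
    """

    individual_ids: list[str]
    population: np.ndarray
    species: np.ndarray
    locus_names: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=object)
        self.species = np.asarray(self.species, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        n, L = len(self.individual_ids), len(self.locus_names)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        if len(self.population) != n or len(self.species) != n:
            raise ValueError("population/species labels must match individuals")
        if len(set(self.locus_names)) != L:
            raise ValueError("duplicated locus name")
        obs = self.alleles[self.alleles != MISSING]
        if obs.size and obs.min() < 1:
            raise ValueError("non-missing allele states must be positive integers")
        # one species per population
        for pop in self.populations:
            sp = set(self.species[self.population == pop])
            if len(sp) > 1:
                raise ValueError(f"population {pop!r} maps to multiple species {sp}")

    # ------------------------------------------------------------------ views
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def populations(self) -> list:
        """Population labels in order of first appearance."""
        return list(pd.unique(self.population))

    @property
    def species_levels(self) -> list:
        return list(pd.unique(self.species))

    def pop_of_species(self, sp) -> list:
        return [p for p in self.populations
                if self.species[self.population == p][0] == sp]

    def pop_indices(self, pop) -> np.ndarray:
        return np.flatnonzero(self.population == pop)

    def subset_loci(self, names) -> "MicrosatDataset":
        names = list(names)
        idx = [self.locus_names.index(nm) for nm in names]
        return MicrosatDataset(
            individual_ids=list(self.individual_ids),
            population=self.population.copy(),
            species=self.species.copy(),
            locus_names=names,
            alleles=self.alleles[:, idx, :].copy(),
        )

    def subset_individuals(self, idx) -> "MicrosatDataset":
        idx = np.asarray(idx)
        return MicrosatDataset(
            individual_ids=[self.individual_ids[i] for i in idx],
            population=self.population[idx].copy(),
            species=self.species[idx].copy(),
            locus_names=list(self.locus_names),
            alleles=self.alleles[idx].copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MicrosatDataset):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and list(self.population) == list(other.population)
            and list(self.species) == list(other.species)
            and self.locus_names == other.locus_names
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class LocusPartition:
    """Disjoint split of loci into neutral and outlier classes."""

    neutral: set = field(default_factory=set)
    positive_outliers: set = field(default_factory=set)
    balancing_outliers: set = field(default_factory=set)

    def __post_init__(self) -> None:
        sets = [self.neutral, self.positive_outliers, self.balancing_outliers]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("locus classes must be disjoint")

    @property
    def outliers(self) -> set:
        return self.positive_outliers | self.balancing_outliers


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def read_genepop(path, grouping: str | None = None) -> MicrosatDataset:
    """Read a GenePop file (3-digit diploid codes, ``000`` = missing).

    Populations are labelled ``pop1..popK`` in file order unless a grouping
    CSV (columns individual, population, species) is supplied, in which case
    labels come from it.  Without a grouping file every population is
    assigned the placeholder species ``"sp"``.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise GenotypeParseError("file too short for GenePop format")
    # locus names: either one per line until 'Pop', or comma separated
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = [x.strip() for x in lines[i].split(",") if x.strip()]
        locus_names.extend(part)
        i += 1
    if len(set(locus_names)) != len(locus_names):
        raise GenotypeParseError("duplicated locus name in header")
    L = len(locus_names)
    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    pop_no = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_no += 1
            i += 1
            continue
        ln = lines[i]
        if not ln.strip():
            i += 1
            continue
        if "," not in ln:
            raise GenotypeParseError(f"line {i + 1}: expected 'name , genotypes'")
        name, geno = ln.split(",", 1)
        fields = geno.split()
        if len(fields) != L:
            raise GenotypeParseError(
                f"line {i + 1}: {len(fields)} genotypes for {L} loci"
            )
        row: list[int] = []
        for f in fields:
            if len(f) != 6 or not f.isdigit():
                raise GenotypeParseError(
                    f"line {i + 1}: malformed genotype {f!r} (expected 6 digits)"
                )
            for code in (f[:3], f[3:]):
                v = int(code)
                row.append(MISSING if v == 0 else v)
        ids.append(name.strip())
        pops.append(f"pop{pop_no}")
        rows.append(row)
        i += 1
    if not rows:
        raise GenotypeParseError("no individuals found")
    alleles = np.array(rows, dtype=np.int32).reshape(len(rows), L, 2)
    species = np.array(["sp"] * len(ids), dtype=object)
    ds = MicrosatDataset(ids, np.array(pops, dtype=object), species,
                         locus_names, alleles)
    if grouping is not None:
        ds = apply_grouping(ds, grouping)
    return ds


def write_genepop(ds: MicrosatDataset, path, title: str = "ecodiverge export") -> None:
    """Write a GenePop file with one ``Pop`` block per population."""
    if ds.n_individuals == 0 or ds.n_loci == 0:
        raise ValueError("cannot write an empty dataset")
    if (ds.alleles >= 1000).any():
        raise ValueError("GenePop 3-digit coding requires allele states < 1000")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for nm in ds.locus_names:
            fh.write(nm + "\n")
        for pop in ds.populations:
            fh.write("Pop\n")
            for i in ds.pop_indices(pop):
                codes = []
                for l in range(ds.n_loci):
                    a, b = ds.alleles[i, l]
                    a = 0 if a == MISSING else a
                    b = 0 if b == MISSING else b
                    codes.append(f"{a:03d}{b:03d}")
                fh.write(f"{ds.individual_ids[i]} , " + " ".join(codes) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE matrix
# ---------------------------------------------------------------------------

def read_structure_table(path, one_row_per_copy: bool = True) -> MicrosatDataset:
    """Read a STRUCTURE-format matrix (whitespace delimited, ``-9`` missing).

    First line is a header of locus names.  Each data row starts with the
    individual label and its population label.  With ``one_row_per_copy``
    (the two-row format) consecutive row pairs hold the two gene copies.
    """
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise GenotypeParseError("file too short for STRUCTURE format")
    locus_names = lines[0]
    L = len(locus_names)
    body = lines[1:]
    ids: list[str] = []
    pops: list[str] = []
    rows: list[np.ndarray] = []
    if one_row_per_copy:
        if len(body) % 2:
            raise GenotypeParseError("odd row count in two-row STRUCTURE format")
        for j in range(0, len(body), 2):
            r1, r2 = body[j], body[j + 1]
            if r1[0] != r2[0]:
                raise GenotypeParseError(
                    f"row pair {j}: labels {r1[0]!r} != {r2[0]!r}"
                )
            if len(r1) != L + 2 or len(r2) != L + 2:
                raise GenotypeParseError(f"row pair {j}: wrong column count")
            ids.append(r1[0])
            pops.append(r1[1])
            g = np.stack([np.array(r1[2:], dtype=np.int32),
                          np.array(r2[2:], dtype=np.int32)], axis=1)
            rows.append(g)
    else:
        for j, r in enumerate(body):
            if len(r) != 2 * L + 2:
                raise GenotypeParseError(f"row {j}: wrong column count")
            ids.append(r[0])
            pops.append(r[1])
            g = np.array(r[2:], dtype=np.int32).reshape(L, 2)
            rows.append(g)
    alleles = np.stack(rows)
    alleles[alleles == -9] = MISSING
    species = np.array(["sp"] * len(ids), dtype=object)
    return MicrosatDataset(ids, np.array(pops, dtype=object), species,
                           locus_names, alleles)


def write_structure_table(ds: MicrosatDataset, path,
                          one_row_per_copy: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(ds.locus_names) + "\n")
        for i, ind in enumerate(ds.individual_ids):
            g = ds.alleles[i].copy()
            g[g == MISSING] = -9
            if one_row_per_copy:
                for c in (0, 1):
                    fh.write(f"{ind} {ds.population[i]} "
                             + " ".join(str(x) for x in g[:, c]) + "\n")
            else:
                fh.write(f"{ind} {ds.population[i]} "
                         + " ".join(str(x) for x in g.reshape(-1)) + "\n")


# ---------------------------------------------------------------------------
# grouping sidecar
# ---------------------------------------------------------------------------

def apply_grouping(ds: MicrosatDataset, path) -> MicrosatDataset:
    """Attach population/species labels from a CSV (individual, population, species)."""
    tab = pd.read_csv(path, dtype=str)
    tab.columns = [c.strip().lower() for c in tab.columns]
    need = {"individual", "population", "species"}
    if not need.issubset(tab.columns):
        raise ValueError(f"grouping CSV must have columns {sorted(need)}")
    m = tab.set_index("individual")
    missing = [i for i in ds.individual_ids if i not in m.index]
    if missing:
        raise ValueError(f"grouping CSV lacks individuals: {missing[:5]}")
    pop = np.array([m.loc[i, "population"] for i in ds.individual_ids], dtype=object)
    sp = np.array([m.loc[i, "species"] for i in ds.individual_ids], dtype=object)
    return MicrosatDataset(list(ds.individual_ids), pop, sp,
                           list(ds.locus_names), ds.alleles.copy())


def write_grouping(ds: MicrosatDataset, path) -> None:
    pd.DataFrame({
        "individual": ds.individual_ids,
        "population": ds.population,
        "species": ds.species,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# allele frequencies and count codings
# ---------------------------------------------------------------------------

def allele_frequencies(ds: MicrosatDataset, by: str = "population") -> pd.DataFrame:
    """Per-group, per-locus allele frequencies with copy counts.

    Returns a tidy frame with columns ``group, locus, allele, count, freq,
    n_copies``; missing copies are excluded from the counts.  A locus with
    no scored copies in some group is flagged with a warning (and emitted
    with ``n_copies = 0``), never silently dropped.
    """
    if by not in ("population", "species"):
        raise ValueError("by must be 'population' or 'species'")
    labels = ds.population if by == "population" else ds.species
    recs = []
    for g in pd.unique(labels):
        sub = ds.alleles[labels == g]
        for l, nm in enumerate(ds.locus_names):
            copies = sub[:, l, :].reshape(-1)
            copies = copies[copies != MISSING]
            if copies.size == 0:
                warnings.warn(f"locus {nm!r} entirely missing in group {g!r}")
                recs.append((g, nm, MISSING, 0, np.nan, 0))
                continue
            vals, cnt = np.unique(copies, return_counts=True)
            n = copies.size
            for v, c in zip(vals, cnt):
                recs.append((g, nm, int(v), int(c), c / n, n))
    return pd.DataFrame(
        recs, columns=["group", "locus", "allele", "count", "freq", "n_copies"]
    )


def allele_count_table(ds: MicrosatDataset, by: str = "population"):
    """Integer allele-count arrays per locus, shaped for the outlier scan.

    Returns ``(groups, counts)`` where ``counts`` is a list of
    ``(n_groups, n_alleles_l)`` arrays, one per locus, in the allele order
    of that locus's sorted distinct states.
    """
    labels = ds.population if by == "population" else ds.species
    groups = list(pd.unique(labels))
    counts = []
    for l in range(ds.n_loci):
        col = ds.alleles[:, l, :]
        obs = col[col != MISSING]
        states = np.unique(obs)
        mat = np.zeros((len(groups), len(states)), dtype=np.int64)
        for gi, g in enumerate(groups):
            copies = col[labels == g].reshape(-1)
            copies = copies[copies != MISSING]
            for si, s in enumerate(states):
                mat[gi, si] = int((copies == s).sum())
        counts.append(mat)
    return groups, counts


def genotype_matrix(ds: MicrosatDataset, impute_mean: bool = True) -> np.ndarray:
    """Individuals x alleles count coding (0/1/2) used by PCA/DAPC/dbRDA.

    Missing genotypes are imputed with the per-column mean (the standard
    centring-friendly choice) when ``impute_mean`` is set, else left NaN.
    """
    cols = []
    for l in range(ds.n_loci):
        col = ds.alleles[:, l, :]
        obs = col[col != MISSING]
        states = np.unique(obs)
        block = np.zeros((ds.n_individuals, len(states)))
        miss = (col == MISSING).all(axis=1)
        for si, s in enumerate(states):
            block[:, si] = (col == s).sum(axis=1)
        block[miss] = np.nan
        cols.append(block)
    X = np.concatenate(cols, axis=1)
    if impute_mean:
        mu = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(mu, idx[1])
    return X
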