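import numpy as np
import pytest

from ecodiverge.genodata import MISSING, MicrosatDataset


def make_dataset(alleles, pops, species=None, ids=None, loci=None):
    """Compact constructor for hand-written genotype fixtures."""
    alleles = np.asarray(alleles, dtype=np.int32)
    n, L, _ = alleles.shape
    ids = ids or [f"ind{i}" for i in range(n)]
    species = species if species is not None else ["sp"] * n
    loci = loci or [f"L{j}" for j in range(L)]
    return MicrosatDataset(ids, np.array(pops, dtype=object),
                           np.array(species, dtype=object), loci, alleles)


@pytest.fixture
def two_pop_fixed():
    """Two species, one population each, fixed for different alleles."""
    alleles = [[[(1, 1)], [(1, 1)]], [[(2, 2)], [(2, 2)]]]
    # 4 individuals: 2 per population, 1 locus
    a = np.array([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]])
    return make_dataset(a, ["A", "A", "B", "B"], ["sp1", "sp1", "sp2", "sp2"])


@pytest.fixture
def random_dataset():
    """Seeded random 10-individual, 4-locus, 2-population dataset."""
    rng = np.random.default_rng(77)
    a = rng.integers(1, 6, size=(10, 4, 2)).astype(np.int32)
    pops = ["A"] * 5 + ["B"] * 5
    species = ["sp1"] * 5 + ["sp2"] * 5
    return make_dataset(a, pops, species)


@pytest.fixture(scope="session")
def study_fixture():
    """One study-shaped coalescent fixture shared across tests."""
    from ecodiverge.synthdata import make_genotype_fixture
    return make_genotype_fixture(seed=3)
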