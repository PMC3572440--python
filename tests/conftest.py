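import numpy as np
import pytest

from hybridest import AlleleFrequencyTable, CodominantGenotype


@pytest.fixture(scope="session")
def diag3():
    return AlleleFrequencyTable.diagnostic(3)


@pytest.fixture(scope="session")
def diag65():
    return AlleleFrequencyTable.diagnostic(65)


def genotype_from_counts(table, n_hom1, n_het, n_hom2):
    """Diagnostic genotype with the given locus-category counts, in locus
    register order: hom-pop1 loci first, then heterozygous, then hom-pop2."""
    loci = table.loci
    assert n_hom1 + n_het + n_hom2 == len(loci)
    calls = {}
    for i, locus in enumerate(loci):
        if i < n_hom1:
            calls[locus] = ("1", "1")
        elif i < n_hom1 + n_het:
            calls[locus] = ("1", "2")
        else:
            calls[locus] = ("2", "2")
    return CodominantGenotype(calls)


@pytest.fixture(scope="session")
def swarm():
    """The packaged synthetic hybrid swarm (session-cached)."""
    from hybridest.experiments import default_swarm

    return default_swarm()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
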