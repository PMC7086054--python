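import numpy as np
import pytest

from mhcdiv.data import AlleleCatalog, Dataset, MultilocusGenotype


@pytest.fixture
def tiny_catalog():
    """Four 12-nt stop-free alleles with hand-checkable translations."""
    return AlleleCatalog(
        entries={
            "a1": "ATGGCTGCTGCT",  # MAAA
            "a2": "ATGGCTGCTGCA",  # MAAA (syn at last codon)
            "a3": "ATGTGGTGGGCT",  # MWWA
            "a4": "TTTGCTTGGGCT",  # FAWA
        },
        frame_offset=0,
    )


@pytest.fixture
def toy_dataset(tiny_catalog):
    genotypes = [
        MultilocusGenotype("i1", "north", {"a1", "a2"}),
        MultilocusGenotype("i2", "north", {"a1", "a3"}),
        MultilocusGenotype("i3", "north", {"a1"}),
        MultilocusGenotype("i4", "south", {"a3", "a4"}),
        MultilocusGenotype("i5", "south", {"a4"}),
    ]
    return Dataset(catalog=tiny_catalog, genotypes=genotypes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
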