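import numpy as np
import pytest

from divflow.genotypes import GenotypeMatrix


def make_matrix(dosages, pops, chrom=None, pos=None):
    """Build a small GenotypeMatrix from a dosage list-of-rows."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    if chrom is None:
        chrom = ["chr1"] * n_sites
    if pos is None:
        pos = np.arange(1, n_sites + 1)
    return GenotypeMatrix(
        chrom=np.array(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        dosages=dosages,
        samples=[f"s{i}" for i in range(n_samples)],
        pop_labels=np.array(pops, dtype=object),
    )


@pytest.fixture
def toy_matrix():
    """5 sites x 4 diploids (2 per population), no missing data."""
    dos = [
        [0, 1, 2, 0],
        [1, 1, 0, 2],
        [0, 0, 1, 1],
        [2, 2, 0, 0],
        [0, 1, 1, 2],
    ]
    return make_matrix(dos, ["p1", "p1", "p2", "p2"])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
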