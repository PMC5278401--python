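import numpy as np
import pytest
from hypothesis import settings

from kinforce.plink_io import AlleleFrequencyTable, Locus

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_panel():
    """Five well-behaved biallelic loci with distinct frequencies."""
    return AlleleFrequencyTable(
        [
            Locus("rs1", "1", 1000, "A", "G", 0.2),
            Locus("rs2", "1", 2000, "C", "T", 0.5),
            Locus("rs3", "2", 1000, "G", "T", 0.1),
            Locus("rs4", "2", 2000, "A", "C", 0.35),
            Locus("rs5", "3", 1000, "T", "A", 0.45),
        ]
    )


def random_forced_dyad(seed, n_loci=50):
    """A random forced dyad on a random panel: (panel, alleles_x, alleles_y)."""
    from kinforce.fixtures import generate_frequency_fixture

    r = np.random.default_rng(seed)
    panel = generate_frequency_fixture(n_loci, seed=seed)
    ax, ay = [], []
    for loc in panel:
        pair = (loc.allele1, loc.allele2)
        ax.append(pair[r.integers(2)])
        ay.append(pair[r.integers(2)])
    return panel, ax, ay
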