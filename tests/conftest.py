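import numpy as np
import pytest

from scstrmix.freq_panel import AlleleFrequencyTable, synthesize_frequency_table
from scstrmix.genotype_sim import GenotypeProfile


@pytest.fixture
def tiny_panel():
    """Two loci with three equifrequent alleles each: exhaustively enumerable."""
    return AlleleFrequencyTable(
        loci=("LA", "LB"),
        alleles_by_locus={"LA": (8.0, 9.0, 10.0), "LB": (8.0, 9.0, 10.0)},
        freqs_by_locus={
            "LA": np.array([0.5, 0.3, 0.2]),
            "LB": np.array([0.2, 0.3, 0.5]),
        },
    )


@pytest.fixture
def one_locus_panel():
    """Single locus, allele 'A'=10 at frequency 0.3 (closed-form checks)."""
    return AlleleFrequencyTable(
        loci=("L1",),
        alleles_by_locus={"L1": (10.0, 11.0, 12.0)},
        freqs_by_locus={"L1": np.array([0.3, 0.45, 0.25])},
    )


@pytest.fixture(scope="session")
def panel21():
    """A realistic 21-locus, 8-allele synthetic panel (study-scale geometry)."""
    return synthesize_frequency_table(21, 8, 1.0, seed=73)


def make_genotype(panel, alleles_per_locus, contributor_id="C1"):
    """Build a GenotypeProfile from {locus: (a1, a2)} on the given panel."""
    genotypes = {
        locus: (min(pair), max(pair)) for locus, pair in alleles_per_locus.items()
    }
    for locus in panel.loci:
        assert locus in genotypes
    return GenotypeProfile(contributor_id=contributor_id, genotypes=genotypes)
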