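import numpy as np
import pytest

from codonburst.genetic_code import SENSE_CODONS
from codonburst.seqio import CodonAlignment, read_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20140601)


@pytest.fixture
def random_codons(rng):
    """1,000 random sense-codon pairs."""
    idx = rng.integers(0, len(SENSE_CODONS), size=(1000, 2))
    return [(SENSE_CODONS[i], SENSE_CODONS[j]) for i, j in idx]


@pytest.fixture
def quartet_tree():
    return read_newick("((A:0.05,B:0.05)n1:0.02,(C:0.05,D:0.05)n2:0.02)root;")


@pytest.fixture
def quartet_alignment():
    return CodonAlignment(
        taxa=["A", "B", "C", "D"],
        sequences=["TTTAAAGGG", "TTTAAAGGG", "TTTAAAGGA", "TTTAAAGGA"],
        frame_offset=0,
    )


@pytest.fixture
def burst_tree():
    """Six-taxon tree used by the episodic-detection simulations."""
    return read_newick(
        "((A:0.02,B:0.02)x:0.02,(C:0.02,D:0.02)y:0.02,(E:0.02,F:0.02)z:0.02)r;"
    )
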