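import numpy as np
import pytest

from bhsgrna import AmpliconLocus, Spacer

BASES = "ACGT"


def random_spacer(rng: np.random.Generator, length: int = 20) -> Spacer:
    return Spacer("".join(rng.choice(list(BASES), size=length)))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def cbe_locus():
    """A + strand CBE amplicon with Cs at protospacer positions 4-7 and 10."""
    proto = "ATCCCCCTACGGTCAGATCA"
    ref = "GATTACAGGA" + proto + "AGGTTCACGATCGATTACGA"
    return AmpliconLocus("site1", ref, 11, 30, "+", "CBE")


@pytest.fixture
def cbe_spacer(cbe_locus):
    return Spacer(cbe_locus.protospacer_sequence())
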