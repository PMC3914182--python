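import numpy as np
import pytest

from mirkit.data import LNA_122I, MIR122_MATURE_RNA, mir122_mature
from mirkit.sequences import Alphabet, NucSequence


@pytest.fixture
def mir122():
    """Mature omy-miR-122 working sequence (RNA)."""
    return mir122_mature()


@pytest.fixture
def lna_oligo():
    """The 13-nt seed-anchored antagomir against miR-122."""
    return LNA_122I


@pytest.fixture
def rng():
    return np.random.default_rng(20240122)


def random_dna(rng, length, bases="ACGT"):
    return "".join(rng.choice(list(bases), size=length))
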