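import numpy as np
import pytest

from hils.patterns import Alignment, CumulativeFrequencies, QuartetAssignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_alignment():
    """Eight-column quartet used for hand-checked pattern counting."""
    return Alignment(
        ("O", "P1", "H", "P2"),
        ("AAAAACGA", "AACAACGC", "ACACACGC", "ACCAATGA"),
    )


@pytest.fixture
def quartet():
    return QuartetAssignment("O", "P1", "H", "P2")


def make_frequencies(iijj=0.0, ijij=0.0, ijji=0.0, ijii=0.0, iiji=0.0,
                     iiij=0.0, N=1e5) -> CumulativeFrequencies:
    return CumulativeFrequencies(iijj, ijij, ijji, ijii, iiji, iiij, N)


def mixture_frequencies(gamma: float) -> CumulativeFrequencies:
    """Class frequencies of an exact parental-tree mixture.

    The S1 vector has vanishing f2 and f4; the S2 vector is its
    parent-swap mirror, so every invariant ratio equals
    gamma/(1 - gamma) exactly.
    """
    s1 = dict(iijj=0.05, ijij=0.02, ijji=0.02, ijii=0.04, iiji=0.015, iiij=0.015)
    s2 = dict(iijj=0.02, ijij=0.02, ijji=0.05, ijii=0.015, iiji=0.015, iiij=0.04)
    mix = {k: gamma * s1[k] + (1 - gamma) * s2[k] for k in s1}
    return make_frequencies(**mix)
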