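import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from peaktopo import motifs, synthetic

JASPAR_TEXT = """\
>MA0004.1 Arnt
A  [ 4 19  0  0  0  0 ]
C  [16  0 20  0  0  0 ]
G  [ 0  1  0 20  0 20 ]
T  [ 0  0  0  0 20  0 ]
>MA0006.1 Ahr::Arnt
A  [ 3  0  0  0  0  0 ]
C  [ 8  0 23  0  0  0 ]
G  [ 2 23  0 23  0 24 ]
T  [11  1  1  1 24  0 ]
"""


@pytest.fixture
def jaspar_text():
    return JASPAR_TEXT


@pytest.fixture
def pfm():
    """First JASPAR record (CACGTG-box, width 6)."""
    return motifs.parse_jaspar_pfm(JASPAR_TEXT)[0]


@pytest.fixture
def pwm(pfm):
    return motifs.pfm_to_pwm(pfm)


@pytest.fixture
def syn_pfm():
    return synthetic.example_pfm()


@pytest.fixture
def syn_pwm(syn_pfm):
    return motifs.pfm_to_pwm(syn_pfm)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_dna(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
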