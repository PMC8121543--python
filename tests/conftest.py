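import numpy as np
import pytest

from clampscan.synthetic import build_library

# 25-codon toy ATPase fragment; the mutagenized window (residues 6-15)
# leaves 15-nt anchor flanks on both sides.
WT_DNA = (
    "ATG"
    "GCTAAACGTGAAGATGAATTTGACCGC"
    "CGTGCACTGAGCAATGGCTATCACAAA"
    "CTGGAATGGTTCGTTAAA"
)
REGION = (6, 15)


@pytest.fixture(scope="session")
def wt_dna() -> str:
    return WT_DNA


@pytest.fixture(scope="session")
def region() -> tuple[int, int]:
    return REGION


@pytest.fixture(scope="session")
def library():
    return build_library(WT_DNA, REGION)


@pytest.fixture()
def rng():
    return np.random.default_rng(20211)
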