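import numpy as np
import pytest

from repeatlens.motif_core import DEFAULT_ALPHABET, AlleleStructure, parse_nomenclature


@pytest.fixture
def alphabet():
    return DEFAULT_ALPHABET


@pytest.fixture
def pathogenic_16():
    """The published 16-repeat pathogenic allele."""
    return parse_nomenclature("CACA20+13xCGCA20+CACA20+CA18")


@pytest.fixture
def control_8():
    """An 8-repeat CA18/CACA20 control allele."""
    return parse_nomenclature("5xCACA20+CA18+CACA20+CA18")


@pytest.fixture
def control_7():
    """The most common allele: 4x CACA20, CA18, CACA20, CA18."""
    return parse_nomenclature("4xCACA20+CA18+CACA20+CA18")


def random_structure(rng: np.random.Generator, lo: int = 2, hi: int = 12) -> AlleleStructure:
    n = int(rng.integers(lo, hi + 1))
    return AlleleStructure(tuple(rng.choice(DEFAULT_ALPHABET.ids, n)))
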