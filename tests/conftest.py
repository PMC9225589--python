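import itertools

import pytest

from protocode.codec import BASES, DIGITS


@pytest.fixture(scope="session")
def all_letter_codons():
    """All 64 letter codons in a fixed order."""
    return ["".join(t) for t in itertools.product(BASES, repeat=3)]


@pytest.fixture(scope="session")
def all_numeric_codons():
    return ["".join(t) for t in itertools.product(DIGITS, repeat=3)]
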