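import numpy as np
import pytest

from gkmloc import DEFAULT_SCHEME, ReducedSequence


@pytest.fixture
def scheme():
    return DEFAULT_SCHEME


def make_rseq(symbols: str, alphabet=None) -> ReducedSequence:
    """Wrap a reduced-alphabet string (alphabet inferred if not given)."""
    if alphabet is None:
        alphabet = tuple(a for a in DEFAULT_SCHEME.class_alphabet if a in symbols) or \
            tuple(dict.fromkeys(symbols))
    return ReducedSequence(symbols=symbols, alphabet=tuple(alphabet))


@pytest.fixture
def paper_reduced():
    """The printed reduced worked-example sequence."""
    return make_rseq("LBBBWWG", alphabet=DEFAULT_SCHEME.class_alphabet)


@pytest.fixture
def binary_reduced():
    """The two-class trie worked-example sequence."""
    return make_rseq("BBBWWBBWB", alphabet=("B", "W"))


def random_reduced(rng: np.random.Generator, length: int, alphabet: tuple) -> ReducedSequence:
    symbols = "".join(rng.choice(list(alphabet), size=length))
    return ReducedSequence(symbols=symbols, alphabet=tuple(alphabet))
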