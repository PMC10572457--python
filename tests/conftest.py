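import numpy as np
import pytest

from safold.alphabet import (
    SubstitutionMatrix,
    build_substitution_matrix,
    encode_geometric,
    load_default_library,
)
from safold.fixtures import GeneratorSpec, generate_chain, generate_corpus
from safold.search import build_database


def make_simple_matrix(
    letters: str, match: int, mismatch: int, gap_open: int, gap_extend: int
) -> SubstitutionMatrix:
    """Uniform match/mismatch toy matrix used throughout the alignment tests."""
    k = len(letters)
    scores = np.full((k, k), mismatch, dtype=int)
    np.fill_diagonal(scores, match)
    return SubstitutionMatrix(
        letters=letters,
        scores=scores,
        gap_open=gap_open,
        gap_extend=gap_extend,
        background=np.full(k, 1.0 / k),
    )


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture(scope="session")
def matrix(library):
    return build_substitution_matrix(library)


@pytest.fixture(scope="session")
def helix20():
    return generate_chain(GeneratorSpec(kind="helix", length=20))


@pytest.fixture(scope="session")
def corpus50():
    """The 50-chain mixed fixture corpus (default recipe, noise 0.05 A)."""
    return generate_corpus(50, seed=3)


@pytest.fixture(scope="session")
def db50(corpus50, library):
    records = [encode_geometric(c, library) for c in corpus50]
    return build_database(records, library.letters)
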