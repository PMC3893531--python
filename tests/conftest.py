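from pathlib import Path

import numpy as np
import pytest

from stacklogo import Alphabet, MultipleAlignment
from stacklogo.fixtures import HmmSpec, make_toy_hmm

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def dna() -> Alphabet:
    return Alphabet.dna()


@pytest.fixture(scope="session")
def amino() -> Alphabet:
    return Alphabet.amino()


@pytest.fixture(scope="session")
def uniform4() -> np.ndarray:
    return np.full(4, 0.25)


def make_msa(rows, alphabet=None, ids=None) -> MultipleAlignment:
    alphabet = alphabet or Alphabet.dna()
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return MultipleAlignment(ids=ids, rows=list(rows), alphabet=alphabet)


@pytest.fixture(scope="session")
def toy_profile():
    """3-state DNA profile with hand-picked gap parameters and a MAP line."""
    spec = HmmSpec(
        match_p=np.array([[1.0, 0, 0, 0], [0.25, 0.25, 0.25, 0.25], [0, 0, 0.5, 0.5]]),
        eps=np.array([0.0, 0.5, 0.9]),
        m_to_i=np.array([0.0, 0.2, 0.1]),
        m_to_d=np.array([0.1, 0.1, 0.0]),
        map_columns=[3, 7, 9],
    )
    return make_toy_hmm(spec)
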