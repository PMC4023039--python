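import numpy as np
import pytest

from retrodict.coding import CharacterMatrix
from retrodict.folding import EnergyModel


@pytest.fixture
def model() -> EnergyModel:
    return EnergyModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_matrix(
    rng: np.random.Generator, n_taxa: int, n_chars: int, k: int
) -> CharacterMatrix:
    return CharacterMatrix(
        taxa=tuple(f"t{i}" for i in range(n_taxa)),
        characters=tuple(f"c{j}" for j in range(n_chars)),
        states=rng.integers(0, k, (n_taxa, n_chars)),
        k=k,
    )


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), n))
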