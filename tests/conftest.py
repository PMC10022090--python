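import numpy as np
import pytest

from npore.model import PenaltyModel


@pytest.fixture(scope="session")
def default_model() -> PenaltyModel:
    return PenaltyModel.default()


@pytest.fixture(scope="session")
def affine_model() -> PenaltyModel:
    """Plain affine model with non-trivial match/mismatch costs."""
    return PenaltyModel.affine_only(G_open=5.0, G_extend=1.0,
                                    match_cost=0.1, mismatch_cost=3.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(rng: np.random.Generator, seq: str, n_edits: int) -> str:
    """A handful of random substitutions/indels, for related read/ref pairs."""
    s = list(seq)
    for _ in range(n_edits):
        if not s:
            break
        kind = rng.integers(3)
        p = int(rng.integers(len(s)))
        if kind == 0:
            s[p] = rng.choice(list("ACGT"))
        elif kind == 1:
            s.insert(p, rng.choice(list("ACGT")))
        else:
            del s[p]
    return "".join(s)
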