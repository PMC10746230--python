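"""Shared fixtures: seeded RNGs and the canonical synthetic world."""

import numpy as np
import pytest

from crisphage.synthetic import make_small_world

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int, at: float = 0.5) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def world():
    """The six-host / twelve-phage synthetic world, fixed seed."""
    return make_small_world(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
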