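from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

AA20 = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_protein(rng, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), size=n))


def random_dna(rng, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))
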