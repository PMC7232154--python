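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


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_genome() -> str:
    """A 2 kb uniform-composition reference."""
    gen = np.random.default_rng(7)
    return "".join("ACGT"[i] for i in gen.integers(0, 4, size=2000))
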