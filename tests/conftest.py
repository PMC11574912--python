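import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def track_rng(seed: int, run: int = 0) -> np.random.Generator:
    """Deterministic generator for driving single tracks in tests."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, run])))
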