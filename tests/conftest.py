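import numpy as np
import pytest

from chlquench.constants import thermal_energy


@pytest.fixture(scope="session")
def kt300() -> float:
    """k_B * 300 K in eV (~0.025852)."""
    return thermal_energy(300.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
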