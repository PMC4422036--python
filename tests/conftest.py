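import numpy as np
import pytest

from thetagamma.spectral import FilterBank


@pytest.fixture(scope="session")
def bank() -> FilterBank:
    """One shared filter bank for the whole suite (design is deterministic)."""
    return FilterBank()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def tone(freq: float, rate: float, n: int, amplitude: float = 1.0,
         phase: float = 0.0) -> np.ndarray:
    t = np.arange(n) / rate
    return amplitude * np.cos(2.0 * np.pi * freq * t + phase)


@pytest.fixture(scope="session")
def make_tone():
    return tone
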