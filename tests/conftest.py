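import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ldflow import PowerSpectrum, default_grid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


GRID = default_grid()  # 20, 40, ..., 12800 Hz


def random_spectrum(rng: np.random.Generator, n_bins: int = 640, df: float = 20.0,
                    idc: float = 1.0, t0: float = 0.0) -> PowerSpectrum:
    """A strictly positive random spectrum on the standard grid layout."""
    f = np.arange(1, n_bins + 1) * df
    return PowerSpectrum(f=f, S=rng.uniform(0.01, 1.0, n_bins), idc=idc, t0=t0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210209)


@pytest.fixture
def toy_spectrum() -> PowerSpectrum:
    """S = 1 at f in {100, 200, 300} Hz, bin width 100 Hz, idc = 1."""
    return PowerSpectrum(f=np.array([100.0, 200.0, 300.0]),
                         S=np.array([1.0, 1.0, 1.0]), idc=1.0)
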