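import numpy as np
import pytest

from nirshelf.grid import SpectrumGrid
from nirshelf.synth import SyntheticStudyConfig, generate_study


@pytest.fixture(scope="session")
def grid() -> SpectrumGrid:
    return SpectrumGrid.default()


@pytest.fixture(scope="session")
def noise_free_config() -> SyntheticStudyConfig:
    """Deterministic limit: no spectral noise, no scatter, exact titration."""
    return SyntheticStudyConfig(
        noise_sd=0.0,
        scatter_slope_sd=0.0,
        scatter_offset_sd=0.0,
        titration_noise_sd=0.0,
        n_decayed=0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_study(noise_free_config):
    return generate_study(noise_free_config)


@pytest.fixture(scope="session")
def default_study():
    """The full emulated study design at default noise levels."""
    return generate_study(SyntheticStudyConfig(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """A reduced design (6 groups of 2) for fast end-to-end checks."""
    return generate_study(
        SyntheticStudyConfig(
            n_fruits=12, n_groups=6, group_size=2, n_positions=2,
            noise_sd=0.0, scatter_slope_sd=0.0, scatter_offset_sd=0.0,
            titration_noise_sd=0.0, n_decayed=0, seed=3,
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
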