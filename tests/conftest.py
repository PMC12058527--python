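import numpy as np
import pytest

from ftbm import (
    BrillouinSpectrum,
    NoiseModel,
    OpticalConfig,
    PhotonBudget,
    SamplingSchedule,
)


@pytest.fixture(scope="session")
def water_optics() -> OpticalConfig:
    return OpticalConfig(wavelength_nm=780.0, theta_deg=90.0, na_eff=0.47,
                         refractive_index=1.33)


@pytest.fixture(scope="session")
def plain_optics() -> OpticalConfig:
    """No aperture broadening: envelope closed forms apply exactly."""
    return OpticalConfig(wavelength_nm=780.0, theta_deg=90.0, na_eff=0.0,
                         refractive_index=1.33)


@pytest.fixture(scope="session")
def water_spectrum(water_optics) -> BrillouinSpectrum:
    return BrillouinSpectrum.water(water_optics)


@pytest.fixture(scope="session")
def water_schedule() -> SamplingSchedule:
    """Experimental water schedule: 5 fine steps of 195 nm, 21 coarse of 10 mm."""
    return SamplingSchedule(n_fine=5, fine_step_nm=195.0, n_coarse=21,
                            coarse_step_mm=10.0)


@pytest.fixture(scope="session")
def sim_schedule() -> SamplingSchedule:
    """Monte-Carlo protocol schedule: N_L=5, N_S=20, total OPL 200 mm."""
    return SamplingSchedule(n_fine=5, fine_step_nm=195.0, n_coarse=20,
                            coarse_step_mm=10.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def quiet_noise() -> NoiseModel:
    return NoiseModel(shot_noise=False)


@pytest.fixture()
def shot_noise() -> NoiseModel:
    return NoiseModel(shot_noise=True)


@pytest.fixture()
def kilophoton_budget() -> PhotonBudget:
    return PhotonBudget(n_brillouin=1000.0)
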