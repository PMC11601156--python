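import numpy as np
import pytest

from maldicrs.spectra_io import Spectrum
from maldicrs.synthetic import ResponderSpec, SimulationConfig, simulate_plate


def small_plate_config(seed: int = 1, responders: bool = True) -> SimulationConfig:
    """A fast desk-scale plate: narrow m/z window, few features."""
    specs = (
        (
            ResponderSpec(mz=520.10, b=-2.0, c=1.0, d=8.0, e=1e-6),
            ResponderSpec(mz=460.25, b=2.0, c=1.0, d=7.0, e=1e-6),
        )
        if responders
        else ()
    )
    return SimulationConfig(
        n_features=12,
        mz_range=(420.0, 600.0),
        responder_specs=specs,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_plate():
    """One simulated plate with 2 responders among 12 features."""
    return simulate_plate(small_plate_config(seed=1))


@pytest.fixture()
def flat_spectrum():
    mz = 400.0 + 0.02 * np.arange(2001)
    return Spectrum(mz=mz, intensity=np.full_like(mz, 5.0), spot_id="flat")


def gaussian_spectrum(
    peaks=((420.0, 50.0),),
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    seed: int = 0,
    sigma: float = 0.05,
):
    """Build a profile spectrum with Gaussian peaks on a flat baseline."""
    mz = 400.0 + 0.02 * np.arange(2001)
    rng = np.random.default_rng(seed)
    y = np.full_like(mz, baseline)
    for mu, h in peaks:
        y += h * np.exp(-0.5 * ((mz - mu) / sigma) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, len(mz))
    return Spectrum(mz=mz, intensity=np.clip(y, 0, None), spot_id="test")
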