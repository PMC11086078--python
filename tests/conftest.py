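import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cottonfir.spectra_io import Spectrum


@pytest.fixture
def flat_spectrum() -> Spectrum:
    """Constant absorbance 0.5 on a 4 cm^-1 grid spanning 600-1800 cm^-1."""
    w = np.arange(600.0, 1804.0, 4.0)
    return Spectrum(w, np.full(w.size, 0.5), sample_id="flat")


@pytest.fixture(scope="session")
def noiseless_spectrum():
    """Noiseless default-model rendering with known target indices (0.8, 80)."""
    from cottonfir.synthetic import render_spectrum, target_to_band_amplitudes

    model = target_to_band_amplitudes(0.8, 80.0)
    return render_spectrum(model, 0.0, sample_id="synthetic")
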