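import numpy as np
import pytest

from wormstim import default_study_models, periodic_protocol, simulate_recording


@pytest.fixture(scope="session")
def models():
    return default_study_models()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def estim_noiseless(models):
    """Noiseless 10-stimulus electrical trial: both fibers, one AP each."""
    protocol = periodic_protocol(["EStim"], 10, interval_s=0.3, region="anterior")
    return simulate_recording(
        protocol,
        models.fibers,
        models.responses["EStim"],
        models.geometry,
        noise_sd=0.0,
        seed=1,
    )
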