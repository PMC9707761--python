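import numpy as np
import pytest

from ehgm.evaluation import fit_corpus_template
from ehgm.simulate import generate_series, reduced_config

# moderate detection jitter for the noisy suites (micrometers)
NOISE_SD = 0.5


@pytest.fixture(scope="session")
def clean_config():
    return reduced_config(noise_sd=0.0, n_frames=20)


@pytest.fixture(scope="session")
def noisy_config():
    return reduced_config(noise_sd=NOISE_SD, n_frames=20)


@pytest.fixture(scope="session")
def clean_template(clean_config):
    return fit_corpus_template(clean_config, rng_seed=7, n_embryos=6)


@pytest.fixture(scope="session")
def noisy_template(noisy_config):
    return fit_corpus_template(noisy_config, rng_seed=7, n_embryos=6)


@pytest.fixture(scope="session")
def clean_series(clean_config):
    return generate_series(clean_config, np.random.default_rng(555))


@pytest.fixture(scope="session")
def noisy_series(noisy_config):
    return generate_series(noisy_config, np.random.default_rng(556))
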