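import pytest

from combifit import GeneratorConfig, build_ccd
from combifit.pipeline import BP_LEVELS, TM_LEVELS


@pytest.fixture(scope="session")
def design():
    return build_ccd(TM_LEVELS, BP_LEVELS, n_center=6)


@pytest.fixture(scope="session")
def noiseless_config():
    return GeneratorConfig(seed=0, noise_cv=0.0)


@pytest.fixture(scope="session")
def noisy_config():
    return GeneratorConfig(seed=1, noise_cv=0.05)
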