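import numpy as np
import pytest

from adcoi import load_national_inputs
from adcoi.pipeline import run_reproduction
from adcoi.synth import default_adult_spec, default_pediatric_spec, generate_cohort


@pytest.fixture(scope="session")
def national():
    return load_national_inputs()


@pytest.fixture(scope="session")
def repro(national):
    """All 8 scenario results recomputed from the packaged fixture inputs."""
    with pytest.warns(UserWarning):  # adult moderate FT+PT shares exceed 1
        return run_reproduction(national)


@pytest.fixture(scope="session")
def adult_cohort():
    """Calibrated adult survey cohort under the study conditions (no deletion)."""
    return generate_cohort(default_adult_spec(seed=11))


@pytest.fixture(scope="session")
def pediatric_cohort():
    return generate_cohort(default_pediatric_spec(seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(2022)
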