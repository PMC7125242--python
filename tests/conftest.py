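import warnings

import pytest
from hypothesis import HealthCheck, settings

from strainrepro.model import aggregate_dataset
from strainrepro.simulate import generate, preset_paper

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset_config():
    return preset_paper()


@pytest.fixture(scope="session")
def preset_dataset(preset_config):
    """Full study-shaped dataset: 10 animals x 3 states x 3 components x 16 x 2 x 2."""
    return generate(preset_config, seed=42)


@pytest.fixture(scope="session")
def preset_globals_rep(preset_dataset):
    """Per-replicate global strain values of the preset dataset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return aggregate_dataset(preset_dataset, average_over_replicates=False)
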