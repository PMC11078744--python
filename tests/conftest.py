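import numpy as np
import pytest

from steppekin.relatedness import build_reference_distributions
from steppekin.scenarios import ScenarioSpec, generate_scenario
from steppekin.transmission import PERFECT_OBSERVATION


@pytest.fixture(scope="session")
def reference_distributions():
    """60-replicate second-degree reference samples (shared across tests)."""
    return build_reference_distributions(n_pedigrees=60, seed=11)


@pytest.fixture(scope="session")
def rk_bundle_perfect():
    """A mid-size patrilineal scenario observed without degradation."""
    spec = ScenarioSpec(preset="rk_like", seed=2,
                        observation=PERFECT_OBSERVATION,
                        overrides={"n_generations": 6})
    return generate_scenario(spec)


@pytest.fixture(scope="session")
def multi_site_bundle():
    return generate_scenario(ScenarioSpec(preset="multi_site", seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
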