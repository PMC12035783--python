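import warnings

import pytest

from xylokinetics.pipeline import zonate_experiment
from xylokinetics.simulate import SimulationParams, simulate_experiment

# statsmodels warns that the identity link is non-canonical for Gamma; that
# combination is the deliberate model choice here.
warnings.filterwarnings("ignore", message=".*Identity link.*")


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(n_trees_per_treatment=4, seed=42)


@pytest.fixture(scope="session")
def small_experiment(small_params):
    return simulate_experiment(small_params)


@pytest.fixture(scope="session")
def small_dated(small_experiment):
    dated, increments = zonate_experiment(
        small_experiment.growth,
        small_experiment.detections,
        small_experiment.schedule,
    )
    return dated, increments
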