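import warnings

import numpy as np
import pytest

from effortmet.choice_model import BehavioralParameters, simulate_choices
from effortmet.model_fitting import to_natural
from effortmet.task_design import generate_session

warnings.filterwarnings("ignore", category=RuntimeWarning, module="effortmet")


@pytest.fixture(scope="session")
def schedule():
    return generate_session(seed=1, start_type="mental")


@pytest.fixture(scope="session")
def moderate_params():
    """Plausible mid-range sensitivities giving variable choices."""
    return BehavioralParameters(kR=1.0, kP=0.8, kEp=0.7, kEm=0.9, kFp=0.5, kLm=0.4, bias=0.3)


@pytest.fixture(scope="session")
def simulated_dataset(schedule, moderate_params):
    return simulate_choices(moderate_params, schedule, seed=11)


@pytest.fixture(scope="session")
def random_latent_dataset(schedule):
    rng = np.random.default_rng(5)
    z = rng.standard_normal(7)
    params = BehavioralParameters.from_array(to_natural(z))
    ds = simulate_choices(params, schedule, seed=6)
    return z, ds
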