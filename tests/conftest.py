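import warnings

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def sim_config():
    from microclip import SimulationConfig

    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_library(sim_config):
    from microclip import simulate_library

    return simulate_library(sim_config)


@pytest.fixture(scope="session")
def sim_library_paths(sim_library, tmp_path_factory):
    return sim_library.write(tmp_path_factory.mktemp("simlib"))


@pytest.fixture(scope="session")
def separable_instances():
    """The separable benchmark corpus: 1:2.5 ratio at n=1400 (200/500
    base-train, 100/250 meta-train, 100/250 test)."""
    from microclip import SimulationConfig, simulate_training_instances

    cfg = SimulationConfig(seed=7, separation=2.0)
    return simulate_training_instances(cfg, n_total=1400)


@pytest.fixture(scope="session")
def trained_model(separable_instances):
    from microclip import train_super_learner
    from microclip.learner import LearnerConfig

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_super_learner(separable_instances, LearnerConfig(seed=7))
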