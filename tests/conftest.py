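import numpy as np
import pytest

from texturemap import synthetic_data as sd
from texturemap import trace_processing as tp


@pytest.fixture(scope="session")
def clustered_population():
    """40 neurons, four planted clusters, strong tuning."""
    return sd.generate_population(
        sd.PopulationSpec(n_neurons=40, cluster_count=4, cluster_radius=20.0, seed=3)
    )


@pytest.fixture(scope="session")
def trial_set(clustered_population):
    return sd.generate_trials(clustered_population, sd.TransientSpec(seed=4, noise_sd=0.01))


@pytest.fixture(scope="session")
def summaries(trial_set):
    return tp.summarize_trial_set(trial_set)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
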