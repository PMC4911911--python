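import numpy as np
import pytest

from pufclip import peaks, pipeline, simulate


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured simulation for module-level tests."""
    return simulate.SimConfig(n_transcripts=40, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return pipeline.simulate_experiment(small_config)


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions (~200 transcripts, 3 replicates)."""
    return pipeline.simulate_experiment(simulate.SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_candidates(default_sim):
    return pipeline.candidate_peaks_per_replicate(
        default_sim, peaks.PeakCallConfig()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
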