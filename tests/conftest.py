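import pytest

from ashmscreen import PipelineThresholds, SimulationConfig, simulate_dataset
from ashmscreen.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_sites=300)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def thresholds() -> PipelineThresholds:
    return PipelineThresholds()


@pytest.fixture(scope="session")
def pipeline_result(small_config, small_dataset, thresholds):
    return run_pipeline(small_config, thresholds, dataset=small_dataset)
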