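import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from biochemom import PipelineConfig, run_pipeline
from biochemom.synthetic import ScenarioSpec, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_panel():
    """One default-scenario synthetic panel (seed 1) shared across tests."""
    spec = ScenarioSpec(seed=1)
    table, meta, bio, truth = generate_dataset(spec)
    return spec, table, meta, bio, truth


@pytest.fixture(scope="session")
def pipeline_result(default_panel):
    """Full workflow run on the shared panel (seed 1 split)."""
    _, table, meta, bio, _ = default_panel
    return run_pipeline(table, meta, bio, PipelineConfig(split_seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
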