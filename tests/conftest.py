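import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vmte.pipeline import default_config, run_all
from vmte.synthetic_data import SimulationConfig, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SIM_SEED = 1


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=SIM_SEED)


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    """The default study conditions: 4 clades x 50 copies, 330 bp consensus,
    2% divergence, 8 diagnostic sites, escape clade = clade4."""
    return simulate(sim_config)


@pytest.fixture(scope="session")
def sim_dir(sim_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("simdata")
    sim_dataset.write(out)
    return out


@pytest.fixture(scope="session")
def pipeline_bundle(sim_dir):
    cfg = default_config(str(sim_dir), str(sim_dir / "results"), seed=SIM_SEED)
    return run_all(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
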