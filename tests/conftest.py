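import warnings

import pytest

from lincscan.config import RunConfig
from lincscan.synthetic_data import SimulationConfig, simulate_expression, simulate_genome
from lincscan.workflow import run_all

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_scene():
    """The default simulated scene (seed fixed): genome, assembly, truth."""
    return simulate_genome(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_expression(default_scene):
    tissue, dev = simulate_expression(default_scene.truth, default_scene.config)
    return tissue, dev


@pytest.fixture(scope="session")
def run_all_result(tmp_path_factory):
    """One full end-to-end run on the default scene, shared across tests."""
    outdir = tmp_path_factory.mktemp("run_all")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = run_all(RunConfig(seed=DEFAULT_SEED), outdir)
    return outdir, summary
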