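import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from lncscout.pipeline import run_pipeline
from lncscout.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic study, shared read-only across tests."""
    return simulate_all(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_run(dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline")
    report = run_pipeline(dataset, out)
    return out, report
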