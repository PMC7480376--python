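import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))  # for oracles.py

from cazloci import SimConfig, emit_fixture_set, simulate_bins
from cazloci.pipeline import run_fixture


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def simulation(default_config):
    """(bins, hits, sequences, manifest, spectra) for the default study conditions."""
    return simulate_bins(default_config)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, simulation):
    d = tmp_path_factory.mktemp("fixture")
    emit_fixture_set(*simulation, d)
    return d


@pytest.fixture(scope="session")
def pipeline_results(fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("report")
    return run_fixture(fixture_dir, out)


@pytest.fixture(scope="session")
def manifest(simulation):
    return simulation[3]
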