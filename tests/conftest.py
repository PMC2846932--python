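import numpy as np
import pytest

from lectinfam.config import AnalysisConfig
from lectinfam.pipeline import run_pipeline
from lectinfam.simulate import SimulationConfig, emit_dataset


def small_config(seed: int = 7) -> SimulationConfig:
    """A reduced simulation for fast plumbing tests.

    Lower birth rates and ancestral sizes than the full study conditions so
    genomes stay small; the full-scale conditions are exercised by the
    acceptance tests.
    """
    return SimulationConfig(
        seed=seed,
        ancestral_sizes={"B_lectin": 3, "Jacalin": 2, "LysM": 2},
        birth_rates={"soybean": 5.0, "rice": 4.0, "arabidopsis": 3.0},
    )


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """One small synthetic dataset shared by the session."""
    directory = tmp_path_factory.mktemp("dataset")
    result = emit_dataset(directory, small_config())
    result["directory"] = directory
    return result


@pytest.fixture(scope="session")
def pipeline_out(dataset, tmp_path_factory):
    """Full pipeline artifacts over the shared dataset."""
    out = tmp_path_factory.mktemp("pipeline_out")
    run_pipeline(AnalysisConfig(), dataset["directory"], out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
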