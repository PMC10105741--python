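from pathlib import Path

import numpy as np
import pytest

from encc_severity import qc_norm
from encc_severity.synthio import SimConfig, read_fixture, simulate_dataset

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture_small"


@pytest.fixture(scope="session")
def fixture_dir() -> Path:
    return FIXTURE_DIR


@pytest.fixture(scope="session")
def small_dataset():
    """The committed 20-gene x 60-cell fixture, re-read from disk."""
    return read_fixture(FIXTURE_DIR)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config simulation shared across tests (seed 1)."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def processed_default(default_dataset):
    """QC-filtered and normalized default dataset: (matrix, annotation)."""
    m, ann = qc_norm.filter_cells(default_dataset.matrix, default_dataset.annotation)
    m = qc_norm.filter_genes(m)
    m = qc_norm.normalize(m)
    return m, ann


@pytest.fixture(scope="session")
def default_axis(processed_default):
    from encc_severity.severity_axis import build_axis

    m, ann = processed_default
    return build_axis(m, ann)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
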