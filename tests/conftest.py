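import numpy as np
import pytest

from timeco.io import ClonotypeKey, ClonotypeTable
from timeco.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Three-patient synthetic cohort shared by the slower tests."""
    return simulate_cohort(CohortConfig(n_patients=3, seed=7))


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """The same cohort written to disk in the pipeline's input layout."""
    path = tmp_path_factory.mktemp("cohort")
    simulate_cohort(CohortConfig(n_patients=2, seed=11), path)
    return path


def make_table(sample_id, counts):
    """Clonotype table from {junction: count} with fixed V/J calls."""
    return ClonotypeTable(
        sample_id=sample_id,
        counts={ClonotypeKey(j, "TRBV9", "TRBJ1-1"): c for j, c in counts.items()},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
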