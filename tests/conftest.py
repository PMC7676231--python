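import numpy as np
import pytest

from imppipe.synthetic_data import SyntheticWorldConfig, simulate_cohort_truth


@pytest.fixture(scope="session")
def small_world():
    """A compact world reused across read-level tests."""
    cfg = SyntheticWorldConfig(
        n_subjects=12,
        n_genes=600,
        n_mgs=8,
        mgs_size=50,
        markers_per_mgs=50,
        read_depth=5000,
        seed=11,
    )
    return simulate_cohort_truth(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
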