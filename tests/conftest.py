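import numpy as np
import pytest

from scaconn import (RoiTimeSeries, generate_cohort, load_aal116,
                     small_test_spec)


@pytest.fixture(scope="session")
def aal():
    return load_aal116()


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded 20-region cohort with three perturbed edges."""
    return generate_cohort(small_test_spec(), master_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_ts(data, tr=2.0):
    data = np.asarray(data, dtype=float)
    names = [f"R{i+1:03d}" for i in range(data.shape[1])]
    return RoiTimeSeries(data, tr, names)
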