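import os

# single-threaded linear algebra: keeps k-means sweeps bit-reproducible
# across machines with different core counts
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from dfcstates import (CohortSpec, RoiTimecourse, load_parcellation,
                       make_state_covariances, simulate_cohort)


@pytest.fixture(scope="session")
def parcellation():
    return load_parcellation()


@pytest.fixture(scope="session")
def state_spec(parcellation):
    return make_state_covariances(parcellation, K=5, seed=1)


@pytest.fixture(scope="session")
def small_cohort(state_spec):
    """A 12-subject single-scan cohort reused across modules."""
    cohort = CohortSpec(n_subjects=12, n_sites=3, families_per_site=4,
                        seed=42)
    scans, behavior, truth = simulate_cohort(state_spec, cohort)
    return scans, behavior, truth


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def white_tc(rng):
    """A 380 x 53 white-noise scan at TR = 0.8 s."""
    return RoiTimecourse(data=rng.standard_normal((380, 53)), tr_seconds=0.8,
                         subject_id="subX", scan_id="scan1")
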