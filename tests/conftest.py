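import numpy as np
import pytest

from connstats import build_design, gen_cohort, gen_fc_data, gen_parcellation
from connstats.simulate import SyntheticTruth


@pytest.fixture(scope="session")
def small_parcellation():
    """40 cortical + 4 subcortical parcels with the default network labels."""
    return gen_parcellation(40, 4, seed=101)


@pytest.fixture(scope="session")
def null_cohort_data(small_parcellation):
    """A clustered cohort with no planted effects (global null)."""
    parcels, assignment = small_parcellation
    cohort = gen_cohort(200, n_sites=12, seed=202)
    Y, _ = gen_fc_data(cohort, assignment, SyntheticTruth(), seed=303)
    design = build_design(cohort, ["age_months", "fd_mean"], "stimulant")
    return cohort, design, Y


@pytest.fixture
def rng():
    return np.random.default_rng(7)
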