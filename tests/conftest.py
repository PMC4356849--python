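import numpy as np
import pytest

import ptstraj as pt


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-subject cohort from the calibrated generating model."""
    spec = pt.dnhs_like_spec(n_subjects=200, seed=12345)
    return pt.simulate_cohort(spec)


@pytest.fixture(scope="session")
def two_class_cohort():
    """Well-separated two-class data, complete (no dropout), for fits whose
    global optimum must be unambiguous."""
    spec = pt.dnhs_like_spec(
        n_subjects=300,
        seed=777,
        class_proportions=(0.6, 0.4),
        growth_coefficients=((25.0, 0.0, 0.0), (70.0, -5.0, 1.0)),
        wave_residual_sds=((5.0, 5.0, 5.0), (5.0, 5.0, 5.0)),
        class_labels=("lo", "hi"),
        dropout=pt.DropoutSpec(retention=(1.0, 1.0, 1.0)),
    )
    return pt.simulate_cohort(spec)


@pytest.fixture(scope="session")
def fitted_four_class(small_cohort):
    return pt.fit_lcga(small_cohort, K=4, n_starts=30, seed=9)
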