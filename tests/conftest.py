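import numpy as np
import pytest

from pvcsurv.pipeline import train_detector
from pvcsurv.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def trained_net():
    """One benchmark-quality detector shared across the session.

    Trained on 60 short-protocol synthetic recordings; reused by the
    end-to-end acceptance check and the behavioural detector tests.
    """
    return train_detector(n_recordings=60, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Complete-data cohort with planted exercise-category hazard ratios."""
    spec = CohortSpec(
        n=6000,
        missingness={},
        recovery_log_hr={},
        baseline_rate_female=0.0135,
        baseline_rate_male=0.0195,
    )
    return generate_cohort(spec, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
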