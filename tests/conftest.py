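import numpy as np
import pytest

from ppcml import cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort at the study size (n=286)."""
    return cohort.generate_cohort(cohort.default_spec(n_patients=286, seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for marginal-fidelity checks."""
    return cohort.generate_cohort(cohort.default_spec(n_patients=10_000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


# 6 informative predictors + 7 pure-noise columns: the 13-variable view used
# by the model-selection experiments
FEATURES_13 = [
    "wbc", "bmi", "approach", "age", "blood_loss", "crp",
    "sex", "smoking", "fev1", "platelets", "hemoglobin", "glucose",
    "operative_time",
]


@pytest.fixture(scope="session")
def feature_view():
    return list(FEATURES_13)
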