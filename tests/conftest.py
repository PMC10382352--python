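import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=list(HealthCheck),
)
settings.load_profile("deterministic")

from raidose.regression import RegressionFit, fit_gee  # noqa: E402
from raidose.synthetic_data import CohortConfig, generate_cohort  # noqa: E402


def observations_from(cohort, truth, measured=True):
    """Regression observations (48-h SUVmax vs therapy-isotope AUC) from a
    generated cohort; ``measured=False`` uses the noise-free predictor."""
    if measured:
        suv48 = cohort[cohort["time_h"] == 48.0].set_index("lesion_id")["suv_max"]
        x = truth["lesion_id"].map(suv48).to_numpy()
    else:
        x = truth["suv48_true"].to_numpy()
    return truth.assign(predictor_value=x, auc=truth["auc_131"])[
        ["patient_id", "lesion_id", "predictor_value", "auc"]
    ]


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=20260921))


@pytest.fixture(scope="session")
def default_observations(default_cohort):
    return observations_from(*default_cohort)


@pytest.fixture(scope="session")
def default_fit(default_observations):
    return fit_gee(default_observations, predictor_name="suv_max@48h")


@pytest.fixture(scope="session")
def published_fit():
    """Regression fit built from the published log-log coefficients."""
    return RegressionFit(
        beta0=0.697, beta1=1.002, robust_cov=np.zeros((2, 2)),
        sigma2=0.1924, n_lesions=208, n_patients=21,
        predictor_name="suv_max@48h",
    )
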