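"""Simulation-based prediction intervals and leave-one-patient-out
cross-validation.

A prediction interval for a *new* lesion's AUC must carry both the sampling
uncertainty of the fitted regression and the lesion-to-lesion scatter.  An
analytic interval is awkward under the clustered fit, so intervals are
simulated: for each draw, the residual variance is sampled from its scaled
inverse-chi-square sampling distribution, the coefficients from a normal
centred on the estimates with the cluster-robust covariance, and a new
log-AUC from the resulting predictive normal.  Interval endpoints are
empirical tail quantiles, exponentiated back to the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import RegressionFit, fit_gee, predict_mean

__all__ = [
    "PredictionInterval",
    "CVResult",
    "predictive_log_draws",
    "simulate_pi",
    "simulate_pi_batch",
    "loo_patient_cv",
]


@dataclass(frozen=True)
class PredictionInterval:
    predictor_value: float
    point_estimate: float
    lower: float
    upper: float
    level: float
    n_sims: int
    seed: int

    def __post_init__(self) -> None:
        if not self.lower > 0:
            raise ValueError("lower bound must be > 0 on the natural scale")
        if self.level >= 0.5 and not (
            self.lower <= self.point_estimate * (1 + 1e-12)
            and self.point_estimate <= self.upper * (1 + 1e-12)
        ):
            raise ValueError("interval must bracket the point estimate")

    def contains(self, value: float) -> bool:
        """Non-strict containment; a lesion is 'outside' the PI when its
        observed AUC is strictly below lower or strictly above upper."""
        return self.lower <= value <= self.upper


@dataclass
class CVResult:
    """Leave-one-patient-out cross-validation output."""

    records: pd.DataFrame
    n_outside: int
    fraction_outside: float
    cv_squared_error: float


def _draw_parameters(
    fit: RegressionFit, n_sims: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (beta draws, sigma draws) from their sampling distributions.

    sigma^2 ~ df * sigma2_hat / chi2_df with a cluster-aware df
    (n_patients - 2): under patient-level correlation the residual-variance
    estimate has an effective sample size of order the number of patients,
    and the lesion-level df understates its spread (prediction intervals
    then undercover).  beta ~ MVN(beta_hat, V_robust).  Degenerate (zero)
    covariance or variance collapses to point masses.
    """
    df = max(fit.n_patients - 2, 1)
    if fit.sigma2 > 0:
        sigma = np.sqrt(df * fit.sigma2 / rng.chisquare(df, size=n_sims))
    else:
        sigma = np.zeros(n_sims)
    mean = np.array([fit.beta0, fit.beta1])
    cov = fit.robust_cov
    if np.all(cov == 0):
        betas = np.tile(mean, (n_sims, 1))
    else:
        betas = rng.multivariate_normal(mean, cov, size=n_sims, method="svd")
    return betas, sigma


def predictive_log_draws(
    fit: RegressionFit,
    predictor_values,
    n_sims: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Matrix of simulated ln(AUC) draws, shape (n_values, n_sims).

    Coefficient and sigma draws are shared across predictor values (one
    simulation set); the residual noise is independent per (value, draw).
    """
    x = np.atleast_1d(np.asarray(predictor_values, dtype=float))
    if np.any(x <= 0):
        raise ValueError("predictor values must be > 0")
    betas, sigma = _draw_parameters(fit, n_sims, rng)
    mean = betas[:, 0][None, :] + np.outer(np.log(x), betas[:, 1])
    noise = rng.standard_normal((x.size, n_sims)) * sigma[None, :]
    return mean + noise


def simulate_pi(
    fit: RegressionFit,
    predictor_value: float,
    level: float = 0.95,
    n_sims: int = 10_000,
    seed: int = 0,
) -> PredictionInterval:
    """Simulated prediction interval for a new lesion's AUC at one predictor
    value.  Endpoints are the symmetric tail quantiles (linear interpolation
    of order statistics) of the log-scale draws, exponentiated."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000")
    rng = np.random.default_rng(seed)
    draws = predictive_log_draws(fit, [predictor_value], n_sims, rng)[0]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.exp(np.quantile(draws, [alpha, 1.0 - alpha]))
    return PredictionInterval(
        predictor_value=float(predictor_value),
        point_estimate=float(predict_mean(fit, predictor_value)),
        lower=float(lo),
        upper=float(hi),
        level=level,
        n_sims=n_sims,
        seed=seed,
    )


def simulate_pi_batch(
    fit: RegressionFit,
    predictor_values,
    level: float = 0.95,
    n_sims: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Vectorised PIs for many predictor values from one simulation set."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x = np.atleast_1d(np.asarray(predictor_values, dtype=float))
    rng = np.random.default_rng(seed)
    draws = predictive_log_draws(fit, x, n_sims, rng)
    alpha = (1.0 - level) / 2.0
    q = np.exp(np.quantile(draws, [alpha, 1.0 - alpha], axis=1))
    return pd.DataFrame(
        {
            "predictor_value": x,
            "point_estimate": predict_mean(fit, x),
            "lower": q[0],
            "upper": q[1],
            "level": level,
        }
    )


def loo_patient_cv(
    observations,
    pi_level: float = 0.95,
    n_sims: int = 10_000,
    seed: int = 0,
    working_correlation: str = "independence",
) -> CVResult:
    """Leave-one-patient-out cross-validation of the prediction pipeline.

    For each patient, the regression is refit on the remaining patients and
    a PI is simulated at each held-out lesion's predictor value; the lesion
    is flagged outside if its observed AUC falls strictly beyond either
    bound.  The cross-validated error is the mean over all lesions of the
    squared log-scale difference between predicted and observed AUC.
    """
    if isinstance(observations, pd.DataFrame):
        df = observations.reset_index(drop=True)
    else:
        df = pd.DataFrame(
            {
                "patient_id": [o.patient_id for o in observations],
                "lesion_id": [o.lesion_id for o in observations],
                "predictor_value": [o.predictor_value for o in observations],
                "auc": [o.auc for o in observations],
            }
        )
    if "lesion_id" not in df.columns:
        df = df.assign(lesion_id=[f"lesion{i}" for i in range(len(df))])
    patients = pd.unique(df["patient_id"])
    if patients.size < 3:
        raise ValueError("need >= 3 patient clusters for leave-one-patient-out CV")

    fold_seeds = np.random.SeedSequence(seed).spawn(patients.size)
    records = []
    for pid, fold_seed in zip(patients, fold_seeds):
        held = df[df["patient_id"] == pid]
        rest = df[df["patient_id"] != pid]
        try:
            fit = fit_gee(rest, working_correlation=working_correlation)
        except Exception as err:
            raise RuntimeError(f"refit failed for held-out patient {pid}: {err}") from err
        x = held["predictor_value"].to_numpy(float)
        rng = np.random.default_rng(fold_seed)
        draws = predictive_log_draws(fit, x, n_sims, rng)
        alpha = (1.0 - pi_level) / 2.0
        q = np.exp(np.quantile(draws, [alpha, 1.0 - alpha], axis=1))
        pred = np.exp(fit.beta0 + fit.beta1 * np.log(x))
        obs = held["auc"].to_numpy(float)
        outside = (obs < q[0]) | (obs > q[1])
        records.append(
            pd.DataFrame(
                {
                    "lesion_id": held["lesion_id"].to_numpy(),
                    "held_out_patient": pid,
                    "predictor_value": x,
                    "predicted_auc": pred,
                    "pi_lower": q[0],
                    "pi_upper": q[1],
                    "observed_auc": obs,
                    "inside_pi": ~outside,
                    "squared_log_error": (np.log(pred) - np.log(obs)) ** 2,
                }
            )
        )
    rec = pd.concat(records, ignore_index=True)
    n_outside = int((~rec["inside_pi"]).sum())
    return CVResult(
        records=rec,
        n_outside=n_outside,
        fraction_outside=n_outside / len(rec),
        cv_squared_error=float(rec["squared_log_error"].mean()),
    )
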