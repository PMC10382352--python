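"""Clustered log-log regression of integrated uptake on a single-timepoint
predictor.

Lesions from the same patient are correlated, so the linear model

    ln(AUC_ij) = beta0 + beta1 * ln(x_ij) + eps_ij

(i indexes patients, j lesions; x is e.g. the 48-h SUVmax) is estimated by
generalized estimating equations with an exchangeable working correlation
and a cluster-robust (sandwich) covariance for (beta0, beta1).  The residual
variance of the log-scale errors is retained for simulation-based prediction
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LesionObservation",
    "RegressionFit",
    "ClusteredLogLogRegressor",
    "fit_gee",
    "predict_mean",
    "compare_predictors",
]


@dataclass(frozen=True)
class LesionObservation:
    """One lesion's (predictor, AUC) pair with its patient cluster."""

    patient_id: str
    lesion_id: str
    predictor_value: float
    auc: float


@dataclass(frozen=True)
class RegressionFit:
    """Fitted log-log regression: coefficients, robust covariance, residual
    variance, and bookkeeping needed by the prediction-interval simulation."""

    beta0: float
    beta1: float
    robust_cov: np.ndarray
    sigma2: float
    n_lesions: int
    n_patients: int
    predictor_name: str = "predictor"

    def __post_init__(self) -> None:
        object.__setattr__(self, "robust_cov", np.asarray(self.robust_cov, float))
        if self.robust_cov.shape != (2, 2):
            raise ValueError("robust_cov must be 2x2")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.n_patients > self.n_lesions:
            raise ValueError("n_patients cannot exceed n_lesions")


class ClusteredLogLogRegressor(RegressorMixin, BaseEstimator):
    """GEE fit of ln(y) on ln(x) with patient-level clustering.

    Parameters
    ----------
    working_correlation : {"independence", "exchangeable"}
        Working correlation structure.  Independence (cluster-robust least
        squares) is the default: with an estimated exchangeable correlation
        the plug-in sandwich ignores the correlation-parameter uncertainty
        and its slope intervals undercover at a few dozen clusters.

    Attributes
    ----------
    beta0_, beta1_ : float
        Intercept and slope on the log-log scale.
    robust_cov_ : ndarray of shape (2, 2)
        Cluster-robust covariance of (beta0, beta1).
    sigma2_ : float
        Residual variance of log-scale residuals (denominator n - 2).
    result_ : RegressionFit
        Immutable summary consumed by the prediction/prescription modules.
    """

    def __init__(self, working_correlation: str = "independence"):
        self.working_correlation = working_correlation

    def fit(self, X, y, groups=None, predictor_name: str = "predictor"):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if groups is None:
            raise ValueError("groups (patient ids) are required")
        groups = np.asarray(groups)
        if not (x.size == y.size == groups.size):
            raise ValueError("X, y and groups must have equal length")
        if x.size < 3:
            raise ValueError("need >= 3 observations")
        bad = np.nonzero((x <= 0) | (y <= 0))[0]
        if bad.size:
            raise ValueError(
                f"log transform needs positive values; offending rows: {bad[:5].tolist()}"
            )
        uniq = pd.unique(groups)
        if uniq.size < 2:
            raise ValueError("need >= 2 patient clusters (robust variance undefined)")

        lx, ly = np.log(x), np.log(y)
        design = np.column_stack([np.ones_like(lx), lx])
        # OLS pre-pass: perfectly linear data degenerates the GEE scale and
        # correlation estimates, so return the exact solution directly.
        beta_ols, *_ = np.linalg.lstsq(design, ly, rcond=None)
        resid_ols = ly - design @ beta_ols
        if np.max(np.abs(resid_ols)) <= 1e-10 * max(1.0, np.max(np.abs(ly))):
            beta = beta_ols
            cov = np.zeros((2, 2))
            resid = resid_ols
        else:
            cov_struct = (
                sm.cov_struct.Exchangeable()
                if self.working_correlation == "exchangeable"
                else sm.cov_struct.Independence()
            )
            model = sm.GEE(
                ly, design, groups=groups,
                family=sm.families.Gaussian(), cov_struct=cov_struct,
            )
            res = model.fit()
            beta = np.asarray(res.params, float)
            cov = np.asarray(res.cov_params(), float)  # robust (sandwich)
            resid = ly - design @ beta

        self.beta0_ = float(beta[0])
        self.beta1_ = float(beta[1])
        self.robust_cov_ = cov
        self.sigma2_ = float(resid @ resid / max(x.size - 2, 1))
        self.n_lesions_ = int(x.size)
        self.n_clusters_ = int(uniq.size)
        self.result_ = RegressionFit(
            beta0=self.beta0_, beta1=self.beta1_, robust_cov=cov,
            sigma2=self.sigma2_, n_lesions=self.n_lesions_,
            n_patients=self.n_clusters_, predictor_name=predictor_name,
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "result_")
        x = np.asarray(X, dtype=float).ravel()
        if np.any(x <= 0):
            raise ValueError("predictor values must be > 0")
        return np.exp(self.beta0_ + self.beta1_ * np.log(x))


def fit_gee(
    observations,
    working_correlation: str = "independence",
    predictor_name: str = "predictor",
) -> RegressionFit:
    """Fit the clustered log-log model to lesion observations.

    ``observations`` is a sequence of :class:`LesionObservation` or a
    DataFrame with columns ``patient_id``, ``predictor_value``, ``auc``.
    """
    if isinstance(observations, pd.DataFrame):
        df = observations
        x, y, g = df["predictor_value"], df["auc"], df["patient_id"]
    else:
        obs = list(observations)
        x = [o.predictor_value for o in obs]
        y = [o.auc for o in obs]
        g = [o.patient_id for o in obs]
    est = ClusteredLogLogRegressor(working_correlation=working_correlation)
    est.fit(np.asarray(x, float), np.asarray(y, float), groups=np.asarray(g),
            predictor_name=predictor_name)
    return est.result_


def predict_mean(fit: RegressionFit, predictor_value) -> np.ndarray | float:
    """Mean-curve AUC prediction exp(beta0 + beta1 ln x)."""
    x = np.asarray(predictor_value, dtype=float)
    if np.any(x <= 0):
        raise ValueError("predictor value must be > 0")
    out = np.exp(fit.beta0 + fit.beta1 * np.log(x))
    return float(out) if out.ndim == 0 else out


def compare_predictors(
    df: pd.DataFrame,
    predictor_cols,
    auc_col: str = "auc",
    group_col: str = "patient_id",
    pi_level: float = 0.95,
    n_sims: int = 2000,
    seed: int = 0,
    working_correlation: str = "independence",
) -> pd.DataFrame:
    """Rank candidate single-timepoint predictors.

    For each predictor column: GEE slope and robust SE, in-sample mean
    squared log-scale prediction error, and leave-one-patient-out
    cross-validated squared error.  Rows with non-positive or missing
    predictor values are dropped per predictor.  The lowest-CV-error
    predictor is flagged.
    """
    from .prediction import loo_patient_cv  # local import: avoids cycle

    predictor_cols = list(predictor_cols)
    if not predictor_cols:
        raise ValueError("empty candidate predictor set")
    rows = []
    for col in predictor_cols:
        sub = df[[group_col, col, auc_col]].dropna()
        sub = sub[(sub[col] > 0) & (sub[auc_col] > 0)]
        if sub.shape[0] < 3 or sub[group_col].nunique() < 2:
            raise ValueError(f"predictor {col}: insufficient data")
        obs = sub.rename(columns={col: "predictor_value", auc_col: "auc",
                                  group_col: "patient_id"})
        fit = fit_gee(obs, working_correlation, predictor_name=col)
        lr = np.log(obs["auc"].to_numpy()) - (
            fit.beta0 + fit.beta1 * np.log(obs["predictor_value"].to_numpy())
        )
        cv = loo_patient_cv(obs, pi_level=pi_level, n_sims=n_sims, seed=seed,
                            working_correlation=working_correlation)
        rows.append(
            {
                "predictor": col,
                "n": fit.n_lesions,
                "slope": fit.beta1,
                "robust_se": float(np.sqrt(fit.robust_cov[1, 1])),
                "squared_error": float(np.mean(lr**2)),
                "cv_squared_error": cv.cv_squared_error,
            }
        )
    out = pd.DataFrame(rows)
    out["best"] = out["cv_squared_error"] == out["cv_squared_error"].min()
    return out
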