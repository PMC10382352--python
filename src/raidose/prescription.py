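"""Translate predicted AUC and its prediction interval into administered
I-131 activity at chosen lesion-coverage probabilities.

The dose delivered to a lesion per mCi administered is AUC x 0.405 cGy, so
the activity that gives a target dose to a fraction ``c`` of lesions with a
given measured uptake is

    activity_mCi = target_cGy / (AUC_q x 0.405),

where AUC_q is the (1 - c) tail quantile of the simulated predictive AUC
distribution (lesions with AUC above the quantile receive at least the
target).  Coverage 0.5 uses the mean log-scale prediction, i.e. the
predictive median on the natural scale.  Recommendations are capped at the
patient's maximum tolerated activity (MTA, from blood/whole-body dosimetry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosimetry import DEFAULT_CONSTANTS, DoseConstants, LesionDosimetry
from .prediction import predictive_log_draws
from .regression import RegressionFit, predict_mean

__all__ = [
    "PrescriptionRow",
    "TreatmentRecommendation",
    "activity_for_coverage",
    "build_prescription_table",
    "prescription_frame",
    "recommend_activity",
]

DEFAULT_COVERAGES = (0.5, 0.9, 0.95, 0.975)


@dataclass
class PrescriptionRow:
    """One predictor value's predicted AUC, PI, and activities by coverage."""

    predictor_value: float
    mean_auc: float
    pi_lower: float
    pi_upper: float
    pi_level: float
    activities: dict  # coverage fraction -> (GBq, mCi)


@dataclass
class TreatmentRecommendation:
    patient_id: str
    index_lesion_id: str
    required_activity_gbq: float
    mta_gbq: float
    recommended_activity_gbq: float
    capped: bool
    projected_doses_cgy: dict = field(default_factory=dict)


def _activity_from_auc(
    auc_q: float, target_dose_cgy: float, constants: DoseConstants
) -> tuple[float, float]:
    mci = target_dose_cgy / (auc_q * constants.equilibrium_dose_constant)
    return mci / constants.mci_per_gbq, mci


def activity_for_coverage(
    fit: RegressionFit,
    predictor_value: float,
    target_dose_cgy: float = 2000.0,
    coverage: float = 0.95,
    n_sims: int = 10_000,
    seed: int = 0,
    constants: DoseConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Activity (GBq, mCi) delivering ``target_dose_cgy`` to a fraction
    ``coverage`` of lesions with the given measured uptake."""
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    if not target_dose_cgy > 0:
        raise ValueError("target dose must be > 0")
    if coverage == 0.5:
        auc_q = float(predict_mean(fit, predictor_value))
    else:
        rng = np.random.default_rng(seed)
        draws = predictive_log_draws(fit, [predictor_value], n_sims, rng)[0]
        auc_q = float(np.exp(np.quantile(draws, 1.0 - coverage)))
    return _activity_from_auc(auc_q, target_dose_cgy, constants)


def build_prescription_table(
    fit: RegressionFit,
    suv_grid,
    target_dose_cgy: float = 2000.0,
    coverages=DEFAULT_COVERAGES,
    pi_level: float = 0.95,
    n_sims: int = 10_000,
    seed: int = 0,
    constants: DoseConstants = DEFAULT_CONSTANTS,
) -> list[PrescriptionRow]:
    """One row per grid value: mean AUC, PI bounds, and activities per
    coverage fraction, all from a single simulation set per row."""
    grid = np.atleast_1d(np.asarray(suv_grid, dtype=float))
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("suv_grid must be non-empty and positive")
    rng = np.random.default_rng(seed)
    draws = predictive_log_draws(fit, grid, n_sims, rng)
    alpha = (1.0 - pi_level) / 2.0
    rows = []
    for i, x in enumerate(grid):
        d = draws[i]
        lo, hi = np.exp(np.quantile(d, [alpha, 1.0 - alpha]))
        acts = {}
        for c in sorted(coverages):
            if c == 0.5:
                auc_q = float(predict_mean(fit, x))
            else:
                auc_q = float(np.exp(np.quantile(d, 1.0 - c)))
            acts[c] = _activity_from_auc(auc_q, target_dose_cgy, constants)
        rows.append(
            PrescriptionRow(
                predictor_value=float(x),
                mean_auc=float(predict_mean(fit, x)),
                pi_lower=float(lo),
                pi_upper=float(hi),
                pi_level=pi_level,
                activities=acts,
            )
        )
    return rows


def prescription_frame(rows: list[PrescriptionRow]) -> pd.DataFrame:
    """Flatten prescription rows to a table (mirrors the clinical layout:
    predictor, mean AUC, 95% PI, activity columns per coverage)."""
    out = []
    for r in rows:
        rec = {
            "suv_48h": r.predictor_value,
            "mean_auc": r.mean_auc,
            "pi_lower": r.pi_lower,
            "pi_upper": r.pi_upper,
        }
        for c, (gbq, mci) in sorted(r.activities.items()):
            rec[f"activity_cov{c:g}_GBq"] = gbq
            rec[f"activity_cov{c:g}_mCi"] = mci
        out.append(rec)
    return pd.DataFrame(out)


def recommend_activity(
    lesions,
    mta_gbq: float,
    target_dose_cgy: float = 2000.0,
    coverage: float = 0.95,
    strategy: str = "lowest",
    fit: RegressionFit | None = None,
    n_sims: int = 10_000,
    seed: int = 0,
    constants: DoseConstants = DEFAULT_CONSTANTS,
    suv_filter: float = 1.0,
    patient_id: str = "",
) -> TreatmentRecommendation:
    """Pick an index lesion and recommend an administered activity <= MTA.

    Two input modes:

    * full dosimetry -- ``lesions`` is a list of :class:`LesionDosimetry`;
      the index lesion is the one with the lowest (default strategy)
      PVC dose per GBq, and the required activity comes from its measured
      dose rate.
    * single timepoint -- ``lesions`` is a list of ``(lesion_id, suv)``
      pairs and ``fit`` must be given; lesions with suv <= ``suv_filter``
      are excluded (no treatment is planned for lesions with no
      differential uptake), the index lesion is chosen by predictor value,
      and the required activity comes from :func:`activity_for_coverage`.
    """
    if not mta_gbq > 0:
        raise ValueError("mta_gbq must be > 0")
    lesions = list(lesions)
    if not lesions:
        raise ValueError("need >= 1 lesion")

    def pick(vals):
        order = np.argsort(vals, kind="stable")
        if strategy == "lowest":
            return order[0]
        if strategy == "highest":
            return order[-1]
        if strategy == "median":
            return order[(len(order) - 1) // 2]
        raise ValueError(f"unknown strategy {strategy!r}")

    if all(isinstance(l, LesionDosimetry) for l in lesions):
        idx = pick([l.dose_per_gbq_pvc for l in lesions])
        index_lesion = lesions[idx]
        required = target_dose_cgy / index_lesion.dose_per_gbq_pvc
        capped = required > mta_gbq
        recommended = min(required, mta_gbq)
        doses = {l.lesion_id: l.dose_per_gbq_pvc * recommended for l in lesions}
        index_id = index_lesion.lesion_id
    else:
        if fit is None:
            raise ValueError("regression fit required for (lesion_id, suv) records")
        kept = [(lid, s) for lid, s in lesions if s > suv_filter]
        if not kept:
            raise ValueError(
                "no treatment is planned for lesions with no differential uptake "
                f"(all SUVmax <= {suv_filter})"
            )
        idx = pick([s for _, s in kept])
        index_id, index_suv = kept[idx]
        required, _ = activity_for_coverage(
            fit, index_suv, target_dose_cgy, coverage, n_sims, seed, constants
        )
        capped = required > mta_gbq
        recommended = min(required, mta_gbq)
        doses = {
            lid: float(predict_mean(fit, s))
            * constants.equilibrium_dose_constant
            * constants.mci_per_gbq
            * recommended
            for lid, s in kept
        }
    return TreatmentRecommendation(
        patient_id=patient_id,
        index_lesion_id=index_id,
        required_activity_gbq=float(required),
        mta_gbq=float(mta_gbq),
        recommended_activity_gbq=float(recommended),
        capped=bool(capped),
        projected_doses_cgy=doses,
    )
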