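"""Synthetic cohorts with the statistical structure of a metastatic
thyroid-cancer radioiodine imaging study.

The generator realizes, per lesion, exactly the model the analysis assumes:
a 48-h SUVmax spanning roughly three orders of magnitude, a log-log linear
relation between SUVmax and the therapy-isotope AUC with a patient-level
random effect (lesions within a patient share avidity) plus lesion-level
scatter, and dual-exponential imaging-isotope kinetics back-solved to be
consistent with that AUC.  Emitted time-activity samples carry
multiplicative lognormal measurement noise.  Cohort shape defaults emulate
the clinical setting: ~21 patients, 3-23 lesions each, four imaging
timepoints near 24/48/72/120 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import I124, I131

__all__ = ["CohortConfig", "generate_cohort", "make_table2_fixture",
           "TABLE2_ADMINISTERED_GBQ", "TABLE2_MTA_GBQ"]

_SITES = (
    "lung nodule", "bone met", "neck node", "thoracic node",
    "thyroid bed", "soft tissue", "liver met",
)


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic cohort.

    The log-log coefficients, variance split and SUV span are chosen so the
    synthetic cohort brackets the clinical cohort's summary statistics
    (median ~11-13 lesions per patient, 48-h SUVmax ~1-1000, lesion doses
    spanning >= 3 logs, ~5.6x ratio between 95% PI bounds at fixed SUV).
    """

    n_patients: int = 21
    lesions_per_patient: tuple[int, int] = (3, 23)  # uniform inclusive
    beta0: float = 0.697
    beta1: float = 1.002
    sigma_patient: float = 0.30   # SD of patient-level log-AUC random effect
    sigma_lesion: float = 0.32    # residual log-scale SD
    suv_log_range: tuple[float, float] = (0.0, float(np.log(1000.0)))
    lambda_uptake_range: tuple[float, float] = (0.03, 0.5)    # 1/h, log-uniform
    bio_half_life_range_h: tuple[float, float] = (48.0, 4800.0)  # log-uniform
    noise_sd: float = 0.10        # multiplicative lognormal TAC noise
    timepoints: tuple[float, ...] = (24.0, 48.0, 72.0, 120.0)
    sul_ratio: float = 0.75
    size_range_cm: tuple[float, float] = (0.4, 4.5)
    mta_lognormal: tuple[float, float] = (np.log(14.0), 0.5)  # GBq
    admin_MBq: float = 222.0
    a0_max: float = 1e7           # feasibility cap for the kinetic back-solve
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("sigma_patient", "sigma_lesion", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")


def _loguniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort as (long-format TAC table, per-lesion ground truth).

    Per patient, a random avidity effect b_i ~ N(0, sigma_patient) and an
    MTA are drawn.  Per lesion: ln SUV48 is drawn uniformly over the
    configured span, the therapy-isotope AUC follows
    ln AUC = beta0 + beta1 ln SUV48 + b_i + N(0, sigma_lesion), uptake and
    biological clearance rates are drawn log-uniformly, and the amplitude is
    back-solved from the closed-form AUC.  Measured SUVs are consistent with
    the kinetics (the noiseless model value at 48 h maps to the drawn
    SUV48); TAC and SUV samples get independent multiplicative noise.

    Raises a RuntimeError if a lesion's back-solved amplitude exceeds the
    feasibility cap after resampling.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lam_phys_124, lam_phys_131 = I124.decay_constant, I131.decay_constant
    t = np.asarray(cfg.timepoints, dtype=float)

    tac_rows, truth_rows = [], []
    for p in range(cfg.n_patients):
        pid = f"P{p + 1:02d}"
        b_i = rng.normal(0.0, cfg.sigma_patient)
        mta = float(np.exp(rng.normal(*cfg.mta_lognormal)))
        n_lesions = int(rng.integers(cfg.lesions_per_patient[0],
                                     cfg.lesions_per_patient[1] + 1))
        for j in range(n_lesions):
            lid = f"{pid}-L{j + 1:02d}"
            for attempt in range(20):
                ln_suv = rng.uniform(*cfg.suv_log_range)
                ln_auc = (cfg.beta0 + cfg.beta1 * ln_suv + b_i
                          + rng.normal(0.0, cfg.sigma_lesion))
                auc131 = np.exp(ln_auc)
                lam1 = float(_loguniform(rng, *cfg.lambda_uptake_range))
                lam_bio = float(np.log(2.0) / _loguniform(rng, *cfg.bio_half_life_range_h))
                lam2_131 = lam_bio + lam_phys_131
                lam2_124 = lam_bio + lam_phys_124
                a0 = auc131 * lam2_131 * (lam1 + lam2_131) / lam1
                if a0 <= cfg.a0_max:
                    break
            else:
                raise RuntimeError(
                    f"lesion {lid}: kinetic back-solve infeasible (a0 > "
                    f"{cfg.a0_max:g}) after 20 resamples"
                )
            conc = a0 * (1.0 - np.exp(-lam1 * t)) * np.exp(-lam2_124 * t)
            conc48 = a0 * (1.0 - np.exp(-lam1 * 48.0)) * np.exp(-lam2_124 * 48.0)
            suv_scale = np.exp(ln_suv) / conc48
            conc_meas = conc * np.exp(rng.normal(0.0, cfg.noise_sd, t.size))
            suv_meas = suv_scale * conc * np.exp(rng.normal(0.0, cfg.noise_sd, t.size))
            sul_meas = cfg.sul_ratio * suv_scale * conc * np.exp(
                rng.normal(0.0, cfg.noise_sd, t.size)
            )
            size = float(_loguniform(rng, *cfg.size_range_cm))
            site = _SITES[int(rng.integers(len(_SITES)))]
            for k, tk in enumerate(t):
                tac_rows.append(
                    (pid, lid, site, size, tk, conc_meas[k], suv_meas[k],
                     sul_meas[k], cfg.admin_MBq)
                )
            truth_rows.append(
                (pid, lid, size, a0, lam1, lam_bio, lam2_124, lam2_131,
                 auc131, float(np.exp(ln_suv)), b_i, mta)
            )

    cohort = pd.DataFrame(
        tac_rows,
        columns=[
            "patient_id", "lesion_id", "site", "mean_size_cm", "time_h",
            "conc_uCi_per_g_per_mCi", "suv_max", "sul", "admin_MBq",
        ],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id", "lesion_id", "mean_size_cm", "a0", "lambda_uptake",
            "lambda_bio", "lambda_clear_124", "lambda_clear_131", "auc_131",
            "suv48_true", "patient_effect", "mta_GBq",
        ],
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Printed single-patient dosimetry table, used as a verification fixture.
# ---------------------------------------------------------------------------

#: Activity administered to the fixture patient (GBq).
TABLE2_ADMINISTERED_GBQ = 15.06
#: That patient's maximum tolerated activity (GBq).
TABLE2_MTA_GBQ = 19.72

# lesion, size_cm, nonPVC cGy/GBq, PVC cGy/GBq, T1/2 eff (d), AUC, uCi/g@48h,
# SUV24, SUV48, SUV72, activity GBq, activity mCi, dose@15.06 GBq, dose@MTA.
# The "ant. aspect of thyroid cartilage" row is excluded: its printed digits
# run together and admit multiple parses.
_TABLE2_ROWS = [
    ("R. parietal skull",    4.03, 868, 1133, 8.02, 79.28, 0.29, 21.92, 25.58, 25.31,  1.77,  47.7, 17063, 22345),
    ("L. scapula",           3.63, 557,  749, 8.02, 50.87, 0.20, 14.66, 17.31, 17.55,  2.67,  72.1, 11284, 14778),
    ("R. ant. 2 rib",        4.10, 440,  573, 8.02, 40.22, 0.15, 10.89, 13.85, 13.18,  3.49,  94.4,  8622, 11291),
    ("L. lateral 7 rib",     3.17, 490,  695, 8.02, 44.73, 0.17, 12.79, 14.65, 16.07,  2.88,  77.8, 10469, 13711),
    ("L. post elements T3",  1.07,  68,  240, 2.33,  6.17, 0.05,  5.54,  3.57,  3.52,  8.33, 225.0,  3618,  4739),
    ("spinous process T4",   0.77, 247, 1398, 8.02, 22.52, 0.09,  6.56,  7.68,  8.58,  1.43,  38.7, 21056, 27575),
    ("T7 vertebral body",    0.60, 215, 1920, 5.24, 19.66, 0.10,  8.83,  8.03,  7.68,  1.04,  28.1, 28916, 37869),
    ("L2 vertebral body",    0.40, 193, 2703, 4.90, 17.63, 0.09,  7.71,  8.26,  7.56,  0.74,  20.0, 40710, 53314),
    ("L. post. acetabulum",  4.27, 213,  275, 6.30, 19.46, 0.09,  7.32,  6.87,  7.07,  7.29, 196.9,  4134,  5414),
    ("L. post. 5 rib",       1.90,  49,   97, 8.02,  4.51, 0.02,  1.63,  1.24,  1.25, 20.59, 556.4,  1462,  1916),
    ("L3 vertebral body",    0.87,  19,   90, 2.21,  1.76, 0.01,  1.48,  1.35,  0.84, 22.19, 599.7,  1357,  1778),
    ("L. thyroid bed",       0.93, 203,  865, 6.75, 18.57, 0.08,  5.44,  7.70,  5.31,  2.31,  62.5, 13022, 17054),
]


def make_table2_fixture() -> pd.DataFrame:
    """Published single-patient lesion dosimetry rows as typed records.

    Values are as printed (integer-rounded doses, two-decimal AUCs), so
    cross-checks against recomputed quantities must allow print rounding.
    """
    return pd.DataFrame(
        _TABLE2_ROWS,
        columns=[
            "lesion", "mean_size_cm", "dose_nonpvc_cGy_per_GBq",
            "dose_pvc_cGy_per_GBq", "t_half_effective_d",
            "auc_uCi_h_per_g_per_mCi", "uCi_per_g_48h", "suv_24h", "suv_48h",
            "suv_72h", "activity_2000cGy_GBq", "activity_2000cGy_mCi",
            "dose_at_admin_cGy", "dose_at_mta_cGy",
        ],
    )
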