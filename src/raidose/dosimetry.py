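"""MIRD-style lesion absorbed dose from integrated activity concentration.

The absorbed dose delivered to a lesion by the non-penetrating beta
emissions of I-131 is the time-integrated activity concentration (AUC,
uCi.h/g per mCi administered) multiplied by the equilibrium dose constant
Delta = 0.405 g.cGy/(uCi.h) (equivalently 10.95 g.cGy/(MBq.h)).  Expressed
per GBq of administered activity,

    dose [cGy/GBq] = AUC * 0.405 * 27.027

since 1 GBq = 27.027 mCi.  Small lesions are partial-volume corrected by
dividing by the recovery coefficient of an equivalent uniform sphere blurred
by the scanner's Gaussian point-spread function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticFit, auc as _auc, effective_half_life

__all__ = [
    "DoseConstants",
    "DEFAULT_CONSTANTS",
    "LesionDosimetry",
    "dose_per_unit_activity",
    "recovery_coefficient",
    "apply_pvc",
    "activity_for_target",
    "absorbed_dose",
    "lesion_dosimetry",
    "dosimetry_table",
]


@dataclass(frozen=True)
class DoseConstants:
    """Physical constants of the dose calculation.

    equilibrium_dose_constant : g.cGy/(uCi.h) for I-131 beta emissions.
    mci_per_gbq : unit conversion, 27.027 mCi per GBq.
    scanner_fwhm_cm : PET point-spread FWHM used for partial-volume recovery.
    rc_floor : lower clamp on the recovery coefficient, to avoid unbounded
        correction for sub-resolution lesions.
    """

    equilibrium_dose_constant: float = 0.405
    mci_per_gbq: float = 27.027
    scanner_fwhm_cm: float = 0.6
    rc_floor: float = 0.05

    def __post_init__(self) -> None:
        for name in ("equilibrium_dose_constant", "mci_per_gbq", "scanner_fwhm_cm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        # 0.405 g.cGy/(uCi.h) and 10.95 g.cGy/(MBq.h) describe the same
        # constant; guard against inconsistent overrides.
        per_mbq = self.equilibrium_dose_constant * self.mci_per_gbq
        if not math.isclose(per_mbq, 10.95, rel_tol=0.005):
            raise ValueError(
                f"equilibrium_dose_constant x mci_per_gbq = {per_mbq:.4f}; "
                "expected ~10.95 g.cGy/(MBq.h)"
            )


DEFAULT_CONSTANTS = DoseConstants()


def dose_per_unit_activity(
    auc: float, constants: DoseConstants = DEFAULT_CONSTANTS
) -> float:
    """Absorbed dose per administered GBq (cGy/GBq) from AUC (uCi.h/g per mCi)."""
    if auc < 0:
        raise ValueError("auc must be >= 0")
    return auc * constants.equilibrium_dose_constant * constants.mci_per_gbq


def recovery_coefficient(
    diameter_cm: float, fwhm_cm: float = 0.6, floor: float = 0.05
) -> float:
    """Center-value recovery of a uniform sphere blurred by a Gaussian PSF.

    For a sphere of radius R imaged with an isotropic Gaussian of standard
    deviation sigma = FWHM/2.355, the recovered fraction of the true
    concentration at the sphere center is

        RC = erf(R / (sigma sqrt 2)) - (R/sigma) sqrt(2/pi) exp(-R^2/(2 sigma^2))

    i.e. the integral of the 3-D Gaussian over the sphere.  The result is
    clamped to [floor, 1].
    """
    if diameter_cm < 0:
        raise ValueError("diameter must be >= 0")
    if not fwhm_cm > 0:
        raise ValueError("fwhm must be > 0")
    sigma = fwhm_cm / 2.355
    r = diameter_cm / 2.0 / sigma
    rc = math.erf(r / math.sqrt(2.0)) - r * math.sqrt(2.0 / math.pi) * math.exp(
        -0.5 * r * r
    )
    return min(1.0, max(float(floor), rc))


def apply_pvc(dose_nonpvc: float, rc: float) -> float:
    """Partial-volume-correct a dose (or concentration) by dividing by RC."""
    if not 0 < rc <= 1:
        raise ValueError("recovery coefficient must be in (0, 1]")
    return dose_nonpvc / rc


def activity_for_target(
    target_dose_cgy: float,
    dose_per_gbq: float,
    constants: DoseConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Administered activity (GBq, mCi) required to deliver a target dose."""
    if target_dose_cgy < 0:
        raise ValueError("target dose must be >= 0")
    if not dose_per_gbq > 0:
        raise ValueError("dose_per_gbq must be > 0: lesion cannot reach target")
    gbq = target_dose_cgy / dose_per_gbq
    return gbq, gbq * constants.mci_per_gbq


def absorbed_dose(dose_per_gbq: float, administered_gbq: float) -> float:
    """Projected lesion dose (cGy) for an administered activity (GBq)."""
    if dose_per_gbq < 0 or administered_gbq < 0:
        raise ValueError("inputs must be >= 0")
    return dose_per_gbq * administered_gbq


@dataclass
class LesionDosimetry:
    """Per-lesion dosimetry summary (one row of the dosimetry report)."""

    lesion_id: str
    auc: float
    effective_half_life_d: float
    recovery_coefficient: float
    dose_per_gbq_nonpvc: float
    dose_per_gbq_pvc: float
    activity_for_target_gbq: float = float("nan")
    activity_for_target_mci: float = float("nan")
    projected_dose_at_admin: float = float("nan")
    projected_dose_at_mta: float = float("nan")
    patient_id: str = ""
    site_label: str = ""
    mean_size_cm: float = float("nan")


def lesion_dosimetry(
    fit: KineticFit,
    lesion_id: str = "",
    mean_size_cm: float = float("nan"),
    target_dose_cgy: float = 2000.0,
    administered_gbq: float | None = None,
    mta_gbq: float | None = None,
    constants: DoseConstants = DEFAULT_CONSTANTS,
    patient_id: str = "",
    site_label: str = "",
) -> LesionDosimetry:
    """Full dose workup for one lesion from its therapy-isotope kinetic fit.

    ``fit`` must already carry the therapy isotope's decay constant (see
    :func:`raidose.kinetics.substitute_isotope`).
    """
    a = _auc(fit)
    nonpvc = dose_per_unit_activity(a, constants)
    if np.isfinite(mean_size_cm):
        rc = recovery_coefficient(
            mean_size_cm, constants.scanner_fwhm_cm, constants.rc_floor
        )
    else:
        rc = 1.0
    pvc = apply_pvc(nonpvc, rc)
    row = LesionDosimetry(
        lesion_id=lesion_id,
        auc=a,
        effective_half_life_d=effective_half_life(fit),
        recovery_coefficient=rc,
        dose_per_gbq_nonpvc=nonpvc,
        dose_per_gbq_pvc=pvc,
        patient_id=patient_id,
        site_label=site_label,
        mean_size_cm=mean_size_cm,
    )
    if pvc > 0 and target_dose_cgy is not None:
        row.activity_for_target_gbq, row.activity_for_target_mci = activity_for_target(
            target_dose_cgy, pvc, constants
        )
    if administered_gbq is not None:
        row.projected_dose_at_admin = absorbed_dose(pvc, administered_gbq)
    if mta_gbq is not None:
        row.projected_dose_at_mta = absorbed_dose(pvc, mta_gbq)
    return row


def dosimetry_table(rows: list[LesionDosimetry]) -> pd.DataFrame:
    """Assemble per-lesion dosimetry records into a report table."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "lesion_id": [r.lesion_id for r in rows],
            "site": [r.site_label for r in rows],
            "mean_size_cm": [r.mean_size_cm for r in rows],
            "dose_nonpvc_cGy_per_GBq": [r.dose_per_gbq_nonpvc for r in rows],
            "dose_pvc_cGy_per_GBq": [r.dose_per_gbq_pvc for r in rows],
            "t_half_effective_d": [r.effective_half_life_d for r in rows],
            "auc_uCi_h_per_g_per_mCi": [r.auc for r in rows],
            "recovery_coefficient": [r.recovery_coefficient for r in rows],
            "activity_for_target_GBq": [r.activity_for_target_gbq for r in rows],
            "activity_for_target_mCi": [r.activity_for_target_mci for r in rows],
            "projected_dose_at_admin_cGy": [r.projected_dose_at_admin for r in rows],
            "projected_dose_at_mta_cGy": [r.projected_dose_at_mta for r in rows],
        }
    )
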