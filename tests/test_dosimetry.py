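import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from raidose.dosimetry import (
    DoseConstants,
    absorbed_dose,
    activity_for_target,
    apply_pvc,
    dose_per_unit_activity,
    lesion_dosimetry,
    recovery_coefficient,
)
from raidose.kinetics import I131, KineticFit
from raidose.synthetic_data import (
    TABLE2_ADMINISTERED_GBQ,
    TABLE2_MTA_GBQ,
    make_table2_fixture,
)


def radial_oracle(diameter, fwhm):
    """Numerical 3-D sphere/Gaussian convolution at the center, reduced by
    spherical symmetry to a radial quadrature (independent of erf)."""
    s = fwhm / 2.355
    r_max = diameter / 2.0
    f = lambda r: 4 * np.pi * r**2 * (2 * np.pi * s**2) ** -1.5 * np.exp(  # noqa: E731
        -(r**2) / (2 * s**2)
    )
    val, _ = quad(f, 0.0, r_max, limit=200)
    return val


def cartesian_grid_oracle(diameter, fwhm, h=0.005):
    """Literal 3-D Cartesian midpoint integration of the Gaussian over the
    sphere (the blurred image value at the sphere center)."""
    s = fwhm / 2.355
    r_cap = diameter / 2.0
    ax = np.arange(-r_cap + h / 2.0, r_cap, h)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    total = 0.0
    for z in ax:
        r2 = xx**2 + yy**2 + z**2
        total += np.exp(-r2[r2 <= r_cap**2] / (2 * s**2)).sum()
    return total * h**3 * (2 * np.pi * s**2) ** -1.5


class TestPublishedLesionTable:
    """Each printed lesion row must be internally consistent with the dose
    pipeline arithmetic, within print rounding."""

    @pytest.fixture()
    def fixture(self):
        return make_table2_fixture()

    def test_fixture_has_enough_rows(self, fixture):
        assert len(fixture) >= 10

    def test_dose_per_gbq_from_auc(self, fixture):
        for _, row in fixture.iterrows():
            computed = dose_per_unit_activity(row["auc_uCi_h_per_g_per_mCi"])
            printed = row["dose_nonpvc_cGy_per_GBq"]
            # printed dose is integer-rounded and printed AUC has 2 decimals
            assert abs(computed - printed) <= max(0.005 * printed, 0.6), row["lesion"]

    def test_activity_to_reach_target(self, fixture):
        for _, row in fixture.iterrows():
            gbq, mci = activity_for_target(2000.0, row["dose_pvc_cGy_per_GBq"])
            assert gbq == pytest.approx(row["activity_2000cGy_GBq"], rel=0.005)
            assert mci == pytest.approx(row["activity_2000cGy_mCi"], rel=0.005)

    @pytest.mark.parametrize(
        "activity,column",
        [(TABLE2_ADMINISTERED_GBQ, "dose_at_admin_cGy"),
         (TABLE2_MTA_GBQ, "dose_at_mta_cGy")],
    )
    def test_projected_doses(self, fixture, activity, column):
        for _, row in fixture.iterrows():
            computed = absorbed_dose(row["dose_pvc_cGy_per_GBq"], activity)
            assert computed == pytest.approx(row[column], rel=0.005), row["lesion"]

    def test_pvc_never_below_nonpvc_and_half_life_capped(self, fixture):
        assert (fixture["dose_pvc_cGy_per_GBq"]
                >= fixture["dose_nonpvc_cGy_per_GBq"]).all()
        assert (fixture["t_half_effective_d"] <= 8.02 + 1e-9).all()


class TestDoseArithmetic:
    @pytest.mark.parametrize("auc,printed", [(19.66, 215), (79.28, 868)])
    def test_dose_per_unit_activity_examples(self, auc, printed):
        assert dose_per_unit_activity(auc) == pytest.approx(printed, rel=0.005)

    def test_zero_auc_gives_zero_dose(self):
        assert dose_per_unit_activity(0.0) == 0.0

    def test_negative_auc_rejected(self):
        with pytest.raises(ValueError):
            dose_per_unit_activity(-1.0)

    @pytest.mark.parametrize(
        "target,dpg,gbq", [(2000.0, 1920.0, 1.042), (2000.0, 240.0, 8.333)]
    )
    def test_activity_for_target_examples(self, target, dpg, gbq):
        got_gbq, got_mci = activity_for_target(target, dpg)
        assert got_gbq == pytest.approx(gbq, abs=5e-4)
        assert got_mci == pytest.approx(got_gbq * 27.027, rel=1e-12)

    def test_zero_target_needs_no_activity(self):
        assert activity_for_target(0.0, 500.0)[0] == 0.0

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError, match="cannot reach"):
            activity_for_target(2000.0, 0.0)

    @pytest.mark.parametrize(
        "dpg,act,printed", [(1398.0, 15.06, 21056), (1133.0, 19.72, 22345)]
    )
    def test_absorbed_dose_examples(self, dpg, act, printed):
        assert absorbed_dose(dpg, act) == pytest.approx(printed, rel=5e-4)

    def test_absorbed_dose_zero_activity(self):
        assert absorbed_dose(1000.0, 0.0) == 0.0

    @given(dpg=st.floats(1e-3, 1e5), target=st.floats(1e-3, 1e6))
    def test_activity_dose_round_trip(self, dpg, target):
        gbq, _ = activity_for_target(target, dpg)
        assert absorbed_dose(dpg, gbq) == pytest.approx(target, rel=1e-9)

    def test_constants_consistency_guard(self):
        with pytest.raises(ValueError, match="10.95"):
            DoseConstants(equilibrium_dose_constant=0.5)


class TestPartialVolume:
    def test_large_sphere_fully_recovered(self):
        assert recovery_coefficient(60.0, 0.6) == pytest.approx(1.0, abs=1e-10)

    def test_point_lesion_clamped_to_floor(self):
        assert recovery_coefficient(0.0, 0.6, floor=0.05) == 0.05

    def test_closed_form_matches_radial_oracle(self):
        for d in np.arange(0.2, 5.01, 0.2):
            assert recovery_coefficient(d, 0.6, floor=0.0) == pytest.approx(
                radial_oracle(d, 0.6), abs=1e-8
            )

    @pytest.mark.parametrize("diameter", [0.8, 1.2])
    def test_closed_form_matches_3d_grid_convolution(self, diameter):
        assert abs(
            recovery_coefficient(diameter, 0.6, floor=0.0)
            - cartesian_grid_oracle(diameter, 0.6)
        ) <= 1e-4

    def test_monotone_in_diameter_and_fwhm(self):
        # strictly increasing until the recovery saturates at 1 in floats
        diam = np.arange(0.4, 2.6, 0.2)
        rc_d = [recovery_coefficient(d, 0.6, floor=0.0) for d in diam]
        assert np.all(np.diff(rc_d) > 0)
        wide = [recovery_coefficient(d, 0.6, floor=0.0) for d in (3.0, 4.0, 5.0)]
        assert np.all(np.diff(wide) >= 0)
        fwhm = np.arange(0.3, 1.6, 0.1)
        rc_f = [recovery_coefficient(1.0, w, floor=0.0) for w in fwhm]
        assert np.all(np.diff(rc_f) < 0)

    def test_apply_pvc_identity_and_published_pair(self):
        assert apply_pvc(500.0, 1.0) == 500.0
        rc = 868.0 / 1133.0  # back-computed from the printed dose pair
        assert apply_pvc(868.0, rc) == pytest.approx(1133.0, rel=1e-12)

    @given(dose=st.floats(0.0, 1e5), rc=st.floats(0.01, 1.0))
    def test_pvc_never_decreases_dose(self, dose, rc):
        assert apply_pvc(dose, rc) >= dose

    @pytest.mark.parametrize("rc", [0.0, -0.1, 1.5])
    def test_invalid_recovery_coefficient_rejected(self, rc):
        with pytest.raises(ValueError):
            apply_pvc(100.0, rc)


class TestLesionDosimetry:
    def test_full_workup_consistency(self):
        fit = KineticFit(2.0, 0.1, 0.006, I131)
        row = lesion_dosimetry(
            fit, lesion_id="L1", mean_size_cm=1.2, target_dose_cgy=2000.0,
            administered_gbq=15.06, mta_gbq=19.72,
        )
        assert row.dose_per_gbq_pvc >= row.dose_per_gbq_nonpvc
        assert row.activity_for_target_gbq * row.dose_per_gbq_pvc == pytest.approx(
            2000.0, rel=1e-9
        )
        assert row.projected_dose_at_mta > row.projected_dose_at_admin

    def test_unknown_size_skips_pvc(self):
        fit = KineticFit(2.0, 0.1, 0.006, I131)
        row = lesion_dosimetry(fit, lesion_id="L1")
        assert row.recovery_coefficient == 1.0
        assert row.dose_per_gbq_pvc == row.dose_per_gbq_nonpvc
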