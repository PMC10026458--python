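"""Relaxivity model: calibration fixture, fitting, prediction, recipe design."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import t2phantom as tp
from t2phantom.errors import DegenerateCalibrationError, InfeasibleTargetError
from t2phantom.recipe import (
    IngredientConcentration,
    RelaxationPair,
    fit_relaxivity_model,
    leave_one_out_errors,
    predict_relaxation,
    design_recipe,
    read_calibration_csv,
    write_calibration_csv,
)


def normal_equations_oracle(ni, ag, t_ms):
    """Independent plane fit via explicitly formed normal equations."""
    X = np.column_stack([np.ones_like(ni), ni, ag])
    y = 1000.0 / np.asarray(t_ms, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestCalibrationFixture:
    def test_embedded_rows(self):
        cal = tp.calibration_fixture()
        assert len(cal) == 10  # 9 tubes + outer fill
        assert list(cal.index[:9]) == list(tp.TUBE_IDS)
        a = cal.loc["A"]
        assert (a["agarose_pct"], a["ni_mM"]) == (1.261, 3.139)
        assert (a["t1_1p4T_ms"], a["t2_1p4T_ms"]) == (821, 40)
        i = cal.loc["I"]
        assert (i["agarose_pct"], i["ni_mM"]) == (2.840, 2.502)
        assert (i["t2_1p5T_ms"], i["t2_3T_ms"]) == (41, 40)

    def test_csv_round_trip(self, tmp_path):
        cal = tp.calibration_fixture()
        path = tmp_path / "cal.csv"
        write_calibration_csv(cal, path)
        back = read_calibration_csv(path)
        pd.testing.assert_frame_equal(back, cal)


class TestFit:
    def test_matches_normal_equations_oracle(self):
        cal = tp.calibration_fixture().drop(index="outer")
        m = fit_relaxivity_model(cal, "1.4T")
        c1 = normal_equations_oracle(cal["ni_mM"], cal["agarose_pct"], cal["t1_1p4T_ms"])
        c2 = normal_equations_oracle(cal["ni_mM"], cal["agarose_pct"], cal["t2_1p4T_ms"])
        got = np.array([m.r1_0, m.r1_ni, m.r1_ag, m.r2_0, m.r2_ni, m.r2_ag])
        want = np.concatenate([c1, c2])
        assert np.allclose(got, want, rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("field", ["1.5T", "3T"])
    def test_clinical_field_relaxivities_positive(self, field):
        m = fit_relaxivity_model(tp.calibration_fixture(), field)
        assert min(m.r1_ni, m.r1_ag, m.r2_ni, m.r2_ag) > 0

    def test_benchtop_dominant_relaxivities_positive(self):
        # at 1.4 T one R1 slope is statistically zero; the dominant pair
        # (the R2 slopes) and the R1 slope on the other ingredient are positive
        m = fit_relaxivity_model(tp.calibration_fixture(), "1.4T")
        assert m.r2_ni > 0 and m.r2_ag > 0 and m.r1_ag > 0

    def test_intercept_only_identical_recipes(self):
        cal = pd.DataFrame(
            {
                "agarose_pct": [0.0, 0.0, 0.0],
                "ni_mM": [0.0, 0.0, 0.0],
                "t1_1p4T_ms": [1000.0] * 3,
                "t2_1p4T_ms": [100.0] * 3,
            },
            index=pd.Index(["a", "b", "c"], name="tube_id"),
        )
        m = fit_relaxivity_model(cal, "1.4T")
        assert m.r1_0 == pytest.approx(1.0)
        assert m.r2_0 == pytest.approx(10.0)
        assert (m.r1_ni, m.r1_ag, m.r2_ni, m.r2_ag) == (0, 0, 0, 0)

    def test_collinear_concentrations_raise(self):
        cal = pd.DataFrame(
            {
                "agarose_pct": [0.5, 1.0, 1.5],
                "ni_mM": [1.0, 2.0, 3.0],  # exactly on a line
                "t1_1p4T_ms": [900.0, 800.0, 700.0],
                "t2_1p4T_ms": [80.0, 60.0, 40.0],
            },
            index=pd.Index(["a", "b", "c"], name="tube_id"),
        )
        with pytest.raises(DegenerateCalibrationError):
            fit_relaxivity_model(cal, "1.4T")

    def test_generate_then_fit_round_trip(self):
        # noiseless synthetic calibration from a chosen coefficient set
        r1_0, r1_ni, r1_ag = 0.35, 0.65, 0.02
        r2_0, r2_ni, r2_ag = 0.4, 0.8, 8.0
        ni, ag = np.meshgrid([0.5, 1.5, 3.0], [0.3, 1.0, 2.5])
        ni, ag = ni.ravel(), ag.ravel()
        cal = pd.DataFrame(
            {
                "agarose_pct": ag,
                "ni_mM": ni,
                "t1_1p4T_ms": 1000.0 / (r1_0 + r1_ni * ni + r1_ag * ag),
                "t2_1p4T_ms": 1000.0 / (r2_0 + r2_ni * ni + r2_ag * ag),
            },
            index=pd.Index([f"t{i}" for i in range(9)], name="tube_id"),
        )
        m = fit_relaxivity_model(cal, "1.4T")
        assert np.allclose(
            [m.r1_0, m.r1_ni, m.r1_ag, m.r2_0, m.r2_ni, m.r2_ag],
            [r1_0, r1_ni, r1_ag, r2_0, r2_ni, r2_ag],
            rtol=1e-12,
        )
        assert m.residual_sd_r1 == pytest.approx(0.0, abs=1e-12)

    def test_row_permutation_invariance(self):
        cal = tp.calibration_fixture()
        m1 = fit_relaxivity_model(cal, "1.5T")
        m2 = fit_relaxivity_model(cal.sample(frac=1, random_state=3), "1.5T")
        assert np.allclose(
            [m1.r1_0, m1.r1_ni, m1.r1_ag, m1.r2_0, m1.r2_ni, m1.r2_ag],
            [m2.r1_0, m2.r1_ni, m2.r1_ag, m2.r2_0, m2.r2_ni, m2.r2_ag],
            rtol=1e-9,
        )

    def test_leave_one_out_reports_every_tube(self):
        loo = leave_one_out_errors(tp.calibration_fixture(), "1.4T")
        assert sorted(loo.index) == sorted(tp.TUBE_IDS)
        assert np.isfinite(loo[["t1_error_ms", "t2_error_ms"]].to_numpy()).all()


class TestPredict:
    def test_zero_concentration_is_intercept(self):
        # 1.5 T model (positive intercept rates)
        m = fit_relaxivity_model(tp.calibration_fixture(), "1.5T")
        p = predict_relaxation(IngredientConcentration(0.0, 0.0), m)
        assert p.t1_ms == pytest.approx(1000.0 / m.r1_0)
        assert p.t2_ms == pytest.approx(1000.0 / m.r2_0)

    def test_tube_a_prediction_within_residual_band(self):
        cal = tp.calibration_fixture()
        m = fit_relaxivity_model(cal, "1.4T")
        p = predict_relaxation(IngredientConcentration(1.261, 3.139), m)
        # within 3 fitted residual SDs of the measured rates
        assert abs(1000.0 / p.t1_ms - 1000.0 / 821.0) <= 3 * max(m.residual_sd_r1, 1e-6)
        assert abs(1000.0 / p.t2_ms - 1000.0 / 40.0) <= 3 * max(m.residual_sd_r2, 1e-6)

    def test_nickel_shortens_t1_at_clinical_field(self):
        m = fit_relaxivity_model(tp.calibration_fixture(), "1.5T")
        for ag in (0.5, 1.0, 2.0):
            t1 = [
                predict_relaxation(IngredientConcentration(ag, ni), m).t1_ms
                for ni in (0.5, 1.0, 2.0, 4.0)
            ]
            assert all(a > b for a, b in zip(t1, t1[1:]))


class TestDesign:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ag=st.floats(0.05, 4.0, allow_nan=False),
        ni=st.floats(0.05, 5.0, allow_nan=False),
    )
    def test_forward_inverse_round_trip(self, ag, ni):
        m = fit_relaxivity_model(tp.calibration_fixture(), "1.4T")
        conc = IngredientConcentration(ag, ni)
        back = design_recipe(predict_relaxation(conc, m), m)
        assert back.agarose_pct == pytest.approx(ag, rel=1e-9, abs=1e-9)
        assert back.ni_mM == pytest.approx(ni, rel=1e-9, abs=1e-9)

    def test_intercept_target_gives_zero_concentrations(self):
        # 1.5 T model: both intercept rates are positive, so the undoped-gel
        # relaxation pair is a feasible target solved by zero concentrations
        m = fit_relaxivity_model(tp.calibration_fixture(), "1.5T")
        target = RelaxationPair(1000.0 / m.r1_0, 1000.0 / m.r2_0)
        conc = design_recipe(target, m)
        assert conc.agarose_pct == pytest.approx(0.0, abs=1e-9)
        assert conc.ni_mM == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_grid(self):
        """Exact solve for (600 ms, 45 ms) agrees with a dense grid search."""
        m = fit_relaxivity_model(tp.calibration_fixture(), "1.4T")
        target = RelaxationPair(600.0, 45.0)
        conc = design_recipe(target, m)

        ni_grid = np.arange(0.0, 6.0 + 1e-9, 1e-3)
        best = (np.inf, None, None)
        for ag in np.arange(0.0, 5.0 + 1e-9, 1e-3):
            e1 = m.r1_0 + m.r1_ni * ni_grid + m.r1_ag * ag - target.r1
            e2 = m.r2_0 + m.r2_ni * ni_grid + m.r2_ag * ag - target.r2
            err = e1**2 + e2**2
            k = int(np.argmin(err))
            if err[k] < best[0]:
                best = (err[k], ni_grid[k], ag)
        # the exact solve zeroes the rate error, so it can only do better
        # than any grid point
        e1 = m.r1_0 + m.r1_ni * conc.ni_mM + m.r1_ag * conc.agarose_pct - target.r1
        e2 = m.r2_0 + m.r2_ni * conc.ni_mM + m.r2_ag * conc.agarose_pct - target.r2
        assert e1**2 + e2**2 <= best[0] + 1e-15
        # the squared-error surface is a strongly anisotropic quadratic, so
        # the discrete argmin can slide a few 1e-3 steps along its shallow
        # valley; the stiff (nickel) axis agrees to one grid step
        assert conc.ni_mM == pytest.approx(best[1], abs=1.5e-3)
        assert conc.agarose_pct == pytest.approx(best[2], abs=6e-3)

    def test_infeasible_target_names_bound(self):
        m = fit_relaxivity_model(tp.calibration_fixture(), "1.4T")
        # longer T2 than the undoped gel requires negative agarose
        with pytest.raises(InfeasibleTargetError, match="< 0"):
            design_recipe(RelaxationPair(4000.0, 3900.0), m)
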