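import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cyclibind.kinetics import DegenerateFitError
from cyclibind.reference import REPORTED_CALIBRATIONS, reference_binding_table
from cyclibind.simulate import BindingSimParams, generate_binding_experiment
from cyclibind.stoichiometry import (
    BindingMeasurement,
    CalibrationCurve,
    audit_binding_table,
    bound_fraction,
    bound_molecules,
    fit_calibration,
    invert_calibration,
    stoichiometry_table,
)

SORBITOL_CURVE = CalibrationCurve(slope=4.00e11, intercept=506_935.0,
                                  r_squared=0.9985, conc_range=(1e-6, 1e-5),
                                  analyte="d-sorbitol")


class TestCalibrationFit:
    def test_exact_line(self):
        concs = np.linspace(1e-6, 1e-5, 6)
        areas = 4.00e11 * concs + 506_935.0
        curve = fit_calibration(concs, areas, "d-sorbitol")
        assert curve.slope == pytest.approx(4.00e11, rel=1e-10)
        assert curve.intercept == pytest.approx(506_935.0, rel=1e-8)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.conc_range == (1e-6, 1e-5)

    def test_constant_areas_rejected(self):
        concs = np.linspace(1e-6, 1e-5, 5)
        with pytest.raises(DegenerateFitError):
            fit_calibration(concs, np.full(5, 1e6))

    def test_too_few_levels(self):
        with pytest.raises(DegenerateFitError):
            fit_calibration([1e-6, 1e-6, 2e-6], [1.0, 1.1, 2.0])

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(12)
        concs = np.linspace(1e-6, 1e-5, 10)
        areas = (4.00e11 * concs + 506_935.0) * (1 + rng.normal(0, 0.02, 10))
        curve = fit_calibration(concs, areas)
        assert abs(curve.slope - 4.00e11) / 4.00e11 < 0.05

    def test_r_squared_invariant_under_affine_area_rescaling(self):
        rng = np.random.default_rng(1)
        concs = np.linspace(1e-6, 1e-5, 8)
        areas = (4.00e11 * concs + 5e5) * (1 + rng.normal(0, 0.02, 8))
        r2 = fit_calibration(concs, areas).r_squared
        r2_scaled = fit_calibration(concs, 3.0 * areas + 1e4).r_squared
        assert r2_scaled == pytest.approx(r2, abs=1e-12)


class TestInversion:
    def test_hand_inverted_area(self):
        # area at 1e-6 M is 906,935; diluted 30x supernatant -> 3e-5 M
        conc = invert_calibration(906_935.0, SORBITOL_CURVE, dilution_factor=30)
        assert conc == pytest.approx(3.0e-5, rel=1e-9)

    def test_area_at_intercept_is_zero(self):
        assert invert_calibration(506_935.0, SORBITOL_CURVE, 30) == 0.0

    def test_below_blank_clips_with_warning(self):
        with pytest.warns(UserWarning, match="below blank"):
            assert invert_calibration(1000.0, SORBITOL_CURVE, 30) == 0.0

    def test_out_of_range_warns_but_returns(self):
        area = float(SORBITOL_CURVE.predict(5e-5))
        with pytest.warns(UserWarning, match="outside the calibration range"):
            conc = invert_calibration(area, SORBITOL_CURVE, 1)
        assert conc == pytest.approx(5e-5, rel=1e-9)

    @given(st.floats(1e-6, 1e-5))
    @settings(derandomize=True, max_examples=50)
    def test_roundtrip_identity(self, c):
        area = float(SORBITOL_CURVE.predict(c))
        assert invert_calibration(area, SORBITOL_CURVE, 1) == pytest.approx(
            c, rel=1e-9)


class TestBoundQuantities:
    @pytest.mark.parametrize("c0,c_free,expected", [
        (1e-4, 5e-5, 50.0), (1e-4, 0.0, 100.0), (1e-4, 1e-4, 0.0),
    ])
    def test_bound_fraction(self, c0, c_free, expected):
        assert bound_fraction(c0, c_free) == pytest.approx(expected)

    def test_bound_fraction_domain(self):
        with pytest.raises(ValueError):
            bound_fraction(0.0, 1e-5)

    @pytest.mark.parametrize("percent,ratio,expected", [
        (20.89, 10, 2.09),   # reported linear-polyol row
        (32.55, 7, 2.28),    # reported cyclic-acid row
        (17.75, 5, 0.89),
        (100.0, 6, 6.00),
    ])
    def test_bound_molecules_reproduces_reported_rows(self, percent, ratio, expected):
        assert round(bound_molecules(percent, ratio), 2) == expected

    def test_bound_molecules_domain(self):
        with pytest.raises(ValueError):
            bound_molecules(101.0, 5)
        with pytest.raises(ValueError):
            bound_molecules(50.0, 0)


class TestStoichiometryTable:
    def test_closed_loop_zero_noise(self):
        params = BindingSimParams(seed=0, curve=SORBITOL_CURVE,
                                  n_bound_rule=lambda r: 0.5 * r,
                                  area_noise_rel=0.0)
        measurements, concs, areas = generate_binding_experiment(params)
        curve = fit_calibration(concs, areas, "d-sorbitol")
        table = stoichiometry_table(measurements, {"d-sorbitol": curve})
        assert np.allclose(table["bound_percent"], 50.0, atol=1e-6)
        assert np.allclose(table["n_bound"], 0.5 * table["molar_ratio"], atol=1e-6)

    def test_saturation_rule_plateaus(self):
        # one protein binds at most ~4 ligands: recovered n_bound plateaus
        params = BindingSimParams(seed=1, curve=SORBITOL_CURVE,
                                  n_bound_rule=lambda r: min(r, 4.0),
                                  ratios=(5.0, 7.0, 10.0),
                                  area_noise_rel=0.02)
        measurements, concs, areas = generate_binding_experiment(params)
        curve = fit_calibration(concs, areas, "d-sorbitol")
        with pytest.warns(UserWarning):  # some diluted areas leave the range
            table = stoichiometry_table(measurements, {"d-sorbitol": curve})
        assert np.allclose(table["n_bound"], 4.0, rtol=0.15)

    def test_empty_measurements(self):
        table = stoichiometry_table([], {})
        assert len(table) == 0
        assert "n_bound" in table.columns

    def test_missing_curve_is_row_level_error(self):
        m = BindingMeasurement(analyte="adonitol", molar_ratio=5.0,
                               peak_area=1e6, c0=5e-5)
        table = stoichiometry_table([m], {})
        assert table.loc[0, "error"] == "no calibration curve for analyte"
        assert np.isnan(table.loc[0, "n_bound"])

    def test_replicates_summarised(self):
        rng = np.random.default_rng(9)
        ms = [BindingMeasurement(analyte="d-sorbitol", molar_ratio=10.0,
                                 peak_area=float(SORBITOL_CURVE.predict(2e-6))
                                 * (1 + rng.normal(0, 0.01)),
                                 c0=1e-4, dilution_factor=30, replicate=i)
              for i in range(3)]
        table = stoichiometry_table(ms, {"d-sorbitol": SORBITOL_CURVE})
        assert len(table) == 1
        assert table.loc[0, "n_replicates"] == 3
        assert table.loc[0, "sd_percent"] > 0


class TestAudit:
    def test_identity_holds_by_construction(self):
        df = pd.DataFrame({
            "analyte": ["x"] * 3, "molar_ratio": [2.0, 5.0, 10.0],
            "bound_percent": [50.0, 20.0, 10.0], "n_bound": [1.0, 1.0, 1.0],
        })
        audit = audit_binding_table(df)
        assert list(audit["status"]) == ["consistent"] * 3
        assert np.allclose(audit["n_bound_recomputed"],
                           audit["molar_ratio"] * audit["bound_percent"] / 100)

    def test_reference_table_flags_exactly_the_transposed_rows(self):
        audit = audit_binding_table(reference_binding_table())
        flagged = audit[audit["status"] != "consistent"]
        assert (audit["status"] == "consistent").sum() == 8
        assert set(zip(flagged["analyte"], flagged["molar_ratio"])) == {
            ("shikimic-acid", 5), ("shikimic-acid", 7)}
        assert set(flagged["status"]) == {"transposed"}

    def test_reference_consistent_rows_match_at_reporting_precision(self):
        audit = audit_binding_table(reference_binding_table())
        ok = audit[audit["status"] == "consistent"]
        assert np.all(np.abs(ok["n_bound_recomputed"] - ok["n_bound"]) <= 0.01)


class TestReportedCalibrations:
    def test_reported_r_squared_within_stated_range(self):
        r2 = [c["r_squared"] for c in REPORTED_CALIBRATIONS.values()]
        assert min(r2) == 0.9960 and max(r2) == 0.9985
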