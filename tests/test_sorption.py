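import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyclibind.chem import DEFAULT_CONSTANTS
from cyclibind.kinetics import InsufficientDataError, PHTimeSeries, detect_breakpoint
from cyclibind.sorption import (
    SorptionSeries,
    WeberMorris,
    compute_sorption_series,
    distribution_constant,
    equilibrium_thermo,
    fit_weber_morris,
    gibbs_free_energy,
    ph_from_sorption,
)
from cyclibind.simulate import generate_ph_series, reconstruction_params

RT_KJ = 8.314 * 295.15 / 1000.0  # at 22 degC


class TestSorptionSeries:
    def test_constant_ph_gives_zero_q(self, solution):
        series = PHTimeSeries(times=[1.0, 5.0, 10.0], pH=[7.14] * 3,
                              solution=solution)
        sorption = compute_sorption_series(series)
        assert np.allclose(sorption.q, 0.0)

    def test_hand_computed_drop(self, solution):
        # pH 7.14 -> 5.60 in 3 mL with 2 mg protein:
        # ([OH]0 - [OH]) * M_OH * V / m = 3.4e-3 mg/g at 2 s.f.
        series = PHTimeSeries(times=[1.0, 5.0, 1440.0], pH=[7.0, 6.0, 5.60],
                              solution=solution)
        sorption = compute_sorption_series(series)
        oh0 = 10 ** (7.14 - 14)
        oh = 10 ** (5.60 - 14)
        expected = (oh0 - oh) * DEFAULT_CONSTANTS.M_OH * 3.0 * 1000.0 / 2.0
        assert sorption.q[-1] == pytest.approx(expected, rel=1e-12)
        assert sorption.q[-1] == pytest.approx(3.4e-3, rel=0.02)

    def test_monotone_ph_gives_monotone_q(self, piecewise_series):
        sorption = compute_sorption_series(piecewise_series)
        assert np.all(np.diff(sorption.q) > 0)

    def test_roundtrip_through_inverse_map(self, piecewise_series):
        sorption = compute_sorption_series(piecewise_series)
        back = ph_from_sorption(sorption)
        assert np.allclose(back, piecewise_series.pH, atol=1e-12, rtol=0)

    def test_sqrt_times(self, piecewise_series):
        sorption = compute_sorption_series(piecewise_series)
        assert np.allclose(sorption.sqrt_times ** 2, sorption.times)


class TestWeberMorris:
    def test_exact_line_in_sqrt_t(self, solution):
        t = np.array([1.0, 4.0, 9.0, 16.0, 25.0])
        q = 0.002 + 5e-5 * np.sqrt(t)
        fit = fit_weber_morris(SorptionSeries(times=t, q=q, solution=solution))
        assert fit.A == pytest.approx(0.002, abs=1e-15)
        assert fit.K_ip == pytest.approx(5e-5, abs=1e-15)
        assert fit.sse == pytest.approx(0.0, abs=1e-25)

    def test_constant_q(self, solution):
        t = np.array([1.0, 4.0, 9.0])
        fit = fit_weber_morris(SorptionSeries(times=t, q=np.full(3, 0.7),
                                              solution=solution))
        assert fit.K_ip == pytest.approx(0.0, abs=1e-15)
        assert fit.A == pytest.approx(0.7)

    def test_too_few_points(self, solution):
        with pytest.raises(InsufficientDataError):
            WeberMorris(SorptionSeries(times=[1.0, 2.0], q=[0.1, 0.2],
                                       solution=solution))

    def test_matches_ols_oracle(self, solution):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(1, 1000, 10))
        q = rng.uniform(0, 0.01, 10)
        fit = fit_weber_morris(SorptionSeries(times=t, q=q, solution=solution))
        st_ = np.sqrt(t)
        slope = np.sum((st_ - st_.mean()) * (q - q.mean())) / np.sum(
            (st_ - st_.mean()) ** 2)
        intercept = q.mean() - slope * st_.mean()
        assert fit.K_ip == pytest.approx(slope, abs=1e-12)
        assert fit.A == pytest.approx(intercept, abs=1e-12)

    def test_noisy_recovery_at_study_scale(self, solution):
        rng = np.random.default_rng(3)
        t = np.array([1.0, 5.0, 10.0, 30.0, 60.0, 120.0, 300.0, 1440.0])
        truth_A, truth_K = 0.00199, 4.77e-5
        q = truth_A + truth_K * np.sqrt(t)
        q = q * (1 + rng.normal(0, 0.05, len(t)))
        fit = fit_weber_morris(SorptionSeries(times=t, q=q, solution=solution))
        assert abs(fit.A - truth_A) / truth_A < 0.25
        assert abs(fit.K_ip - truth_K) / truth_K < 0.25

    def test_segment_diagnostics_for_two_step_series(self, piecewise_series):
        seg = detect_breakpoint(piecewise_series)
        sorption = compute_sorption_series(piecewise_series)
        fit = WeberMorris(sorption, segmentation=seg).fit()
        assert fit.n_segments == 2
        assert len(fit.segments) == 2
        # the rapid step climbs much faster in sqrt(t) than the gradual step
        assert fit.segments[0][1] > fit.segments[1][1]


class TestThermodynamics:
    def test_distribution_constant_basics(self):
        assert distribution_constant(1.0, 1.0) == 1.0
        assert distribution_constant(0.0, 5e-5) == 0.0
        with pytest.raises(ValueError):
            distribution_constant(1.0, 0.0)
        with pytest.raises(ValueError):
            distribution_constant(-1.0, 1.0)

    def test_hand_computed_ratio(self, solution):
        # from the hand-computed sorption example at pH 5.60 equilibrium
        series = PHTimeSeries(times=[1.0, 5.0, 1440.0], pH=[7.0, 6.0, 5.60],
                              solution=solution)
        thermo = equilibrium_thermo(series)
        oh0, oh = 10 ** (7.14 - 14), 10 ** (5.60 - 14)
        q_eq = (oh0 - oh) * DEFAULT_CONSTANTS.M_OH * 3.0 * 1000.0 / 2.0 * 1000.0
        ce = oh * DEFAULT_CONSTANTS.M_OH * 1000.0
        assert thermo.K_D == pytest.approx(q_eq / ce, rel=1e-12)
        assert thermo.K_D == pytest.approx(5.05e4, rel=0.01)

    def test_gibbs_identity_cases(self):
        assert gibbs_free_energy(1.0, 295.15)[0] == pytest.approx(0.0, abs=1e-15)
        dg_kj, dg_kcal = gibbs_free_energy(math.e, 295.15)
        assert dg_kj == pytest.approx(-RT_KJ, rel=1e-12)
        assert dg_kcal == pytest.approx(-RT_KJ / 4.184, rel=1e-12)

    def test_gibbs_inverts_reported_value(self):
        # K_D = exp(21.74 / RT) must map back to -21.74 kJ/mol
        kd = math.exp(21.74 / RT_KJ)
        dg_kj, dg_kcal = gibbs_free_energy(kd, 295.15)
        assert round(dg_kj, 2) == -21.74
        assert round(dg_kcal, 2) == -5.20

    def test_gibbs_domain_errors(self):
        with pytest.raises(ValueError):
            gibbs_free_energy(0.0, 295.15)
        with pytest.raises(ValueError):
            gibbs_free_energy(1.0, -1.0)

    @given(st.floats(1e-6, 1e12), st.floats(1e-6, 1e12))
    @settings(derandomize=True, max_examples=50)
    def test_dg_strictly_decreasing_in_kd(self, kd1, kd2):
        lo, hi = sorted((kd1, kd2))
        if lo == hi:
            return
        assert gibbs_free_energy(hi, 295.15)[0] < gibbs_free_energy(lo, 295.15)[0]

    @given(st.floats(1e-6, 1e12))
    @settings(derandomize=True, max_examples=50)
    def test_dg_sign_matches_kd(self, kd):
        dg = gibbs_free_energy(kd, 295.15)[0]
        if kd > 1:
            assert dg < 0
        elif kd < 1:
            assert dg > 0

    def test_rebound_above_initial_is_clipped(self, solution):
        series = PHTimeSeries(times=[1.0, 5.0, 10.0, 30.0],
                              pH=[7.10, 7.20, 7.30, 7.40], solution=solution)
        with pytest.warns(UserWarning, match="negative equilibrium sorption"):
            thermo = equilibrium_thermo(series)
        assert thermo.q_eq == 0.0
        assert not thermo.defined
        assert math.isnan(thermo.dG_kJ)

    def test_equilibrium_time_override(self, piecewise_series):
        default = equilibrium_thermo(piecewise_series)
        assert default.eq_time == 1440.0
        early = equilibrium_thermo(piecewise_series, eq_time=30.0)
        assert early.eq_time == 30.0
        with pytest.raises(ValueError):
            equilibrium_thermo(piecewise_series, eq_time=33.0)

    def test_end_to_end_dg_band_on_reconstructions(self):
        # paper-scale trajectories must land in the weak-binding band
        for analyte in ("d-sorbitol", "adonitol"):
            series = generate_ph_series(reconstruction_params(analyte, seed=5))
            thermo = equilibrium_thermo(series)
            assert -30.0 < thermo.dG_kJ < -10.0
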