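"""Initial-rate extraction and Michaelis-Menten fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasekin.kinetics import (
    CalibrationLine,
    MichaelisMentenParams,
    ProgressCurve,
    RateMeasurement,
    RateWindow,
    fit_michaelis_menten,
    initial_rate,
    kcat_from_vmax,
    mm_rate,
    signal_to_concentration,
)
from phasekin.synthetic import NoiseModel, gen_progress_curves
from tests.conftest import S_LEVELS


def _curve(times, signal, S0=250.0, units="au", **kw):
    return ProgressCurve(times=np.asarray(times, float),
                         signal=np.asarray(signal, float),
                         substrate_0=S0, enzyme_0=0.5, units=units, **kw)


class TestSignalToConcentration:
    def test_linear_arithmetic(self):
        cal = CalibrationLine(slope=2.0, intercept=100.0)
        c = signal_to_concentration(
            _curve([0, 1, 2, 3, 4], [100, 150, 200, 250, 300]), cal)
        np.testing.assert_allclose(c.signal, [0, 25, 50, 75, 100])
        assert c.units == "uM"

    def test_negative_concentration_flagged_not_dropped(self):
        cal = CalibrationLine(slope=2.0, intercept=100.0)
        c = signal_to_concentration(
            _curve([0, 1, 2, 3, 4], [90, 150, 200, 250, 300]), cal)
        assert c.signal[0] < 0
        assert any("negative" in f for f in c.flags)
        assert len(c.signal) == 5

    def test_condition_mismatch_refused(self):
        cal = CalibrationLine(slope=2.0, intercept=0.0, condition_label="pH6")
        with pytest.raises(ValueError, match="does not match"):
            signal_to_concentration(
                _curve([0, 1, 2, 3, 4], [0, 1, 2, 3, 4],
                       condition_label="pH7.5"), cal)

    def test_round_trip_with_generator(self, mm_homogeneous, cal_line):
        curves = gen_progress_curves(
            mm_homogeneous, [250.0], cal_line, n_reps=1,
            noise=NoiseModel(scale=0.0))
        conc = signal_to_concentration(curves[0], cal_line)
        expected = (curves[0].signal - cal_line.intercept) / cal_line.slope
        np.testing.assert_allclose(conc.signal, expected, rtol=1e-12)


class TestInitialRate:
    def test_exact_line(self):
        t = np.arange(0.0, 50.0, 5.0)
        c = _curve(t, 0.5 * t, units="uM")
        r = initial_rate(c)
        assert r.rate == pytest.approx(0.5, abs=1e-12)
        assert r.rate_se == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_mm_curve_matches_window_midpoint_rate(
            self, mm_homogeneous, cal_line):
        """OLS slope over the low-conversion window equals the analytic
        rate at the window-mean substrate concentration (depletion makes
        it sit below v(S0) by the conversion reached in the window)."""
        curves = gen_progress_curves(
            mm_homogeneous, [250.0], cal_line, n_reps=1,
            noise=NoiseModel(scale=0.0))
        r = initial_rate(signal_to_concentration(curves[0], cal_line))
        assert r.conversion_fraction <= 0.10
        v_mid = mm_rate(mm_homogeneous, r.substrate_effective)
        assert r.rate == pytest.approx(v_mid, rel=5e-3)
        # and sits within the depletion bias of the instantaneous rate
        assert r.rate == pytest.approx(mm_rate(mm_homogeneous, 250.0), rel=0.06)

    def test_noisy_mm_curve_within_3se(self, mm_homogeneous, cal_line):
        curves = gen_progress_curves(
            mm_homogeneous, [250.0], cal_line, n_reps=1,
            noise=NoiseModel(kind="multiplicative_gaussian", scale=0.01,
                             seed=7))
        r = initial_rate(signal_to_concentration(curves[0], cal_line))
        v_mid = mm_rate(mm_homogeneous, r.substrate_effective)
        assert abs(r.rate - v_mid) < 3 * r.rate_se

    def test_too_few_window_points_names_window(self):
        t = np.arange(0.0, 50.0, 5.0)
        c = _curve(t, 10.0 * t, S0=100.0, units="uM")  # converts instantly
        with pytest.raises(ValueError, match="10% conversion window"):
            initial_rate(c)

    def test_window_extension_flagged(self):
        t = np.arange(0.0, 50.0, 5.0)
        c = _curve(t, 10.0 * t, S0=100.0, units="uM")
        r = initial_rate(c, RateWindow(extend_to_min=True))
        assert any("extended" in f for f in r.flags)

    def test_requires_concentration_units(self):
        with pytest.raises(ValueError, match="concentration"):
            initial_rate(_curve([0, 1, 2, 3, 4], [0, 1, 2, 3, 4]))

    def test_decreasing_signal_flagged(self):
        t = np.arange(0.0, 50.0, 5.0)
        rng = np.random.default_rng(0)
        y = -0.5 * t + 0.01 * rng.standard_normal(t.size)
        r = initial_rate(_curve(t, y, units="uM"))
        assert any("non-monotone" in f for f in r.flags)


class TestMMRate:
    def test_half_saturation(self):
        p = MichaelisMentenParams(v_max=2.1, K_M=713.0, enzyme_0=0.5)
        assert mm_rate(p, 713.0) == pytest.approx(1.05)

    def test_zero_substrate(self, mm_homogeneous):
        assert mm_rate(mm_homogeneous, 0.0) == 0.0

    def test_reference_point(self, mm_homogeneous):
        assert mm_rate(mm_homogeneous, 250.0) == pytest.approx(0.545, abs=5e-4)

    @given(s1=st.floats(0.0, 1e4), s2=st.floats(0.0, 1e4))
    @settings(max_examples=200, derandomize=True)
    def test_strictly_increasing_and_bounded(self, s1, s2):
        p = MichaelisMentenParams(v_max=2.1, K_M=713.0, enzyme_0=0.5)
        lo, hi = sorted((s1, s2))
        if lo < hi:
            assert mm_rate(p, lo) < mm_rate(p, hi)
        assert mm_rate(p, hi) < p.v_max

    def test_concave_in_substrate(self, mm_homogeneous):
        S = np.linspace(1.0, 2000.0, 200)
        v = mm_rate(mm_homogeneous, S)
        assert np.all(np.diff(v, 2) < 0)


class TestFitMichaelisMenten:
    def test_noiseless_recovery(self):
        truth = MichaelisMentenParams(v_max=3.8, K_M=388.0, enzyme_0=0.5)
        data = [RateMeasurement(substrate_0=s, rate=mm_rate(truth, s))
                for s in S_LEVELS]
        fit = fit_michaelis_menten(data, 0.5)
        assert fit.v_max == pytest.approx(3.8, rel=1e-3)
        assert fit.K_M == pytest.approx(388.0, rel=1e-3)
        assert fit.k_cat == pytest.approx(7.6, rel=1e-3)

    def test_extrapolation_warning_when_km_beyond_design(self):
        truth = MichaelisMentenParams(v_max=2.1, K_M=713.0, enzyme_0=0.5)
        data = [RateMeasurement(substrate_0=s, rate=mm_rate(truth, s))
                for s in S_LEVELS]
        fit = fit_michaelis_menten(data, 0.5)
        assert any("max(S) < fitted K_M" in w for w in fit.warnings)

    def test_saturated_design_flags_km_boundary(self):
        data = [RateMeasurement(substrate_0=s, rate=3.8)
                for s in (1000.0, 2000.0, 4000.0, 8000.0)]
        fit = fit_michaelis_menten(data, 0.5)
        assert any("boundary" in w for w in fit.warnings)

    def test_too_few_levels(self):
        data = [RateMeasurement(substrate_0=s, rate=1.0) for s in (1.0, 2.0)]
        with pytest.raises(ValueError, match=">= 3 distinct"):
            fit_michaelis_menten(data, 0.5)

    def test_coverage_of_95ci_under_noise(self):
        """5% multiplicative noise, 4 replicates per level: the true
        parameters fall inside the 95% CIs in >= 90% of 200 fits."""
        rng = np.random.default_rng(12345)
        truth = MichaelisMentenParams(v_max=3.8, K_M=388.0, enzyme_0=0.5)
        n_sim, cover_v, cover_k = 200, 0, 0
        for _ in range(n_sim):
            reps = mm_rate(truth, S_LEVELS)[:, None] * (
                1 + 0.05 * rng.standard_normal((S_LEVELS.size, 4)))
            data = [RateMeasurement(
                substrate_0=s, rate=float(m.mean()),
                rate_se=float(m.std(ddof=1) / 2), n_replicates=4)
                for s, m in zip(S_LEVELS, reps)]
            ci = fit_michaelis_menten(data, 0.5).ci95()
            cover_v += ci["v_max"][0] <= 3.8 <= ci["v_max"][1]
            cover_k += ci["K_M"][0] <= 388.0 <= ci["K_M"][1]
        assert cover_v / n_sim >= 0.90
        assert cover_k / n_sim >= 0.90


class TestKcat:
    def test_heterogeneous_column(self):
        assert kcat_from_vmax(3.8, 0.5) == pytest.approx(7.6)

    def test_homogeneous_column_rounding(self):
        # 2.1/0.5 = 4.2; the tabulated 4.3 reflects an unrounded v_max
        assert kcat_from_vmax(2.1, 0.5) == pytest.approx(4.2)
        assert kcat_from_vmax(2.1, 0.5) == pytest.approx(4.3, rel=0.05)

    def test_zero_rate(self):
        assert kcat_from_vmax(0.0, 0.5) == 0.0

    def test_zero_enzyme_rejected(self):
        with pytest.raises(ValueError, match="enzyme_0"):
            kcat_from_vmax(2.1, 0.0)

    def test_params_kcat_consistency(self, mm_homogeneous):
        assert mm_homogeneous.k_cat == pytest.approx(
            mm_homogeneous.v_max / mm_homogeneous.enzyme_0, rel=1e-12)
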