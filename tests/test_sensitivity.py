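"""Saturation and rising-phase sensitivity fits."""

import numpy as np
import pytest
from scipy.optimize import minimize

from retinostat import synth
from retinostat.sensitivity import (FitError, RisingPhaseModel, SaturationModel,
                                    photons_to_isomerizations,
                                    select_rising_window, summarize_cohort)
from retinostat.traces import FlashMeasurement, Trace


def _sat(i, s_b, b_max):
    return b_max * s_b * i / (1 + s_b * i)


class TestSaturation:
    def test_two_point_exact_inversion(self):
        pts = [FlashMeasurement(1.0, _sat(1.0, 1.0, 1.0)),
               FlashMeasurement(1e6, _sat(1e6, 1.0, 1.0))]
        fit = SaturationModel(pts).fit()
        assert fit.exact
        assert fit.s_b == pytest.approx(1.0, rel=1e-9)
        assert fit.b_max == pytest.approx(1.0, rel=1e-9)

    def test_half_saturation_point(self):
        # I = 1/S_B gives exactly half of B_max
        fit = SaturationModel([FlashMeasurement(1.0, 50.0),
                               FlashMeasurement(1e7, 100.0 / (1 + 1e-7))]).fit()
        assert fit.s_b == pytest.approx(1.0, rel=1e-6)
        assert fit.b_max == pytest.approx(100.0, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_point_matches_numeric_least_squares(self, seed):
        r = np.random.default_rng(seed)
        s_b, b_max = np.exp(r.uniform(-3, 3)), np.exp(r.uniform(1, 5))
        i = np.sort(np.exp(r.uniform(-2, 4, 2)))
        i[1] = i[0] * np.exp(r.uniform(0.5, 3))
        b = _sat(i, s_b, b_max)
        fit = SaturationModel(i, b).fit()

        def sse(p):
            return np.sum((_sat(i, np.exp(p[0]), np.exp(p[1])) - b) ** 2)

        num = minimize(sse, x0=np.log([fit.s_b * 1.7, fit.b_max * 0.6]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-13, "fatol": 1e-26, "maxiter": 5000})
        s_num, b_num = np.exp(num.x)
        assert fit.s_b == pytest.approx(s_num, rel=1e-6)
        assert fit.b_max == pytest.approx(b_num, rel=1e-6)

    def test_study_flash_intensities_give_finite_fit(self):
        # dim and saturating scotopic flashes of the protocol
        i = np.array([0.00022, 0.011])
        b = _sat(i, 1000.0, 400.0)
        fit = SaturationModel(i, b).fit()
        assert fit.s_b == pytest.approx(1000.0, rel=1e-9)
        assert fit.b_max == pytest.approx(400.0, rel=1e-9)

    def test_overdetermined_least_squares_recovers(self):
        i = np.array([0.1, 0.3, 1.0, 3.0, 10.0])
        fit = SaturationModel(i, _sat(i, 2.5, 80.0)).fit()
        assert not fit.exact
        assert fit.s_b == pytest.approx(2.5, rel=1e-6)
        assert fit.b_max == pytest.approx(80.0, rel=1e-6)

    def test_inconsistent_amplitudes_raise(self):
        with pytest.raises(FitError):
            SaturationModel([FlashMeasurement(1.0, 50.0),
                             FlashMeasurement(10.0, 40.0)]).fit()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            SaturationModel([FlashMeasurement(1.0, 5.0)])
        with pytest.raises(ValueError):
            SaturationModel([1.0, 1.0], [5.0, 6.0])


class TestRisingWindow:
    def _awave(self, t_peak, dt=0.0002, duration=0.1):
        t = np.arange(0, round(duration / dt)) * dt
        # corneal-negative deflection peaking (in magnitude) at t_peak
        vals = -np.exp(-((t - t_peak) ** 2) / (2 * 0.004**2))
        return Trace(vals, dt, polarity="corneal-positive")

    def test_short_period_window_ends_at_peak(self):
        t_d = 0.004
        tr = self._awave(t_peak=t_d + 0.004)
        t0, t1 = select_rising_window(tr, t_d, "erg_awave")
        assert t0 == pytest.approx(t_d)
        assert t1 == pytest.approx(t_d + 0.004, abs=1e-6)

    def test_long_period_window_ends_5ms_before_peak(self):
        t_d = 0.004
        tr = self._awave(t_peak=t_d + 0.012)
        t0, t1 = select_rising_window(tr, t_d, "erg_awave")
        assert t1 == pytest.approx(t_d + 0.012 - 0.005, abs=1e-6)

    def test_cap_length_alternative_rule(self):
        t_d = 0.004
        tr = self._awave(t_peak=t_d + 0.012)
        _, t1 = select_rising_window(tr, t_d, "erg_awave",
                                     long_period_rule="cap-length")
        assert t1 == pytest.approx(t_d + 0.005, abs=1e-6)

    def test_rod_window_is_60ms(self):
        tr, _ = synth.gen_rising_phase_trace(7.1, 14.1, 0.015, 10.0,
                                             dt=0.001, duration=0.09)
        t0, t1 = select_rising_window(tr, 0.015, "rod_photocurrent")
        assert t1 - t0 == pytest.approx(0.060, abs=1e-9)


class TestRisingPhaseFit:
    def _family(self, s_a, a_max, t_d, intensities, mode, dt, duration):
        polarity = "corneal-positive" if mode == "erg_awave" else "photocurrent"
        return [synth.gen_rising_phase_trace(s_a, a_max, t_d, i, dt=dt,
                                             duration=duration,
                                             polarity=polarity)[0]
                for i in intensities]

    def test_rod_round_trip(self):
        traces = self._family(7.1, 14.1, 0.015, (2.0, 10.0, 50.0),
                              "rod_photocurrent", 0.001, 0.09)
        fit = RisingPhaseModel(traces, "rod_photocurrent").fit()
        assert fit.s_a == pytest.approx(7.1, rel=1e-4)
        assert fit.a_max == pytest.approx(14.1, rel=1e-4)
        assert fit.t_d == pytest.approx(0.015, rel=1e-4)

    def test_erg_round_trip(self):
        traces = self._family(2200.0, 317.0, 0.004, (0.5, 2.0, 10.0),
                              "erg_awave", 0.0002, 0.06)
        fit = RisingPhaseModel(traces, "erg_awave").fit()
        assert fit.s_a == pytest.approx(2200.0, rel=1e-4)
        assert fit.a_max == pytest.approx(317.0, rel=1e-4)

    def test_amplitude_scale_equivariance(self):
        traces = self._family(7.1, 14.1, 0.015, (2.0, 10.0), "rod_photocurrent",
                              0.001, 0.09)
        doubled = [t.with_values(2 * t.values) for t in traces]
        f1 = RisingPhaseModel(traces, "rod_photocurrent").fit()
        f2 = RisingPhaseModel(doubled, "rod_photocurrent").fit()
        assert f2.a_max == pytest.approx(2 * f1.a_max, rel=1e-6)
        assert f2.s_a == pytest.approx(f1.s_a, rel=1e-6)
        assert f2.t_d == pytest.approx(f1.t_d, abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_round_trip_random_grid(self, seed):
        r = np.random.default_rng(seed)
        s_a = np.exp(r.uniform(1.0, 3.0))
        a_max = np.exp(r.uniform(2.0, 4.0))
        t_d = r.uniform(0.0145, 0.0165)
        traces = self._family(s_a, a_max, t_d, (2.0, 8.0, 30.0),
                              "rod_photocurrent", 0.001, 0.09)
        fit = RisingPhaseModel(traces, "rod_photocurrent").fit()
        assert fit.s_a == pytest.approx(s_a, rel=1e-6)
        assert fit.a_max == pytest.approx(a_max, rel=1e-6)
        assert fit.t_d == pytest.approx(t_d, rel=1e-6)


def test_results_plot_smoke():
    import matplotlib
    matplotlib.use("Agg")
    fit = SaturationModel([FlashMeasurement(1.0, 50.0),
                           FlashMeasurement(100.0, 99.0)]).fit()
    ax = fit.plot()
    assert ax.get_legend() is not None
    traces = [synth.gen_rising_phase_trace(7.1, 14.1, 0.015, i,
                                           dt=0.001, duration=0.09)[0]
              for i in (2.0, 10.0)]
    rfit = RisingPhaseModel(traces, "rod_photocurrent").fit()
    assert rfit.plot() is not None


def test_photons_to_isomerizations():
    assert photons_to_isomerizations(20.0) == 10.0
    assert photons_to_isomerizations(0.0) == 0.0
    assert photons_to_isomerizations(7.0, collecting_area=1.0) == 7.0
    with pytest.raises(ValueError):
        photons_to_isomerizations(-1.0)


class TestSummarize:
    def test_two_eyes_average(self):
        rows = [{"mouse": "m1", "genotype": "WT", "pair": 0, "eye": "OD",
                 "unit": "cd.s/m^2", "s_b": 2.0},
                {"mouse": "m1", "genotype": "WT", "pair": 0, "eye": "OS",
                 "unit": "cd.s/m^2", "s_b": 4.0}]
        out = summarize_cohort(rows)
        assert len(out) == 1
        assert out["s_b"].iloc[0] == 3.0
        assert out["n_units"].iloc[0] == 2

    def test_single_eye_flagged(self):
        out = summarize_cohort([{"mouse": "m1", "genotype": "KO", "pair": 1,
                                 "unit": "u", "a_max": 13.0}])
        assert out["n_units"].iloc[0] == 1
        assert out["a_max"].iloc[0] == 13.0

    def test_rod_average(self):
        rows = [{"mouse": "m2", "genotype": "WT", "pair": 0, "unit": "R*/rod",
                 "a_max": v} for v in (10.0, 12.0, 14.0, 16.0)]
        assert summarize_cohort(rows)["a_max"].iloc[0] == 13.0

    def test_mixed_units_rejected(self):
        rows = [{"mouse": "m1", "genotype": "WT", "pair": 0, "unit": "uV", "s_b": 1.0},
                {"mouse": "m1", "genotype": "WT", "pair": 0, "unit": "pA", "s_b": 2.0}]
        with pytest.raises(ValueError, match="mixed units"):
            summarize_cohort(rows)
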