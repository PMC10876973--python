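"""Aperiodic trend forms, peak+trend fitting, detrending and slope fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aperspectra.spectral import (SpectralTrendParams, Spectrum,
                                  detrend, eval_trend, fit_slope,
                                  fit_trend_and_peaks, read_spectrum_tsv,
                                  write_spectrum_tsv, trend_params_from_json,
                                  trend_params_to_json, _gauss)

F = np.linspace(0.5, 100.0, 400)


def two_lor(A1, tau1, A2, tau2):
    return SpectralTrendParams(A1=A1, tau1=tau1, A2=A2, tau2=tau2,
                               trend_form="two_lorentzian")


class TestEvalTrend:
    def test_dc_value_is_sum_of_amplitudes(self):
        s = eval_trend(two_lor(1.0, 0.02, 1.0, 0.002), [0.0])
        assert s.power[0] == pytest.approx(2.0)

    def test_half_power_point_of_single_lorentzian(self):
        tau1 = 0.02
        s = eval_trend(two_lor(3.0, tau1, 0.0, 0.002), [1.0 / (2 * np.pi * tau1)])
        assert s.power[0] == pytest.approx(1.5)

    def test_diff_exp_high_frequency_floor(self):
        p = SpectralTrendParams(A1=5.0, tau1=0.02, tau_r=0.004, lam=0.3,
                                trend_form="diff_exp_plus_const")
        s = eval_trend(p, [5e4])
        assert s.power[0] == pytest.approx(0.3, rel=1e-4)

    def test_matches_independent_symbolic_evaluation(self):
        # frozen from sympy: A1/(1+(2*pi*tau1*f)**2) + A2/(1+(2*pi*tau2*f)**2)
        # with A1=2, tau1=20 ms, A2=0.5, tau2=2 ms, f=10 Hz
        expected = 1.2676803352775522
        s = eval_trend(two_lor(2.0, 0.020, 0.5, 0.002), [10.0])
        assert s.power[0] == pytest.approx(expected, rel=1e-12)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            eval_trend(two_lor(1, 0.02, 1, 0.002), [-1.0])

    def test_invalid_trend_form_rejected(self):
        with pytest.raises(ValueError):
            SpectralTrendParams(A1=1, tau1=0.02, trend_form="powerlaw")

    def test_lorentzian_normalisation_equivalence(self):
        """two_lorentzian with A2=0 equals lorentzian_plus_const with
        lam=0 after the A1 vs A1*tau1 rescaling."""
        tau1 = 0.015
        a = eval_trend(two_lor(2.0, tau1, 0.0, 0.002), F).power
        b = eval_trend(SpectralTrendParams(A1=2.0 / tau1, tau1=tau1, lam=0.0,
                                           trend_form="lorentzian_plus_const"),
                       F).power
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_diff_exp_converges_to_lorentzian_as_rise_vanishes(self):
        tau1, lam = 0.02, 0.1
        p_rise = SpectralTrendParams(A1=150.0, tau1=tau1, tau_r=1e-6,
                                     lam=lam, trend_form="diff_exp_plus_const")
        # A1*(tau_r - tau1)^2 -> A1*tau1^2 = (A1*tau1) * tau1
        lor = SpectralTrendParams(A1=150.0 * tau1, tau1=tau1, lam=lam,
                                  trend_form="lorentzian_plus_const")
        np.testing.assert_allclose(eval_trend(p_rise, F).power,
                                   eval_trend(lor, F).power, rtol=1e-3)


class TestFitTrendAndPeaks:
    def test_parameter_recovery_diff_exp(self):
        p = SpectralTrendParams(A1=200.0, tau1=0.020, tau_r=0.004, lam=0.01,
                                trend_form="diff_exp_plus_const")
        fit = fit_trend_and_peaks(eval_trend(p, F), "diff_exp_plus_const")
        assert fit.converged
        assert fit.trend.tau1 == pytest.approx(0.020, rel=0.02)

    def test_flat_spectrum_is_pure_floor(self):
        fit = fit_trend_and_peaks(Spectrum(F, np.full_like(F, 5.0)),
                                  "lorentzian_plus_const")
        assert fit.trend.lam == pytest.approx(5.0, rel=1e-3)
        assert fit.trend.A1 * fit.trend.tau1 < 5e-3

    def test_single_peak_recovered(self):
        p = SpectralTrendParams(A1=200.0, tau1=0.020, tau_r=0.004, lam=0.01,
                                trend_form="diff_exp_plus_const")
        logp = np.log10(eval_trend(p, F).power) + _gauss(F, 10.0, 0.8, 1.5)
        fit = fit_trend_and_peaks(Spectrum(F, 10 ** logp), "diff_exp_plus_const")
        assert len(fit.peaks) >= 1
        assert fit.peaks[0].center == pytest.approx(10.0, abs=0.5)

    def test_tau1_bounds_honoured(self):
        """Physiological bound for anesthesia fits: 10 ms < tau1 < 75 ms."""
        p = SpectralTrendParams(A1=200.0, tau1=0.005, tau_r=0.004, lam=0.01,
                                trend_form="diff_exp_plus_const")
        fit = fit_trend_and_peaks(eval_trend(p, F), "diff_exp_plus_const",
                                  bounds={"tau1": (0.010, 0.075)})
        assert 0.010 <= fit.trend.tau1 <= 0.075

    def test_idempotent_refit(self):
        p = SpectralTrendParams(A1=50.0, tau1=0.025, tau_r=0.004, lam=0.05,
                                trend_form="diff_exp_plus_const")
        fit1 = fit_trend_and_peaks(eval_trend(p, F), "diff_exp_plus_const")
        fit2 = fit_trend_and_peaks(eval_trend(fit1.trend, F),
                                   "diff_exp_plus_const")
        assert fit2.trend.tau1 == pytest.approx(fit1.trend.tau1, rel=1e-4)
        assert fit2.trend.A1 == pytest.approx(fit1.trend.A1, rel=1e-3)

    def test_rejects_degenerate_spectra(self):
        with pytest.raises(ValueError):
            fit_trend_and_peaks(Spectrum(F, np.zeros_like(F)),
                                "lorentzian_plus_const")
        with pytest.raises(ValueError):
            fit_trend_and_peaks(Spectrum(F[:10], np.ones(10)),
                                "lorentzian_plus_const")


class TestDetrend:
    def setup_method(self):
        p = SpectralTrendParams(A1=100.0, tau1=0.02, tau_r=0.004, lam=0.02,
                                trend_form="diff_exp_plus_const")
        self.trend = eval_trend(p, F)

    def test_self_division_is_zero_db(self):
        out = detrend(self.trend, self.trend, "divide", as_db=True)
        np.testing.assert_allclose(out.power, 0.0, atol=1e-12)

    def test_fit_then_divide_is_flat(self):
        fit = fit_trend_and_peaks(self.trend, "diff_exp_plus_const")
        out = detrend(self.trend, eval_trend(fit.trend, F), "divide")
        assert np.all((out.power > 0.9) & (out.power < 1.1))

    def test_subtract_recovers_additive_peak(self):
        peak = _gauss(F, 10.0, 5.0, 1.5)
        spec = Spectrum(F, self.trend.power + peak)
        out = detrend(spec, self.trend, "subtract")
        np.testing.assert_allclose(out.power, peak, atol=1e-10)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detrend(self.trend, Spectrum(F + 1.0, self.trend.power), "divide")


class TestFitSlope:
    def test_inverse_square_power_law(self):
        fit = fit_slope(Spectrum(F, 1.0 / F ** 2))
        assert fit.beta == pytest.approx(2.0, abs=1e-10)

    def test_flat_spectrum_zero_slope(self):
        fit = fit_slope(Spectrum(F, np.full_like(F, 3.0)))
        assert fit.beta == pytest.approx(0.0, abs=1e-10)

    def test_matches_bruteforce_regression(self):
        spec = eval_trend(two_lor(2.0, 0.02, 0.5, 0.002), F)
        m = (F >= 1.0) & (F <= 40.0)
        slope, alpha = np.polyfit(np.log10(F[m]), np.log10(spec.power[m]), 1)
        fit = fit_slope(spec)
        assert fit.beta == pytest.approx(-slope, rel=1e-12)
        assert fit.alpha == pytest.approx(alpha, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_slope(Spectrum(np.array([1.0, 2, 3, 50]), np.ones(4)))


@settings(max_examples=25, deadline=None)
@given(a_ratio=st.floats(20.0, 200.0))
def test_slope_increases_with_slow_timescale(a_ratio):
    """beta over 1-40 Hz is non-decreasing in tau1 on {10, 20, 40} ms when
    the slow (inhibitory) Lorentzian dominates the band.

    The qualification matters: if A1/A2 is small, the slow knee drops out
    of the fit band as tau1 grows and the in-band slope declines again.
    """
    betas = [fit_slope(eval_trend(two_lor(a_ratio, t, 1.0, 0.002), F)).beta
             for t in (0.010, 0.020, 0.040)]
    assert betas[0] <= betas[1] + 1e-9
    assert betas[1] <= betas[2] + 1e-9


def test_spectrum_tsv_roundtrip(tmp_path):
    spec = eval_trend(two_lor(2.0, 0.02, 0.5, 0.002), F)
    path = tmp_path / "spec.tsv"
    write_spectrum_tsv(spec, path)
    back = read_spectrum_tsv(path)
    np.testing.assert_allclose(back.power, spec.power, rtol=1e-6)


def test_trend_params_json_roundtrip(tmp_path):
    p = SpectralTrendParams(A1=2.0, tau1=0.02, A2=0.5, tau2=0.002,
                            trend_form="two_lorentzian")
    s = trend_params_to_json(p, tmp_path / "p.json")
    assert trend_params_from_json(s) == p
    assert trend_params_from_json(tmp_path / "p.json") == p


def test_hdf5_roundtrip(tmp_path):
    from aperspectra.spectral import read_spectrum_hdf5, write_spectrum_hdf5

    spec = eval_trend(two_lor(2.0, 0.02, 0.5, 0.002), F)
    path = tmp_path / "spec.h5"
    write_spectrum_hdf5(spec, path, metadata={"unit": "uV^2/Hz"})
    back = read_spectrum_hdf5(path)
    np.testing.assert_allclose(back.power, spec.power)
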