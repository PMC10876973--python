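"""Point-dipole neuron: sampling, input generation, membrane/dipole
dynamics, unitary spectra and slope sensitivity."""

import numpy as np
import pytest
from dataclasses import replace

from aperspectra.neuron import (BiophysParams, RateFunction,
                                REFERENCE_PARAMS, SAMPLING_RANGES,
                                SynapseLayout, generate_input, sample_biophys,
                                simulate_dipole, slope_sensitivity,
                                sobol_indices, unitary_spectrum)
from aperspectra.spectral import fit_slope, fit_trend_and_peaks


class TestSampleBiophys:
    def test_all_draws_inside_stated_ranges(self):
        draws = sample_biophys(2000, 0)
        for name, (lo, hi, _) in SAMPLING_RANGES.items():
            vals = np.array([getattr(p, name) for p in draws])
            assert vals.min() >= lo and vals.max() <= hi

    def test_determinism(self):
        assert sample_biophys(50, 7) == sample_biophys(50, 7)

    def test_extremes_approached(self):
        """Order statistics: tauI min/max over many draws approach the
        stated 5-20 ms range edges."""
        draws = sample_biophys(10_000, 1)
        ti = np.array([p.tauI for p in draws])
        assert ti.min() < 5.01e-3 + 15e-3 / 10_000 * 10
        assert ti.max() > 20e-3 - 15e-3 / 10_000 * 10

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BiophysParams(tauE=0.2e-3)  # decay below rise
        with pytest.raises(ValueError):
            BiophysParams(EL=-90.0)  # below inhibitory reversal


class TestLayout:
    def test_unit_norm_and_kind_counts(self):
        lay = SynapseLayout.random(200, rng_seed=0)
        np.testing.assert_allclose(np.linalg.norm(lay.directions, axis=1), 1.0,
                                   atol=1e-9)
        assert lay.is_inh.sum() == 30  # 0.15 ratio

    def test_antithetic_balance(self):
        lay = SynapseLayout.random(200, rng_seed=1)
        np.testing.assert_allclose(lay.directions.sum(0), 0.0, atol=1e-9)


class TestGenerateInput:
    def test_homogeneous_rate(self):
        lay = SynapseLayout.random(400, rng_seed=2)
        p = replace(REFERENCE_PARAMS, lamE=2.0, lamI=2.0)
        ev = generate_input(lay, p, RateFunction(), T=20.0, dt=1e-3, rng_seed=3)
        rate = ev.t_ms.size / 20.0 / lay.n
        se = np.sqrt(2.0 / (20.0 * lay.n))
        assert abs(rate - 2.0) < 3 * se

    def test_sinusoidal_modulation_makes_spectral_line(self):
        lay = SynapseLayout.random(400, rng_seed=4)
        p = replace(REFERENCE_PARAMS, lamE=5.0, lamI=5.0)
        rf = RateFunction(kind="sinusoid", alpha=0.8, omega=2.0)
        ev = generate_input(lay, p, rf, T=60.0, dt=1e-3, rng_seed=5)
        # periodogram of binned apical counts
        apical_ids = np.flatnonzero(lay.apical)
        sel = np.isin(ev.synapse, apical_ids)
        counts, _ = np.histogram(ev.t_ms[sel], bins=np.arange(0, 60001, 10))
        f = np.fft.rfftfreq(counts.size, 0.010)
        P = np.abs(np.fft.rfft(counts - counts.mean())) ** 2
        peak = f[np.argmax(P)]
        assert peak == pytest.approx(2.0, abs=0.05)

    def test_counterphase_apical_basal(self):
        """Sinusoid drive: apical and basal populations are modulated in
        antiphase (k = pi vs k = 0)."""
        lay = SynapseLayout.random(600, rng_seed=6)
        p = replace(REFERENCE_PARAMS, lamE=10.0, lamI=10.0)
        rf = RateFunction(kind="sinusoid", alpha=0.9, omega=1.0)
        ev = generate_input(lay, p, rf, T=40.0, dt=1e-3, rng_seed=7)
        bins = np.arange(0, 40001, 50)
        ap = np.histogram(ev.t_ms[np.isin(ev.synapse, np.flatnonzero(lay.apical))],
                          bins=bins)[0]
        ba = np.histogram(ev.t_ms[np.isin(ev.synapse, np.flatnonzero(~lay.apical))],
                          bins=bins)[0]
        r = np.corrcoef(ap - ap.mean(), ba - ba.mean())[0, 1]
        assert r < -0.5

    def test_coarse_dt_warns(self):
        lay = SynapseLayout.random(20, rng_seed=8)
        p = replace(REFERENCE_PARAMS, lamE=300.0)
        with pytest.warns(UserWarning):
            generate_input(lay, p, RateFunction(), T=0.5, dt=1e-3, rng_seed=9)


class TestSimulateDipole:
    def test_no_input_relaxes_to_leak_reversal(self):
        lay = SynapseLayout.random(50, rng_seed=10)
        p = replace(REFERENCE_PARAMS, lamE=0.0, lamI=0.0)
        ev = generate_input(lay, p, RateFunction(), T=0.5, dt=1e-4, rng_seed=11)
        tr = simulate_dipole(p, lay, ev, 1e-4)
        assert tr.Vm[-1] == pytest.approx(p.EL, abs=1e-9)
        assert np.all(tr.Q == 0.0)

    def test_single_synapse_dipole_points_to_synapse(self):
        """The dipole at the response peak is parallel to the activated
        synapse's direction."""
        lay = SynapseLayout.random(50, rng_seed=12)
        p = REFERENCE_PARAMS
        syn = 7
        trains = [np.array([50.0]) if i == syn else np.array([])
                  for i in range(lay.n)]
        ev = generate_input(lay, p, None, T=0.2, dt=1e-4, rng_seed=0,
                            external_trains=trains)
        tr = simulate_dipole(p, lay, ev, 1e-4)
        i_pk = np.argmax(np.linalg.norm(tr.Q, axis=1))
        q = tr.Q[i_pk] / np.linalg.norm(tr.Q[i_pk])
        assert q @ lay.directions[syn] == pytest.approx(1.0, abs=1e-9)

    def test_inhibition_only_steady_state(self):
        """Strong steady inhibition settles V at the conductance-weighted
        mean of EL and EI."""
        lay = SynapseLayout.random(10, n_i=200, rng_seed=13)
        p = replace(REFERENCE_PARAMS, lamE=0.0, lamI=200.0, tauI=50e-3)
        ev = generate_input(lay, p, RateFunction(), T=2.0, dt=1e-4, rng_seed=14)
        tr = simulate_dipole(p, lay, ev, 1e-4)
        v_late = tr.Vm[-2000:].mean()
        # conductance-weighted steady state from the mean gate level
        from aperspectra.neuron import _gate_filters, _AREA_CM2
        sI_tot, _ = _gate_filters(ev, lay, p.tauI, p.riseI, lay.is_inh,
                                  tr.Vm.size, 0.1)
        GL = p.gL * _AREA_CM2 * 1e6
        gI = p.gI * sI_tot[-2000:].mean()
        v_pred = (GL * p.EL + gI * p.EI) / (GL + gI)
        assert v_late == pytest.approx(v_pred, abs=1.0)
        assert p.EI < v_late < p.EL

    def test_clamped_superposition_is_exactly_linear(self):
        """Disjoint synapse subsets simulated separately sum to the joint
        dipole under voltage clamp."""
        lay = SynapseLayout.random(40, rng_seed=15)
        p = REFERENCE_PARAMS
        rng = np.random.default_rng(16)
        trains = [np.sort(rng.random(3) * 400) for _ in range(lay.n)]
        half = lay.n // 2
        sub_a = [t if i < half else np.array([]) for i, t in enumerate(trains)]
        sub_b = [t if i >= half else np.array([]) for i, t in enumerate(trains)]
        out = {}
        for key, tr_set in (("all", trains), ("a", sub_a), ("b", sub_b)):
            ev = generate_input(lay, p, None, T=0.5, dt=1e-4, rng_seed=0,
                                external_trains=tr_set)
            out[key] = simulate_dipole(p, lay, ev, 1e-4, clamp_voltage=-60.0).Q
        np.testing.assert_allclose(out["a"] + out["b"], out["all"], atol=1e-9)

    def test_conductance_scaling_of_clamped_spectrum(self):
        """Scaling all synaptic conductances by c scales the clamped
        unitary spectrum by c^2."""
        lay = SynapseLayout.random(100, rng_seed=17)
        p1 = REFERENCE_PARAMS
        p2 = replace(p1, gE=2 * p1.gE, gI=2 * p1.gI)
        s1 = unitary_spectrum(p1, layout=lay, T=4.0, n_trials=1, rng_seed=18,
                              clamp_voltage=-60.0)
        s2 = unitary_spectrum(p2, layout=lay, T=4.0, n_trials=1, rng_seed=18,
                              clamp_voltage=-60.0)
        np.testing.assert_allclose(s2.power, 4.0 * s1.power, rtol=1e-8)

    def test_unstable_integration_aborts(self):
        lay = SynapseLayout.random(10, rng_seed=19)
        p = replace(REFERENCE_PARAMS, EE=500.0, gE=2.0, lamE=500.0, gL=0.01)
        ev = generate_input(lay, p, RateFunction(), T=0.5, dt=1e-4, rng_seed=20)
        with pytest.raises(FloatingPointError):
            simulate_dipole(p, lay, ev, 1e-4)


class TestUnitarySpectrum:
    def test_tau1_tracks_inhibitory_decay(self):
        """Fitted slow Lorentzian timescale follows tauI with unit slope."""
        taus = [5e-3, 10e-3, 15e-3, 20e-3]
        fitted = []
        for t_i in taus:
            p = replace(REFERENCE_PARAMS, tauI=t_i)
            spec = unitary_spectrum(p, T=10.0, n_trials=8,
                                    rng_seed=int(t_i * 1e6))
            fit = fit_trend_and_peaks(spec.crop(1, 60), "two_lorentzian",
                                      max_peaks=0)
            fitted.append(fit.trend.tau1)
        slope = np.polyfit(taus, fitted, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_tau2_tracks_excitatory_decay(self):
        """The fast timescale follows tauE (tracked over its 1-3.5 ms
        range; absolute values carry the rise-time bias of the proxy)."""
        taus = [1.5e-3, 2.5e-3, 3.5e-3]
        fitted = []
        for t_e in taus:
            p = replace(REFERENCE_PARAMS, tauE=t_e)
            spec = unitary_spectrum(p, T=10.0, n_trials=8,
                                    rng_seed=int(t_e * 1e6))
            fit = fit_trend_and_peaks(spec.crop(1, 300), "two_lorentzian",
                                      max_peaks=0)
            fitted.append(fit.trend.tau2)
        assert fitted[0] < fitted[1] < fitted[2]

    def test_doubling_gI_raises_low_frequency_trend(self):
        """More inhibitory conductance scales up the slow (inhibition
        dominated) part of the spectrum without new input dynamics."""
        p1 = REFERENCE_PARAMS
        p2 = replace(p1, gI=2 * p1.gI)
        s1 = unitary_spectrum(p1, T=8.0, n_trials=4, rng_seed=21)
        s2 = unitary_spectrum(p2, T=8.0, n_trials=4, rng_seed=21)
        low = s1.freqs < 5.0
        assert np.median(s2.power[low] / s1.power[low]) > 1.5


class TestSensitivity:
    def test_additive_toy_matches_analytic_sobol(self):
        c = np.array([1.0, 2.0, 0.0, 0.5])
        res = sobol_indices(lambda U: U @ c, 4, 20_000, 42,
                            second_order_pairs=[(0, 1)])
        expect = c ** 2 / (c ** 2).sum()
        np.testing.assert_allclose(res["S1"], expect, atol=0.03)
        np.testing.assert_allclose(res["ST"], expect, atol=0.03)
        assert abs(res["S2"][(0, 1)]) < 0.05

    def test_pure_interaction_detected(self):
        g = lambda U: (U[:, 0] - 0.5) * (U[:, 1] - 0.5)
        res = sobol_indices(g, 3, 40_000, 1,
                            second_order_pairs=[(0, 1), (0, 2)])
        assert abs(res["S1"][0]) < 0.05 and abs(res["S1"][1]) < 0.05
        assert res["S2"][(0, 1)] == pytest.approx(1.0, abs=0.05)
        assert abs(res["S2"][(0, 2)]) < 0.05
        assert res["ST"][2] == pytest.approx(0.0, abs=1e-9)

    def test_dummy_parameter_has_zero_index_with_toy_simulator(self):
        def sim(p):
            return np.log10(p.gI) + p.tauI * 100 + np.log10(p.gE)

        df = slope_sensitivity(n_samples=512, rng_seed=3, simulator=sim,
                               include_dummy=True)
        assert df.loc["dummy", "ST"] == pytest.approx(0.0, abs=1e-9)
        assert df.loc["lamE", "ST"] == pytest.approx(0.0, abs=1e-9)

    def test_key_parameters_carry_first_order_weight(self):
        """tauI, gE, gI and EL all move the spectral slope."""
        df = slope_sensitivity(n_samples=48, rng_seed=5, include_dummy=True)
        base = df.loc["dummy", "ST"]
        for name in ("tauI", "gE", "gI", "EL"):
            assert df.loc[name, "ST"] > base + 0.05


def test_ei_leak_interaction_on_spectral_slope():
    """The relation between the spectral exponent and the E:I rate ratio
    depends on the leak stratum: with a strong leak (V clamped near EL)
    more excitation flattens the spectrum (negative correlation), while
    with a weak leak driving-force compensation largely cancels it.  The
    exponent is therefore not a single-valued readout of E:I balance."""
    params = sample_biophys(300, 11)
    betas = np.array([
        fit_slope(unitary_spectrum(p, T=4.0, n_trials=1, rng_seed=1000 + i),
                  (1, 40)).beta
        for i, p in enumerate(params)])
    gl = np.array([p.gL for p in params])
    ei = np.array([np.log(p.lamE / p.lamI) for p in params])
    lo, hi = gl < 0.1, gl > 1.0
    c_lo = np.corrcoef(betas[lo], ei[lo])[0, 1]
    c_hi = np.corrcoef(betas[hi], ei[hi])[0, 1]
    assert c_hi < -0.15          # strong-leak stratum: clear negative relation
    assert abs(c_lo) < abs(c_hi)  # weak-leak stratum: relation attenuated
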