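"""Synthetic propofol-cohort EEG with known ground truth.

Each subject is a single-channel EEG built from independent components
whose statistical structure matches what the analysis chain assumes:

* an aperiodic component: Gaussian noise driven through a time-varying
  difference-of-exponentials filter (inhibitory decay tau1(t), rise
  tau_r = 4 ms), so its spectrum follows the fitted trend form exactly,
  with tau1(t) sliding under a pharmacokinetic Hill drive
  (Marsh effect-site concentration -> fold change of tau1);
* a low-frequency excess: the population rate of a slightly subcritical
  branching network, band-limited below a few Hz (neural-dynamics colour
  the trend fit deliberately excludes);
* alpha (~10 Hz) and beta (~20 Hz) rhythms as 1-Hz-wide filtered noise,
  ramping after infusion onset and plateauing before LOC;
* a delta (~1.5 Hz) rhythm stepping on at LOC;
* a white noise floor (the lambda term of the trend).

Ground truth (tau1 trajectory, Hill parameters, onset times, component
amplitudes) is carried on every record, so end-to-end recovery of the
analysis chain can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import signal as sps

from aperspectra.branching import BranchingParams, build_network, simulate, population_rate
from aperspectra.pipeline import CohortRecord, PKParams, marsh_effect_site

__all__ = ["CohortTruth", "synth_subject", "synth_cohort", "tau1_trajectory"]


@dataclass(frozen=True)
class CohortTruth:
    """Per-subject generator settings (the recoverable ground truth)."""

    latency: float = 135.0        # s, infusion onset -> LOC
    t_infusion: float = 60.0      # s of pre-infusion baseline
    t_post: float = 30.0          # s recorded after LOC
    tau1_base: float = 16.7e-3    # s
    tau_r: float = 4e-3           # s
    hill_ec50: float = 3.7        # uM
    hill_n: float = 1.6
    hill_span: float = 1.6        # saturating fold change is 1 + span
    sigma_aperiodic: float = 15.0  # uV rms at baseline
    sigma_lowfreq: float = 4.0     # uV rms, subcritical low-frequency excess
    sigma_alpha: float = 5.0       # uV rms at plateau
    sigma_beta: float = 2.5
    sigma_delta: float = 20.0   # anesthetic delta dominates the post-LOC EEG
    sigma_floor: float = 2.0       # white-noise floor
    alpha_freq: float = 10.0       # Hz
    beta_freq: float = 20.0
    delta_freq: float = 1.5
    osc_bandwidth: float = 1.0     # Hz
    weight: float = 70.0           # kg
    infusion_rate: float = 1.0     # mg/kg/min
    beta_rise_fall: bool = False   # optional rise-then-fall beta template

    def __post_init__(self):
        if self.latency <= 0 or not 0.010 <= self.tau1_base <= 0.075:
            raise ValueError("latency must be positive and tau1 within "
                             "[10, 75] ms")
        for name in ("sigma_aperiodic", "sigma_lowfreq", "sigma_alpha",
                     "sigma_beta", "sigma_delta", "sigma_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def duration(self):
        return self.t_infusion + self.latency + self.t_post

    @property
    def t_loc(self):
        return self.t_infusion + self.latency


try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _expfilt_tv(x, a):
        y = np.empty_like(x)
        acc = 0.0
        for i in range(x.size):
            acc = a[i] * acc + x[i]
            y[i] = acc
        return y
except ImportError:  # pragma: no cover
    def _expfilt_tv(x, a):
        y = np.empty_like(x)
        acc = 0.0
        for i in range(x.size):
            acc = a[i] * acc + x[i]
            y[i] = acc
        return y


def _diffexp_tv(x, tau1_t, tau_r, fs):
    """White noise through a peak-normalised difference-of-exponentials
    filter with slowly varying decay tau1(t).

    The kernel (exp(-t/tau1) - exp(-t/tau_r)) / peak mimics a synaptic
    response with fixed peak conductance: lengthening tau1 injects more
    charge per event, so low-frequency power grows ~ (tau1 - tau_r)^2 —
    the multiplicative confound the trend fit is designed to remove.  The
    power spectrum follows the difference-of-exponentials Lorentzian form
    exactly.
    """
    a1 = np.exp(-1.0 / (fs * tau1_t))
    ar = np.full(x.size, np.exp(-1.0 / (fs * tau_r)))
    tpk = np.log(tau1_t / tau_r) * tau1_t * tau_r / (tau1_t - tau_r)
    peak = np.exp(-tpk / tau1_t) - np.exp(-tpk / tau_r)
    return (_expfilt_tv(x, a1) - _expfilt_tv(x, ar)) / peak


def _narrowband(n, fs, f0, bw, rng):
    """Unit-variance noise band-passed to f0 +/- bw/2 (4th-order
    Butterworth, zero phase)."""
    lo = max(f0 - bw / 2.0, 0.05)
    sos = sps.butter(4, [lo, f0 + bw / 2.0], btype="bandpass", fs=fs,
                     output="sos")
    y = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return y / y.std()


def _ramp_env(t, t_on, t_plateau):
    """0 before t_on, linear to 1 at t_plateau, 1 after."""
    env = np.clip((t - t_on) / max(t_plateau - t_on, 1e-9), 0.0, 1.0)
    return env


def tau1_trajectory(truth: CohortTruth, t: np.ndarray,
                    pk: PKParams | None = None) -> np.ndarray:
    """Ground-truth tau1(t): baseline times the Hill fold change of the
    Marsh effect-site concentration."""
    rec = CohortRecord("pk", np.zeros(1), t_infusion=truth.t_infusion,
                       t_loc=truth.t_loc, weight=truth.weight,
                       infusion_rate=truth.infusion_rate)
    tt, ce = marsh_effect_site(rec, pk=pk, t_end=float(t[-1]) + 1.0)
    ce_t = np.interp(t, tt, ce)
    fold = 1.0 + truth.hill_span * ce_t ** truth.hill_n / (
        truth.hill_ec50 ** truth.hill_n + ce_t ** truth.hill_n)
    return truth.tau1_base * fold


def synth_subject(truth: CohortTruth, fs: float = 1024.0, rng_seed=0,
                  subject_id: str = "synthetic",
                  branching: BranchingParams | None = None) -> CohortRecord:
    """Generate one synthetic subject record (EEG in uV at ``fs``).

    The aperiodic component feeds white noise through two cascaded
    time-varying one-pole filters (decay tau1(t), rise tau_r); its gain is
    set so the *baseline* rms equals ``sigma_aperiodic`` and is held fixed
    afterwards, so all spectral change comes from the filter timescale —
    the multiplicative confound under study.  Oscillations are
    amplitude-modulated narrowband noise; all components are generated
    independently and summed.
    """
    rng = np.random.default_rng(rng_seed)
    n = int(round(truth.duration * fs))
    t = np.arange(n) / fs

    tau1_t = tau1_trajectory(truth, t)
    x = rng.standard_normal(n)
    ap = _diffexp_tv(x, tau1_t, truth.tau_r, fs)
    base = t < truth.t_infusion
    gain = truth.sigma_aperiodic / ap[base].std() if ap[base].std() > 0 else 0.0
    ap *= gain

    # low-frequency excess from a subcritical branching network
    if truth.sigma_lowfreq > 0:
        if branching is None:
            # coarse bins are fine here: the trace is variance-normalised,
            # so the near-critical rate bias is irrelevant, and the record
            # is minutes long
            branching = BranchingParams(N=200, m=0.98, lam0=1.0, dt=1.0)
        tg, pos = build_network(branching, rng.integers(2 ** 31))
        ras = simulate(tg, branching, truth.duration,
                       rng.integers(2 ** 31), positions=pos)
        _, rate = population_rate(ras, bin_ms=1000.0 / fs)
        rate = rate[:n] if rate.size >= n else np.pad(rate, (0, n - rate.size))
        sos = sps.butter(4, 2.5, btype="lowpass", fs=fs, output="sos")
        lf = sps.sosfiltfilt(sos, rate - rate.mean())
        sd = lf.std()
        lf = truth.sigma_lowfreq * lf / sd if sd > 0 else lf * 0.0
    else:
        lf = np.zeros(n)

    env_alpha = _ramp_env(t, truth.t_infusion,
                          truth.t_infusion + 0.5 * truth.latency)
    if truth.beta_rise_fall:
        up = _ramp_env(t, truth.t_infusion, truth.t_infusion + 0.4 * truth.latency)
        down = 1.0 - 0.6 * _ramp_env(t, truth.t_infusion + 0.6 * truth.latency,
                                     truth.t_loc)
        env_beta = up * down
    else:
        env_beta = _ramp_env(t, truth.t_infusion,
                             truth.t_infusion + 0.5 * truth.latency)
    env_delta = _ramp_env(t, truth.t_loc, truth.t_loc + 2.0)  # step with 2-s ramp

    alpha = truth.sigma_alpha * env_alpha * _narrowband(
        n, fs, truth.alpha_freq, truth.osc_bandwidth, rng)
    beta = truth.sigma_beta * env_beta * _narrowband(
        n, fs, truth.beta_freq, truth.osc_bandwidth, rng)
    delta = truth.sigma_delta * env_delta * _narrowband(
        n, fs, truth.delta_freq, truth.osc_bandwidth, rng)
    floor = truth.sigma_floor * rng.standard_normal(n)

    eeg = ap + lf + alpha + beta + delta + floor
    return CohortRecord(subject_id=subject_id, eeg=eeg, fs=fs,
                        t_infusion=truth.t_infusion, t_loc=truth.t_loc,
                        weight=truth.weight,
                        infusion_rate=truth.infusion_rate,
                        truth={**asdict(truth),
                               "component_variances": {
                                   "aperiodic": float(np.var(ap)),
                                   "lowfreq": float(np.var(lf)),
                                   "alpha": float(np.var(alpha)),
                                   "beta": float(np.var(beta)),
                                   "delta": float(np.var(delta)),
                                   "floor": float(np.var(floor))}})


def synth_cohort(n: int = 14, master_seed=0, fs: float = 1024.0,
                 base_truth: CohortTruth | None = None,
                 latency_range=(95.0, 285.0), jitter: float = 0.10):
    """Generate ``n`` independent subjects with jittered truths.

    Latencies are uniform over ``latency_range``; amplitudes and the
    baseline tau1 get ``jitter`` lognormal subject-level variation (tau1
    clipped to the physiological fit bounds).  Returns (records, truths).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if base_truth is None:
        base_truth = CohortTruth()
    ss = np.random.SeedSequence(master_seed)
    records, truths = [], []
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)

        def jit():
            return float(np.exp(jitter * rng.standard_normal()))

        truth = replace(
            base_truth,
            latency=float(rng.uniform(*latency_range)),
            tau1_base=float(np.clip(base_truth.tau1_base * jit(),
                                    0.010, 0.075)),
            sigma_aperiodic=base_truth.sigma_aperiodic * jit(),
            sigma_lowfreq=base_truth.sigma_lowfreq * jit(),
            sigma_alpha=base_truth.sigma_alpha * jit(),
            sigma_beta=base_truth.sigma_beta * jit(),
            sigma_delta=base_truth.sigma_delta * jit(),
        )
        rec = synth_subject(truth, fs=fs,
                            rng_seed=rng.integers(2 ** 31),
                            subject_id=f"synth{i:02d}")
        records.append(rec)
        truths.append(truth)
    return records, truths
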