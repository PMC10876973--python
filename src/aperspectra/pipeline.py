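"""Anesthesia EEG analysis chain: multitaper spectrograms, line-noise gap
filling, infusion/LOC time rescaling, per-window aperiodic trend tracking,
detrended band power, effect-site pharmacokinetics and Hill dose-response.

The scientific core: propofol lengthens the decay of inhibitory synaptic
currents, which multiplies the aperiodic EEG trend (slow timescale tau1 of
the difference-of-exponentials Lorentzian form ``diff_exp_plus_const``)
rather than reflecting changed neural dynamics.  Fitting tau1 per 2-s
window, dividing spectra by the fitted trend, and renormalising to
baseline isolates band-power changes that genuinely reflect dynamics —
e.g. a delta-band step at loss of consciousness (LOC).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import signal as sps
from scipy import optimize, stats

from aperspectra.spectral import (Spectrum, SpectralTrendParams, eval_trend,
                                  fit_trend_and_peaks)

__all__ = [
    "CohortRecord", "Spectrogram", "PKParams", "DoseResponse", "HillFit",
    "BANDS", "multitaper_spectrogram", "multitaper_kernel",
    "fill_line_noise", "rescale_time",
    "marsh_effect_site", "track_tau1", "fit_hill", "band_power",
    "group_sign_test", "detrended_band_power",
]

BANDS = {"delta": (0.5, 3.0), "alpha": (8.0, 15.0), "beta": (15.0, 30.0)}


@dataclass
class CohortRecord:
    """One subject: single-channel EEG (uV) with infusion and LOC marks."""

    subject_id: str
    eeg: np.ndarray
    fs: float = 1024.0
    t_infusion: float = 60.0   # s
    t_loc: float = 195.0       # s
    weight: float = 70.0       # kg
    infusion_rate: float = 1.0  # mg / kg / min
    truth: dict | None = None

    def __post_init__(self):
        if not self.t_infusion < self.t_loc:
            raise ValueError("require t_infusion < t_loc")

    @property
    def latency(self):
        return self.t_loc - self.t_infusion

    def save_tsv(self, path):
        t = np.arange(self.eeg.size) / self.fs
        np.savetxt(path, np.column_stack([t, self.eeg]), delimiter="\t",
                   header="time_s\teeg_uv", comments="")


@dataclass
class Spectrogram:
    """Multitaper spectrogram: window-centre times (s), freqs (Hz),
    power (uV^2/Hz, shape (n_times, n_freqs))."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray

    def spectrum_at(self, i: int) -> Spectrum:
        return Spectrum(self.freqs, self.power[i])

    def mean_spectrum(self, t_lo: float, t_hi: float) -> Spectrum:
        m = (self.times >= t_lo) & (self.times <= t_hi)
        if not m.any():
            raise ValueError("no windows in requested interval")
        return Spectrum(self.freqs, self.power[m].mean(0))

    def save_hdf5(self, path, group="spectrogram", meta=None):
        import h5py

        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            g = fh.create_group(group)
            g.create_dataset("times", data=self.times)
            g.create_dataset("freqs", data=self.freqs)
            g.create_dataset("power", data=self.power)
            for k, v in (meta or {}).items():
                g.attrs[k] = v

    @classmethod
    def load_hdf5(cls, path, group="spectrogram"):
        import h5py

        with h5py.File(path, "r") as fh:
            g = fh[group]
            return cls(np.asarray(g["times"]), np.asarray(g["freqs"]),
                       np.asarray(g["power"]))


def multitaper_spectrogram(x, fs: float, window: float = 2.0,
                           overlap: float = 1.9, n_tapers: int = 3,
                           nw: float = 2.0, fmax: float | None = None) -> Spectrogram:
    """DPSS multitaper spectrogram (defaults: 3 tapers, 2-s windows,
    1.9-s overlap, time-bandwidth NW=2).

    Power is a one-sided PSD in uV^2/Hz, averaged over tapers; window
    count is floor((n - M) / hop) + 1.
    """
    x = np.asarray(x, dtype=float)
    if fs is None or fs <= 0:
        raise ValueError("sampling rate required")
    M = int(round(window * fs))
    if x.size < M:
        raise ValueError("signal shorter than one window")
    hop = int(round((window - overlap) * fs))
    if hop < 1:
        raise ValueError("overlap must be smaller than the window")
    tapers = sps.windows.dpss(M, nw, Kmax=n_tapers)  # unit-energy rows
    n_win = (x.size - M) // hop + 1
    idx = np.arange(M)[None, :] + hop * np.arange(n_win)[:, None]
    frames = x[idx]
    freqs = np.fft.rfftfreq(M, 1.0 / fs)
    psd = np.zeros((n_win, freqs.size))
    for tap in tapers:
        F = np.fft.rfft(frames * tap, axis=1)
        p = (F.real ** 2 + F.imag ** 2) / fs
        p[:, 1:] *= 2.0
        if M % 2 == 0:
            p[:, -1] /= 2.0
        psd += p
    psd /= n_tapers
    times = (idx[:, 0] + M / 2.0) / fs
    if fmax is not None:
        keep = freqs <= fmax
        freqs, psd = freqs[keep], psd[:, keep]
    return Spectrogram(times=times, freqs=freqs, power=psd)


def multitaper_kernel(window: float = 2.0, fs: float = 1024.0,
                      n_tapers: int = 3, nw: float = 2.0,
                      n_side: int = 8, oversample: int = 16):
    """Spectral window of the multitaper estimator on the rfft grid:
    offsets (Hz) and weights (sum 1) for convolving a model spectrum.

    Fitting a sharply kneed trend to a multitaper spectrum without this
    kernel inflates the fitted timescales, because the +/- NW/window Hz
    smoothing flattens the knee.
    """
    M = int(round(window * fs))
    tapers = sps.windows.dpss(M, nw, Kmax=n_tapers)
    nfft = M * oversample
    W = np.abs(np.fft.fft(tapers, n=nfft, axis=1)) ** 2
    K = W.mean(0)
    df = 1.0 / window
    idx = np.arange(-n_side, n_side + 1)
    w = K[(idx * oversample) % nfft]
    w = w / w.sum()
    return idx * df, w


def fill_line_noise(spectrum: Spectrum, center: float = 60.0,
                    halfwidth: float = 2.0) -> Spectrum:
    """Replace the power-line band (center +/- halfwidth Hz) by linear
    interpolation in log power between the flanking bins."""
    f, p = spectrum.freqs, spectrum.power.copy()
    if not (f[0] <= center <= f[-1]):
        raise ValueError("line-noise frequency outside spectrum range")
    band = (f >= center - halfwidth) & (f <= center + halfwidth)
    if band.any() and not band.all():
        good = ~band
        logp = np.log10(np.maximum(p, 1e-300))
        p[band] = 10.0 ** np.interp(f[band], f[good], logp[good])
    return Spectrum(f, p)


def rescale_time(times, t_infusion: float, t_loc: float) -> np.ndarray:
    """Map time so infusion onset -> -1 and LOC -> 0:
    t -> (t - t_loc) / (t_loc - t_infusion)."""
    if not t_infusion < t_loc:
        raise ValueError("require t_infusion < t_loc")
    return (np.asarray(times, dtype=float) - t_loc) / (t_loc - t_infusion)


@dataclass(frozen=True)
class PKParams:
    """Three-compartment plasma PK with effect-site equilibration.

    Rate constants in 1/min, V1 in L/kg; defaults load from the packaged
    configuration citing the original reference.
    """

    k10: float
    k12: float
    k13: float
    k21: float
    k31: float
    V1: float
    keo: float = 1.21
    molar_mass: float = 178.27

    def __post_init__(self):
        if min(self.k10, self.k12, self.k13, self.k21, self.k31,
               self.V1, self.keo) <= 0:
            raise ValueError("all rate constants must be positive")

    @classmethod
    def from_config(cls, path=None, **overrides):
        if path is None:
            cfg = json.loads(resources.files("aperspectra.data")
                             .joinpath("marsh_pk.json").read_text())
        else:
            with open(path) as fh:
                cfg = json.load(fh)
        kw = {k: cfg[k] for k in ("k10", "k12", "k13", "k21", "k31", "V1", "keo")}
        kw["molar_mass"] = cfg.get("molar_mass_g_per_mol", 178.27)
        kw.update(overrides)
        return cls(**kw)


def marsh_effect_site(record: CohortRecord, pk: PKParams | None = None,
                      dt: float = 0.5, t_end: float | None = None):
    """Effect-site propofol concentration (uM) under the record's infusion.

    Integrates the three-compartment plasma model (RK4) for a constant-rate
    infusion from t_infusion to t_loc, then first-order effect-site
    equilibration dCe/dt = keo (Cp - Ce).  Returns (t_s, Ce_uM).
    """
    if pk is None:
        pk = PKParams.from_config()
    if record.weight <= 0:
        raise ValueError("subject weight must be positive")
    if t_end is None:
        t_end = record.eeg.size / record.fs if record.eeg.size else record.t_loc + 60.0
    n = int(np.ceil(t_end / dt)) + 1
    t = np.arange(n) * dt
    V1_l = pk.V1 * record.weight                      # litres
    rate_mg_min = record.infusion_rate * record.weight  # mg/min

    def deriv(y, infusing):
        c1, c2, c3, ce = y
        inp = rate_mg_min / V1_l if infusing else 0.0  # mg/L/min
        dc1 = inp - (pk.k10 + pk.k12 + pk.k13) * c1 + pk.k21 * c2 + pk.k31 * c3
        dc2 = pk.k12 * c1 - pk.k21 * c2
        dc3 = pk.k13 * c1 - pk.k31 * c3
        dce = pk.keo * (c1 - ce)
        return np.array([dc1, dc2, dc3, dce])

    y = np.zeros(4)
    ce = np.zeros(n)
    h = dt / 60.0  # minutes
    for i in range(1, n):
        infusing = record.t_infusion <= t[i - 1] < record.t_loc
        k1 = deriv(y, infusing)
        k2 = deriv(y + h / 2 * k1, infusing)
        k3 = deriv(y + h / 2 * k2, infusing)
        k4 = deriv(y + h * k3, infusing)
        y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        ce[i] = y[3]
    ce_um = ce * 1000.0 / pk.molar_mass  # mg/L -> uM
    return t, ce_um


@dataclass
class Tau1Track:
    """Per-window slow-timescale series with baseline fold change."""

    times: np.ndarray
    tau1: np.ndarray
    ok: np.ndarray
    baseline: float
    trends: list  # SpectralTrendParams per window

    @property
    def fold_change(self):
        return self.tau1 / self.baseline


def track_tau1(spg: Spectrogram, t_infusion: float, fit_range=(3.0, 55.0),
               tau1_bounds=(0.010, 0.075), tau_r: float = 0.004,
               stride: int = 1, max_peaks: int = 6,
               line_freq: float | None = 60.0, window: float = 2.0,
               fs: float = 1024.0, n_tapers: int = 3,
               nw: float = 2.0, smooth: int = 21,
               min_peak_height: float = 0.2,
               tau1_median_s: float = 15.0) -> Tau1Track:
    """Fit the difference-of-exponentials trend (tau_r fixed, tau1 within
    physiological bounds) to every ``stride``-th spectrogram window over
    ``fit_range`` (frequencies < ~3 Hz excluded: there the trend is
    coloured by slow neural dynamics, not synaptic kinetics).

    Baseline tau1 is the mean over pre-infusion windows; failed window
    fits are flagged and linearly interpolated for display continuity.

    ``smooth`` averages each fitted spectrum over that many neighbouring
    (heavily overlapping) windows: a 2-s single-window multitaper estimate
    has only ~6 dof per bin, and trend fits to it are noise-skewed; +/- 1 s
    of smoothing is negligible against the ~30 s pharmacokinetic drift of
    tau1 but stabilises the per-window fit.  Set 1 to disable.

    ``tau1_median_s`` applies a second pass: the free per-window tau1
    series is smoothed by a running median of that temporal extent (tau1
    drifts on the pharmacokinetic timescale, so this removes
    fit-degeneracy spikes where the knee leaves the fit range), and the
    per-window trend amplitudes are refitted with tau1 fixed at the
    smoothed value.  Set 0 to disable.
    """
    if spg.times.size < 1:
        raise ValueError("empty spectrogram")
    kernel = multitaper_kernel(window=window, fs=fs, n_tapers=n_tapers, nw=nw)
    if smooth > 1:
        from scipy.ndimage import uniform_filter1d
        power = uniform_filter1d(spg.power, size=smooth, axis=0,
                                 mode="nearest")
        spg = Spectrogram(times=spg.times, freqs=spg.freqs, power=power)
    sel = np.arange(0, spg.times.size, stride)
    times = spg.times[sel]
    tau1 = np.full(sel.size, np.nan)
    ok = np.zeros(sel.size, dtype=bool)
    trends = []
    for out_i, i in enumerate(sel):
        spec = spg.spectrum_at(i).crop(fit_range[0], fit_range[1])
        if line_freq is not None and fit_range[0] < line_freq < fit_range[1]:
            spec = fill_line_noise(spec, center=line_freq)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_trend_and_peaks(
                    spec, "diff_exp_plus_const", tau_r=tau_r,
                    bounds={"tau1": tau1_bounds}, max_peaks=max_peaks,
                    min_peak_height=min_peak_height, max_iter=8,
                    kernel=kernel)
            tau1[out_i] = fit.trend.tau1
            ok[out_i] = True
            trends.append(fit.trend)
        except (ValueError, FloatingPointError):
            trends.append(None)
    if (~ok).any() and ok.any():
        tau1[~ok] = np.interp(times[~ok], times[ok], tau1[ok])

    if tau1_median_s and tau1.size >= 3:
        step = float(np.median(np.diff(times))) if times.size > 1 else 1.0
        ksize = max(int(round(tau1_median_s / step)) | 1, 3)
        ksize = min(ksize, tau1.size - (tau1.size + 1) % 2)
        pad = ksize // 2
        padded = np.concatenate([tau1[pad:0:-1], tau1, tau1[-2:-2 - pad:-1]])
        tau1 = np.array([np.median(padded[i:i + ksize])
                         for i in range(tau1.size)])
        trends = [_refit_amplitudes(spg.spectrum_at(i), float(tau1[j]),
                                    tau_r, fit_range, line_freq, kernel)
                  for j, i in enumerate(sel)]

    pre = times < t_infusion
    if not pre.any():
        raise ValueError("no pre-infusion windows for the tau1 baseline")
    # baseline: a single fit to the average of all pre-infusion windows —
    # statistically much tighter than averaging noisy per-window fits
    pre_all = spg.times < t_infusion
    base_spec = Spectrum(spg.freqs, spg.power[pre_all].mean(0)).crop(*fit_range)
    if line_freq is not None and fit_range[0] < line_freq < fit_range[1]:
        base_spec = fill_line_noise(base_spec, center=line_freq)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bfit = fit_trend_and_peaks(base_spec, "diff_exp_plus_const",
                                       tau_r=tau_r, bounds={"tau1": tau1_bounds},
                                       max_peaks=max_peaks,
                                       min_peak_height=min_peak_height,
                                       kernel=kernel)
        baseline = float(bfit.trend.tau1)
    except (ValueError, FloatingPointError):
        baseline = float(np.nanmean(tau1[pre]))
    return Tau1Track(times=times, tau1=tau1, ok=ok, baseline=baseline,
                     trends=trends)


def _refit_amplitudes(spec: Spectrum, tau1: float, tau_r: float, fit_range,
                      line_freq, kernel) -> SpectralTrendParams:
    """Refit A1 and lambda of the difference-of-exponentials trend with
    tau1 held fixed (second pass of the tau1 tracker)."""
    from aperspectra.spectral import _smoothed_trend_power

    s = spec.crop(fit_range[0], fit_range[1])
    if line_freq is not None and fit_range[0] < line_freq < fit_range[1]:
        s = fill_line_noise(s, center=line_freq)
    logp = np.log10(np.maximum(s.power, 1e-300))
    p0 = max(s.power[0], 1e-30)

    def resid(theta):
        tr = SpectralTrendParams(A1=10.0 ** theta[0], tau1=tau1,
                                 trend_form="diff_exp_plus_const",
                                 tau_r=tau_r, lam=10.0 ** theta[1])
        if kernel is None:
            model = eval_trend(tr, s.freqs).power
        else:
            model = _smoothed_trend_power(tr, s.freqs, kernel)
        r = np.log10(np.maximum(model, 1e-300)) - logp
        # one-sided robustness: oscillatory peaks sit above the trend
        return np.where(r > 0, r, 0.3 * r)

    x0 = [np.log10(p0 / (tau1 - tau_r) ** 2), np.log10(max(s.power[-1], p0 * 1e-6))]
    sol = optimize.least_squares(resid, x0, xtol=1e-10, ftol=1e-10, max_nfev=100)
    return SpectralTrendParams(A1=10.0 ** sol.x[0], tau1=tau1,
                               trend_form="diff_exp_plus_const",
                               tau_r=tau_r, lam=10.0 ** sol.x[1])


@dataclass
class HillFit:
    ec50: float
    n: float
    baseline: float
    span: float

    def __call__(self, c):
        c = np.asarray(c, dtype=float)
        return self.baseline + self.span * c ** self.n / (self.ec50 ** self.n + c ** self.n)


@dataclass
class DoseResponse:
    """Fold change of tau1 against effect-site concentration (uM)."""

    concentrations: np.ndarray
    fold_change: np.ndarray
    hill: HillFit | None = None


def fit_hill(dose, response, fix_baseline: float | None = None) -> HillFit:
    """Least-squares Hill fit: r(C) = b + span * C^n / (EC50^n + C^n).

    ``fix_baseline`` pins b (e.g. at 1 for fold-change data); otherwise it
    is free.  Requires >= 4 positive dose points.
    """
    c = np.asarray(dose, dtype=float)
    r = np.asarray(response, dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 dose points")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")

    span0 = max(r.max() - r.min(), 1e-6)
    b0 = r.min() if fix_baseline is None else fix_baseline
    ec0 = float(np.median(c))

    def model(theta):
        if fix_baseline is None:
            ec50, n, b, span = theta
        else:
            ec50, n, span = theta
            b = fix_baseline
        return b + span * c ** n / (ec50 ** n + c ** n)

    if fix_baseline is None:
        x0 = [ec0, 1.5, b0, span0]
        lo = [1e-6, 0.1, -np.inf, 0.0]
        hi = [np.inf, 10.0, np.inf, np.inf]
    else:
        x0 = [ec0, 1.5, span0]
        lo = [1e-6, 0.1, 0.0]
        hi = [np.inf, 10.0, np.inf]
    sol = optimize.least_squares(lambda th: model(th) - r, x0,
                                 bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
    if fix_baseline is None:
        ec50, n, b, span = sol.x
    else:
        ec50, n, span = sol.x
        b = fix_baseline
    return HillFit(ec50=float(ec50), n=float(n), baseline=float(b),
                   span=float(span))


def band_power(spg: Spectrogram, band, baseline_interval=None) -> np.ndarray:
    """Trapezoid-integrated power per window over ``band`` (Hz pair or a
    named band).  With ``baseline_interval`` (t_lo, t_hi in seconds), the
    series is divided by its mean over that interval."""
    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = band
    m = (spg.freqs >= lo) & (spg.freqs <= hi)
    if m.sum() < 2:
        raise ValueError("band contains fewer than 2 frequency bins")
    bp = np.trapezoid(spg.power[:, m], spg.freqs[m], axis=1)
    if baseline_interval is not None:
        t_lo, t_hi = baseline_interval
        sel = (spg.times >= t_lo) & (spg.times <= t_hi)
        if not sel.any():
            raise ValueError("no windows in baseline interval")
        bp = bp / bp[sel].mean()
    return bp


def detrended_band_power(spg: Spectrogram, track: Tau1Track, band,
                         baseline_interval=None) -> np.ndarray:
    """Band power of each window after dividing by that window's fitted
    aperiodic trend (evaluated over the full grid, i.e. extrapolated below
    the fit range), optionally baseline-normalised."""
    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = band
    m = (spg.freqs >= lo) & (spg.freqs <= hi)
    if m.sum() < 2:
        raise ValueError("band contains fewer than 2 frequency bins")
    sel_times = track.times
    idx = np.searchsorted(spg.times, sel_times)
    out = np.full(sel_times.size, np.nan)
    f = spg.freqs[m]
    for j, (i, trend) in enumerate(zip(idx, track.trends)):
        if trend is None:
            continue
        tr = eval_trend(trend, f).power
        out[j] = np.trapezoid(spg.power[i][m] / tr, f)
    bad = np.isnan(out)
    if bad.any() and not bad.all():
        out[bad] = np.interp(sel_times[bad], sel_times[~bad], out[~bad])
    if baseline_interval is not None:
        t_lo, t_hi = baseline_interval
        sel = (sel_times >= t_lo) & (sel_times <= t_hi)
        if not sel.any():
            raise ValueError("no windows in baseline interval")
        out = out / out[sel].mean()
    return out


def group_sign_test(rescaled_times: list, series: list,
                    segment_length: float = 0.05, t_range=(-1.5, 0.5),
                    tail: str = "right", bh_correct: bool = False):
    """Per-segment right-tailed sign test of a positive median change
    across subjects.

    ``rescaled_times``/``series``: per-subject time grids (rescaled units)
    and change series (e.g. baseline-normalised band power minus 1).  For
    each ``segment_length``-long segment, each subject contributes the
    median of its samples in the segment; the p-value is the exact
    binomial tail P(K >= k) with ties excluded.  Returns (segment_centres,
    p_values).  ``bh_correct`` optionally applies Benjamini-Hochberg
    (off by default).
    """
    if len(series) < 5:
        raise ValueError("need at least 5 subjects")
    edges = np.arange(t_range[0], t_range[1] + segment_length, segment_length)
    centres = (edges[:-1] + edges[1:]) / 2.0
    pvals = np.full(centres.size, np.nan)
    for s_i in range(centres.size):
        vals = []
        for t, x in zip(rescaled_times, series):
            m = (t >= edges[s_i]) & (t < edges[s_i + 1])
            if m.any():
                vals.append(np.median(np.asarray(x)[m]))
        vals = np.asarray(vals)
        vals = vals[vals != 0.0]  # exclude ties
        if vals.size == 0:
            continue
        k = int((vals > 0).sum()) if tail == "right" else int((vals < 0).sum())
        pvals[s_i] = float(stats.binom.sf(k - 1, vals.size, 0.5))
    if bh_correct:
        good = ~np.isnan(pvals)
        from statsmodels.stats.multitest import multipletests
        pvals[good] = multipletests(pvals[good], method="fdr_bh")[1]
    return centres, pvals


def load_eeg_tsv(path, **kwargs) -> CohortRecord:
    """Read a two-column (time_s, eeg_uv) TSV into a CohortRecord; sampling
    rate inferred from the time column."""
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    fs = 1.0 / np.median(np.diff(arr[:, 0]))
    kwargs.setdefault("subject_id", str(path))
    return CohortRecord(eeg=arr[:, 1], fs=float(round(fs)), **kwargs)
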