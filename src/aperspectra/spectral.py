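"""Aperiodic spectral trend models, peak+trend fitting and detrending.

The aperiodic ("1/f-like") background of an EEG power spectrum is modelled
here with biophysically interpretable closed forms built from Lorentzians,
the spectral density of exponentially decaying synaptic currents:

* ``two_lorentzian``:      A1/(1+(2*pi*tau1*f)^2) + A2/(1+(2*pi*tau2*f)^2)
* ``lorentzian_plus_const``: A1*tau1/(1+(2*pi*tau1*f)^2) + lam
* ``diff_exp_plus_const``: A1*(tau_r-tau1)^2 /
                           [(1+(2*pi*tau_r*f)^2)(1+(2*pi*tau1*f)^2)] + lam

tau1 and tau2 reflect the decay kinetics of inhibitory (GABAR) and
excitatory (AMPAR) synaptic currents; tau_r is the inhibitory rise time;
lam is an additive high-frequency floor (spike afterpotentials, EMG,
amplifier noise).  Oscillatory peaks are fitted as Gaussians in log-power,
in the style of spectral parameterization ("FOOOF-like") algorithms, so
that band power can be separated from multiplicative trend changes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize

__all__ = [
    "Spectrum",
    "SpectralTrendParams",
    "PeakParams",
    "SlopeFit",
    "TrendFit",
    "eval_trend",
    "fit_trend_and_peaks",
    "detrend",
    "fit_slope",
    "read_spectrum_tsv",
    "write_spectrum_tsv",
    "read_spectrum_hdf5",
    "write_spectrum_hdf5",
]

TREND_FORMS = ("two_lorentzian", "lorentzian_plus_const", "diff_exp_plus_const")


@dataclass(frozen=True)
class Spectrum:
    """A one-sided power spectral density on a strictly increasing grid.

    Attributes
    ----------
    freqs : ndarray, Hz (non-negative, strictly increasing)
    power : ndarray, spectral density (uV^2/Hz for EEG; arbitrary for
        simulated dipoles).  May be negative only for subtractive residuals.
    """

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.ndim != 1 or p.shape != f.shape:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if f.size and (np.any(f < 0) or np.any(np.diff(f) <= 0)):
            raise ValueError("freqs must be non-negative and strictly increasing")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)

    def crop(self, fmin: float, fmax: float) -> "Spectrum":
        m = (self.freqs >= fmin) & (self.freqs <= fmax)
        return Spectrum(self.freqs[m], self.power[m])


@dataclass(frozen=True)
class SpectralTrendParams:
    """Parameters of the aperiodic trend.

    Amplitudes A1 (inhibitory) and A2 (excitatory) carry the units of the
    spectral density they are fitted to; their normalisation differs between
    trend forms (A1 vs A1*tau1 vs A1*(tau_r-tau1)^2) and A1 is treated as a
    free fit amplitude per form.  Timescales are in seconds.
    """

    A1: float
    tau1: float
    trend_form: str
    A2: float = 0.0
    tau2: float = 0.0
    tau_r: float = 0.0
    lam: float = 0.0

    def __post_init__(self):
        if self.trend_form not in TREND_FORMS:
            raise ValueError(f"unknown trend_form {self.trend_form!r}")
        if min(self.A1, self.A2, self.lam) < 0:
            raise ValueError("amplitudes A1, A2, lam must be non-negative")
        if self.tau_r < 0 or self.tau1 <= self.tau_r:
            raise ValueError("require tau1 > tau_r >= 0")
        if self.trend_form == "two_lorentzian" and self.tau2 <= 0:
            raise ValueError("two_lorentzian requires tau2 > 0")


@dataclass(frozen=True)
class PeakParams:
    """Gaussian oscillatory peak: center (Hz), height, width (Gaussian SD, Hz).

    ``height`` is expressed in the fitting space: log10-power for raw
    spectra, dB for detrended spectra.
    """

    center: float
    height: float
    width: float

    def __post_init__(self):
        if self.center <= 0 or self.width <= 0 or self.height < 0:
            raise ValueError("require center > 0, width > 0, height >= 0")


@dataclass(frozen=True)
class SlopeFit:
    """Power-law fit 10^alpha / f^beta of a spectrum over ``f_range``."""

    alpha: float
    beta: float
    f_range: tuple
    residual: float


@dataclass
class TrendFit:
    """Result of a combined trend + peaks fit."""

    trend: SpectralTrendParams
    peaks: list
    converged: bool
    n_iter: int
    rsq_log: float
    residual_sd: float


def _trend_power(params: SpectralTrendParams, f: np.ndarray) -> np.ndarray:
    w1 = (2.0 * np.pi * params.tau1 * f) ** 2
    if params.trend_form == "two_lorentzian":
        w2 = (2.0 * np.pi * params.tau2 * f) ** 2
        p = params.A1 / (1.0 + w1) + params.A2 / (1.0 + w2)
    elif params.trend_form == "lorentzian_plus_const":
        p = params.A1 * params.tau1 / (1.0 + w1) + params.lam
    else:  # diff_exp_plus_const
        wr = (2.0 * np.pi * params.tau_r * f) ** 2
        p = params.A1 * (params.tau_r - params.tau1) ** 2 / ((1.0 + wr) * (1.0 + w1)) + params.lam
    return p


def eval_trend(params: SpectralTrendParams, freqs) -> Spectrum:
    """Evaluate the chosen aperiodic closed form pointwise."""
    f = np.asarray(freqs, dtype=float)
    if np.any(f < 0):
        raise ValueError("negative frequency")
    return Spectrum(f, _trend_power(params, f))


# ---------------------------------------------------------------------------
# trend + peak fitting
# ---------------------------------------------------------------------------

def _trend_param_spec(trend_form, bounds, guess_power, guess_lam):
    """Free parameters per form: names, initial values and (lo, hi) bounds.

    Amplitudes and timescales are fitted in log10 for conditioning.
    ``bounds`` may override per-name (linear units): e.g. ``{"tau1": (0.010,
    0.075)}``.
    """
    b = dict(bounds or {})

    def rng(name, lo, hi):
        lo, hi = b.get(name, (lo, hi))
        return np.log10(lo), np.log10(hi)

    p0 = max(guess_power, 1e-30)
    lam0 = max(guess_lam, p0 * 1e-6)
    if trend_form == "two_lorentzian":
        names = ["A1", "tau1", "A2", "tau2"]
        init = [np.log10(p0), np.log10(0.015), np.log10(p0 / 10), np.log10(0.002)]
        lims = [rng("A1", p0 * 1e-8, p0 * 1e8), rng("tau1", 4e-3, 0.2),
                rng("A2", p0 * 1e-10, p0 * 1e8), rng("tau2", 2e-4, 4e-3)]
    elif trend_form == "lorentzian_plus_const":
        names = ["A1", "tau1", "lam"]
        init = [np.log10(p0 / 0.015), np.log10(0.015), np.log10(lam0)]
        lims = [rng("A1", p0 * 1e-8, p0 * 1e10), rng("tau1", 4e-3, 0.2),
                rng("lam", p0 * 1e-10, p0 * 1e4)]
    elif trend_form == "diff_exp_plus_const":
        names = ["A1", "tau1", "lam"]
        init = [np.log10(p0 / 0.015 ** 2), np.log10(0.020), np.log10(lam0)]
        lims = [rng("A1", p0 * 1e-8, p0 * 1e14), rng("tau1", 5e-3, 0.2),
                rng("lam", p0 * 1e-10, p0 * 1e4)]
    else:
        raise ValueError(f"unknown trend_form {trend_form!r}")
    init = [float(np.clip(v, lo, hi)) for v, (lo, hi) in zip(init, lims)]
    return names, np.array(init), np.array([l for l, _ in lims]), np.array([h for _, h in lims])


def _make_trend(trend_form, names, theta, tau_r):
    vals = {n: 10.0 ** t for n, t in zip(names, theta)}
    kw = dict(A1=vals["A1"], tau1=vals["tau1"], trend_form=trend_form)
    if trend_form == "two_lorentzian":
        kw.update(A2=vals["A2"], tau2=vals["tau2"])
    else:
        kw.update(lam=vals["lam"])
        if trend_form == "diff_exp_plus_const":
            kw.update(tau_r=tau_r)
    return SpectralTrendParams(**kw)


def _smoothed_trend_power(trend, freqs, kernel):
    """Trend evaluated as seen through a spectral-estimator kernel:
    sum_k w_k * trend(|f + off_k|)."""
    offs, w = kernel
    f_ext = np.abs(freqs[:, None] + offs[None, :])
    return _trend_power(trend, f_ext) @ w


def _fit_trend_logls(freqs, logpow, trend_form, bounds, tau_r, theta0=None,
                     kernel=None):
    names, init, lo, hi = _trend_param_spec(
        trend_form, bounds, guess_power=10.0 ** logpow[0], guess_lam=10.0 ** logpow[-1])
    if theta0 is not None:
        init = np.clip(theta0, lo, hi)

    def resid(theta):
        tr = _make_trend(trend_form, names, theta, tau_r)
        if kernel is None:
            model = eval_trend(tr, freqs).power
        else:
            model = _smoothed_trend_power(tr, freqs, kernel)
        return np.log10(np.maximum(model, 1e-300)) - logpow

    # multi-start over the slow timescale: the log-space landscape has
    # local optima where tau2 degenerates into a floor and tau1 absorbs
    # all curvature
    i_tau1 = names.index("tau1")
    starts = [init]
    if theta0 is None:
        for lt in (-2.0, -1.4):
            alt = init.copy()
            alt[i_tau1] = np.clip(lt, lo[i_tau1], hi[i_tau1])
            starts.append(alt)
    best = None
    for x0 in starts:
        sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                     xtol=1e-12, ftol=1e-12, max_nfev=400)
        if best is None or sol.cost < best.cost:
            best = sol
    return _make_trend(trend_form, names, best.x, tau_r), best.x, names


def _gauss(f, center, height, width):
    return height * np.exp(-0.5 * ((f - center) / width) ** 2)


def _fit_peaks(freqs, resid_log, threshold_sd, max_peaks, min_width,
               min_height=0.05, max_width=3.0):
    """Detect and fit Gaussian peaks, largest first, on a log-power residual.

    A candidate must exceed both ``threshold_sd`` residual SDs and an
    absolute ``min_height`` (log10 units) so that numerically perfect fits
    do not sprout spurious peaks.
    """
    res = resid_log.copy()
    peaks = []
    for _ in range(max_peaks):
        sd = np.std(res)
        i = int(np.argmax(res))
        if res[i] <= max(threshold_sd * sd, min_height):
            break
        c0, h0 = freqs[i], res[i]
        # half-height width guess
        above = res >= h0 / 2
        j = i
        while j + 1 < len(res) and above[j + 1]:
            j += 1
        k = i
        while k - 1 >= 0 and above[k - 1]:
            k -= 1
        w0 = float(np.clip((freqs[j] - freqs[k]) / 2.355, min_width, max_width))
        try:
            # width capped so a broad pseudo-peak cannot absorb the trend
            popt, _ = optimize.curve_fit(
                _gauss, freqs, res, p0=[c0, h0, w0],
                bounds=([freqs[0], 0, min_width],
                        [freqs[-1], 2 * h0 + 1, max_width]),
                maxfev=2000)
        except RuntimeError:
            break
        peaks.append(PeakParams(*[float(v) for v in popt]))
        res = res - _gauss(freqs, *popt)
    return peaks, res


def fit_trend_and_peaks(spectrum: Spectrum, trend_form: str = "diff_exp_plus_const",
                        bounds: dict | None = None, max_peaks: int = 6,
                        tau_r: float = 0.004, peak_threshold_sd: float = 2.0,
                        min_peak_width: float = 0.5, min_peak_height: float = 0.05,
                        max_peak_width: float = 3.0, max_iter: int = 50,
                        tol: float = 1e-4, kernel=None) -> TrendFit:
    """Iterative FOOOF-style decomposition into aperiodic trend + Gaussian peaks.

    The fit runs in log10-power space: (1) a robust initial trend fit that
    down-weights putative peak regions, (2) Gaussian peaks fitted
    largest-first on the residual above ``peak_threshold_sd`` residual SDs,
    (3) trend refit on the peak-subtracted spectrum, iterated to
    convergence (relative parameter change < ``tol``).

    Frequencies at exactly 0 Hz are excluded (log undefined).  ``tau_r`` is
    the fixed inhibitory rise time for the ``diff_exp_plus_const`` form.
    Non-convergence within ``max_iter`` is flagged, not raised.

    ``kernel`` = (offsets_hz, weights) describes the spectral window of the
    estimator that produced the spectrum (e.g. the multitaper kernel): the
    trend model is convolved with it before comparison, removing the
    knee-smearing bias that frequency smoothing otherwise induces in the
    fitted timescales.
    """
    m = spectrum.freqs > 0
    freqs, power = spectrum.freqs[m], spectrum.power[m]
    if freqs.size < 20:
        raise ValueError("need at least 20 positive-frequency points")
    if not np.all(np.isfinite(power)) or np.all(power <= 0):
        raise ValueError("spectrum must be finite and not all-zero")
    logpow = np.log10(np.maximum(power, 1e-300))

    def trend_power(tr):
        if kernel is None:
            return eval_trend(tr, freqs).power
        return _smoothed_trend_power(tr, freqs, kernel)

    # (1) robust initial trend: fit, drop high-residual (peak) points, refit
    trend, theta, names = _fit_trend_logls(freqs, logpow, trend_form, bounds,
                                           tau_r, kernel=kernel)
    r = logpow - np.log10(np.maximum(trend_power(trend), 1e-300))
    keep = r < np.std(r)
    if keep.sum() >= 20:
        trend, theta, _ = _fit_trend_logls(freqs[keep], logpow[keep], trend_form,
                                           bounds, tau_r, theta0=theta,
                                           kernel=kernel)

    peaks: list = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        trend_log = np.log10(np.maximum(trend_power(trend), 1e-300))
        peaks, resid = _fit_peaks(freqs, logpow - trend_log, peak_threshold_sd,
                                  max_peaks, min_peak_width, min_peak_height,
                                  max_peak_width)
        peak_log = logpow - trend_log - resid  # summed Gaussian model
        trend_new, theta_new, _ = _fit_trend_logls(freqs, logpow - peak_log, trend_form,
                                                   bounds, tau_r, theta0=theta,
                                                   kernel=kernel)
        change = np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), 1e-12))
        trend, theta = trend_new, theta_new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn("fit_trend_and_peaks did not converge; returning flagged fit")

    model_log = np.log10(np.maximum(trend_power(trend), 1e-300))
    for pk in peaks:
        model_log = model_log + _gauss(freqs, pk.center, pk.height, pk.width)
    resid = logpow - model_log
    ss_tot = np.sum((logpow - logpow.mean()) ** 2)
    rsq = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return TrendFit(trend=trend, peaks=peaks, converged=converged, n_iter=it,
                    rsq_log=float(rsq), residual_sd=float(np.std(resid)))


def detrend(spectrum: Spectrum, trend: Spectrum, mode: str = "divide",
            as_db: bool = False) -> Spectrum:
    """Remove a fitted trend: divisively (multiplicative, postsynaptic
    confounds) or subtractively (additive, independent-source confounds).

    Divide returns the elementwise ratio, optionally as 10*log10 (dB).
    Subtract returns the difference clipped at 0 in linear power.
    """
    if spectrum.freqs.shape != trend.freqs.shape or not np.allclose(
            spectrum.freqs, trend.freqs):
        raise ValueError("frequency grids mismatch")
    if mode == "divide":
        if np.any(trend.power <= 0):
            raise ValueError("trend must be strictly positive for division")
        out = spectrum.power / trend.power
        if as_db:
            out = 10.0 * np.log10(np.maximum(out, 1e-300))
    elif mode == "subtract":
        out = np.maximum(spectrum.power - trend.power, 0.0)
        if as_db:
            raise ValueError("dB output is only defined for divisive detrending")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Spectrum(spectrum.freqs, out)


def fit_slope(spectrum: Spectrum, f_range=(1.0, 40.0)) -> SlopeFit:
    """Fit the power law 10^alpha / f^beta over ``f_range`` by least squares
    of log10(power) on log10(f); beta is minus the regression slope."""
    if f_range[0] <= 0:
        raise ValueError("f_range must start above 0 Hz")
    s = spectrum.crop(*f_range)
    if s.freqs.size < 5:
        raise ValueError("fewer than 5 points in f_range")
    if np.any(s.power <= 0):
        raise ValueError("spectrum must be strictly positive over f_range")
    x, y = np.log10(s.freqs), np.log10(s.power)
    slope, alpha = np.polyfit(x, y, 1)
    resid = float(np.sqrt(np.mean((y - (alpha + slope * x)) ** 2)))
    return SlopeFit(alpha=float(alpha), beta=float(-slope),
                    f_range=tuple(f_range), residual=resid)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_spectrum_tsv(spectrum: Spectrum, path):
    np.savetxt(path, np.column_stack([spectrum.freqs, spectrum.power]),
               delimiter="\t", header="freq_hz\tpower", comments="")


def read_spectrum_tsv(path) -> Spectrum:
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    return Spectrum(arr[:, 0], arr[:, 1])


def write_spectrum_hdf5(spectrum: Spectrum, path, group: str = "spectrum",
                        metadata: dict | None = None):
    import h5py

    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("freqs", data=spectrum.freqs)
        g.create_dataset("power", data=spectrum.power)
        for k, v in (metadata or {}).items():
            g.attrs[k] = v


def read_spectrum_hdf5(path, group: str = "spectrum") -> Spectrum:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh[group]
        return Spectrum(np.asarray(g["freqs"]), np.asarray(g["power"]))


def trend_params_to_json(params: SpectralTrendParams, path=None) -> str:
    s = json.dumps(asdict(params), indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def trend_params_from_json(src) -> SpectralTrendParams:
    if hasattr(src, "read"):
        d = json.load(src)
    else:
        try:
            d = json.loads(src)
        except (json.JSONDecodeError, TypeError):
            with open(src) as fh:
                d = json.load(fh)
    return SpectralTrendParams(**d)
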