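"""Point-dipole proxy neuron: conductance-based membrane, synaptic drive,
dipole readout and unitary EEG spectra.

The morphologically detailed neuron is reduced to a single compartment with
direction-tagged synapses: each synapse carries a unit vector (soma at the
origin) and its synaptic current contributes to the dipole moment along
that vector, exploiting the near-linear relation between synapse location
and evoked dipole orientation.  Membrane dynamics follow

    Cm dV/dt = -gL (V - EL) - sum_E gE sE(t) (V - EE) - sum_I gI sI(t) (V - EI)

with difference-of-exponentials conductance gates per synapse.  The dipole

    Q(t) = sum_syn g_x s_syn(t) (E_x - V) d_syn

is read out through a sampled scalar lead-field gain and projection
direction, giving location/trial-averaged *unitary spectra*: the expected
EEG power spectrum contributed by one average neuron.

Absolute EEG amplitudes are calibrated (configurable dipole-to-scalp
gain), not predicted; shapes and parameter dependencies are the object of
study.  Membrane area is fixed at 1e-4 cm^2 so that gL in mS/cm^2 maps to
a membrane time constant Cm/gL of 1 ms at gL = 1 (Cm = 1 uF/cm^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from aperspectra.spectral import Spectrum, fit_slope

__all__ = [
    "BiophysParams", "SynapseLayout", "RateFunction", "DipoleTrace",
    "SpikeEvents", "REFERENCE_PARAMS", "SAMPLING_RANGES", "sample_biophys",
    "generate_input", "generate_mixed_input", "simulate_dipole",
    "unitary_spectrum",
    "slope_sensitivity", "sobol_indices",
]

_AREA_CM2 = 1e-4  # membrane area; gL [mS/cm^2] -> 100*gL nS, Cm -> 100 pF


@dataclass(frozen=True)
class BiophysParams:
    """Single-neuron synaptic and membrane parameters.

    Rates in Hz per synapse; decay/rise times in seconds; conductances in
    nS; potentials in mV; gL in mS/cm^2; Cm in uF/cm^2.
    """

    lamE: float = 1.0
    lamI: float = 5.0
    tauE: float = 1.8e-3
    tauI: float = 10e-3
    gE: float = 0.7
    gI: float = 0.7
    EL: float = -58.0
    gL: float = 1.0
    EE: float = 0.0
    EI: float = -80.0
    riseE: float = 0.3e-3
    riseI: float = 2e-3
    Cm: float = 1.0

    def __post_init__(self):
        if min(self.lamE, self.lamI, self.gE, self.gI, self.gL) < 0:
            raise ValueError("rates and conductances must be non-negative")
        if self.tauE <= self.riseE or self.tauI <= self.riseI:
            raise ValueError("decay must exceed rise time for each receptor")
        if not (self.EI < self.EL < self.EE):
            raise ValueError("require EI < EL < EE")


REFERENCE_PARAMS = BiophysParams()

# sampling ranges: (lo, hi, "uniform" | "loguniform")
SAMPLING_RANGES = {
    "lamE": (0.1, 5.0, "loguniform"),
    "lamI": (0.5, 25.0, "loguniform"),
    "tauE": (1e-3, 3.5e-3, "uniform"),
    "tauI": (5e-3, 20e-3, "uniform"),
    "gE": (0.2, 2.0, "loguniform"),
    "gI": (0.2, 2.0, "loguniform"),
    "EL": (-75.0, -45.0, "uniform"),
    "gL": (0.01, 5.0, "loguniform"),
}


def _from_unit(name, u):
    lo, hi, kind = SAMPLING_RANGES[name]
    if kind == "loguniform":
        return lo * (hi / lo) ** u
    return lo + (hi - lo) * u


def sample_biophys(n: int, rng_seed) -> list:
    """Draw ``n`` independent parameter sets from the sampling distributions
    (log-uniform conductances and rates, uniform timescales and EL)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    u = rng.random((n, len(SAMPLING_RANGES)))
    names = list(SAMPLING_RANGES)
    return [BiophysParams(**{nm: _from_unit(nm, u[i, j])
                             for j, nm in enumerate(names)})
            for i in range(n)]


@dataclass(frozen=True)
class SynapseLayout:
    """Direction-tagged synapses on the unit sphere (soma at origin).

    ``directions``: (n, 3) unit vectors; ``is_inh``: boolean per synapse.
    The apical-like hemisphere is direction z > 0.
    """

    directions: np.ndarray
    is_inh: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        ii = np.asarray(self.is_inh, dtype=bool)
        if d.ndim != 2 or d.shape[1] != 3 or ii.shape != (d.shape[0],):
            raise ValueError("directions must be (n, 3) with matching is_inh")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("directions must be unit vectors")
        if ii.sum() < 1 or (~ii).sum() < 1:
            raise ValueError("need at least one synapse of each kind")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "is_inh", ii)

    @property
    def n(self):
        return self.directions.shape[0]

    @property
    def apical(self):
        return self.directions[:, 2] > 0

    @property
    def apical_axis(self):
        a = self.directions.mean(0)
        nrm = np.linalg.norm(a)
        return a / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])

    @classmethod
    def random(cls, n_e: int = 500, n_i: int | None = None, rng_seed=0,
               antithetic: bool = True):
        """Uniformly random directions; default inhibitory:excitatory 0.15.

        With ``antithetic`` (default) directions come in +/- pairs per
        kind, so the layout is balanced (sum of directions exactly zero):
        network-wide rate fluctuations then cancel out of the dipole
        instead of leaking through the O(sqrt(n)) residual of an
        unbalanced sample, mimicking a dendritic arbor that surrounds its
        soma."""
        if n_i is None:
            n_i = max(int(round(0.15 * n_e)), 1)
        rng = np.random.default_rng(rng_seed)

        def draw(n):
            if antithetic:
                h = rng.standard_normal(((n + 1) // 2, 3))
                h /= np.linalg.norm(h, axis=1, keepdims=True)
                return np.vstack([h, -h])[:n]
            v = rng.standard_normal((n, 3))
            return v / np.linalg.norm(v, axis=1, keepdims=True)

        return cls(np.vstack([draw(n_e), draw(n_i)]),
                   np.arange(n_e + n_i) >= n_e)


@dataclass(frozen=True)
class RateFunction:
    """Synaptic rate modulation: rate(t) = max(lam_x (1 + alpha*Ytilde(t)), 0).

    ``Ytilde`` is the zero-mean unit-variance series ``Y`` on apical
    synapses and ``1 - Y`` on basal synapses (counterphase drive).  The
    sinusoid kind follows the phase convention k = pi (apical) / k = 0
    (basal), i.e. Ytilde = -/+ sin(2 pi omega t).

    kind: "constant" | "sinusoid" | "white" | "damped_oscillator" | "external"
    """

    kind: str = "constant"
    alpha: float = 0.0
    omega: float = 10.0        # Hz, sinusoid / oscillator natural frequency
    damping: float = 0.3       # damped_oscillator damping ratio
    series: np.ndarray | None = None  # external Y(t), sampled at dt

    def make_y(self, n_bins: int, dt: float, rng) -> np.ndarray:
        """Standardised modulation series Y(t) on the simulation grid."""
        t = np.arange(n_bins) * dt
        if self.kind == "constant" or self.alpha == 0.0:
            return np.zeros(n_bins)
        if self.kind == "sinusoid":
            return np.sin(2.0 * np.pi * self.omega * t)
        if self.kind == "white":
            y = rng.standard_normal(n_bins)
        elif self.kind == "damped_oscillator":
            w0 = 2.0 * np.pi * self.omega
            # x'' + 2 z w0 x' + w0^2 x = white noise, discretised
            b, a = signal.cont2discrete(([w0 ** 2], [1.0, 2.0 * self.damping * w0, w0 ** 2]),
                                        dt)[:2]
            y = signal.lfilter(np.atleast_1d(b.squeeze()), a, rng.standard_normal(n_bins))
        elif self.kind == "external":
            if self.series is None:
                raise ValueError("external rate function requires a series")
            src = np.asarray(self.series, dtype=float)
            y = np.interp(np.linspace(0, 1, n_bins), np.linspace(0, 1, src.size), src)
        else:
            raise ValueError(f"unknown rate function kind {self.kind!r}")
        sd = y.std()
        return (y - y.mean()) / sd if sd > 0 else y * 0.0


@dataclass
class SpikeEvents:
    """Synaptic input events: parallel arrays of synapse index and time (ms)."""

    synapse: np.ndarray
    t_ms: np.ndarray
    T: float   # s
    dt: float  # s, generation bin

    def save_tsv(self, path):
        np.savetxt(path, np.column_stack([self.synapse, self.t_ms]),
                   delimiter="\t", header="synapse_id\tspike_time_ms",
                   comments="", fmt=("%d", "%.6f"))


@dataclass
class DipoleTrace:
    """Dipole moment time series (arbitrary units ~ current x distance)."""

    t_ms: np.ndarray
    Q: np.ndarray    # (n, 3)
    Vm: np.ndarray   # mV

    def save_hdf5(self, path, group: str = "dipole"):
        import h5py

        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            g = fh.create_group(group)
            g.create_dataset("t", data=self.t_ms)
            g.create_dataset("Q", data=self.Q)
            g.create_dataset("Vm", data=self.Vm)

    @classmethod
    def load_hdf5(cls, path, group: str = "dipole"):
        import h5py

        with h5py.File(path, "r") as fh:
            g = fh[group]
            return cls(t_ms=np.asarray(g["t"]), Q=np.asarray(g["Q"]),
                       Vm=np.asarray(g["Vm"]))


def generate_input(layout: SynapseLayout, params: BiophysParams,
                   rates: RateFunction, T: float, dt: float, rng_seed,
                   external_trains: list | None = None) -> SpikeEvents:
    """Per-synapse inhomogeneous Poisson trains with counterphase
    apical/basal modulation, or externally supplied trains.

    ``external_trains``: optional list (len = layout.n) of spike-time arrays
    in ms, overriding Poisson generation (e.g. branching-network units
    mapped onto synapses).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if external_trains is not None:
        syn = np.concatenate([np.full(len(tr), i, dtype=np.int64)
                              for i, tr in enumerate(external_trains)])
        t = np.concatenate([np.asarray(tr, dtype=float) for tr in external_trains])
        order = np.argsort(t, kind="stable")
        return SpikeEvents(syn[order], t[order], T, dt)

    rng = np.random.default_rng(rng_seed)
    n_bins = int(round(T / dt))
    y = rates.make_y(n_bins, dt, rng)
    max_rate = max(params.lamE, params.lamI) * (1.0 + abs(rates.alpha) * max(1.0, np.max(np.abs(y)) if y.size else 0.0))
    if max_rate * dt > 0.1:
        warnings.warn("rate*dt exceeds 0.1; consider a finer dt")

    syn_all, t_all = [], []
    apical = layout.apical
    for is_inh, lam in ((False, params.lamE), (True, params.lamI)):
        for is_ap in (True, False):
            grp = np.flatnonzero((layout.is_inh == is_inh) & (apical == is_ap))
            if grp.size == 0:
                continue
            if rates.kind == "sinusoid":
                ytil = -y if is_ap else y    # k = pi apical, k = 0 basal
            else:
                ytil = y if is_ap else 1.0 - y
            rate = np.maximum(lam * (1.0 + rates.alpha * ytil), 0.0)
            counts = rng.poisson(rate * dt * grp.size)
            tot = int(counts.sum())
            if tot == 0:
                continue
            bins = np.repeat(np.arange(n_bins), counts)
            times = (bins + rng.random(tot)) * dt * 1000.0
            syn_all.append(rng.choice(grp, size=tot))
            t_all.append(times)
    if syn_all:
        syn = np.concatenate(syn_all)
        t = np.concatenate(t_all)
        order = np.argsort(t, kind="stable")
        syn, t = syn[order], t[order]
    else:
        syn, t = np.empty(0, dtype=np.int64), np.empty(0)
    return SpikeEvents(syn, t, T, dt)


def generate_mixed_input(layout: SynapseLayout, params: BiophysParams,
                         assignments, T: float, dt: float,
                         rng_seed) -> SpikeEvents:
    """Mixed synaptic input: different synapse groups receive different
    rate functions (e.g. half oscillatory, half aperiodic network drive).

    ``assignments``: list of (synapse_index_array, RateFunction).  Groups
    must be disjoint; unlisted synapses stay silent.
    """
    ss = np.random.SeedSequence(rng_seed)
    syn_all, t_all = [], []
    for (idx, rf), child in zip(assignments, ss.spawn(len(assignments))):
        ev = generate_input(layout, params, rf, T, dt,
                            child.generate_state(1)[0] % (2 ** 31))
        keep = np.isin(ev.synapse, idx)
        syn_all.append(ev.synapse[keep])
        t_all.append(ev.t_ms[keep])
    syn = np.concatenate(syn_all)
    t = np.concatenate(t_all)
    order = np.argsort(t, kind="stable")
    return SpikeEvents(syn[order], t[order], T, dt)


# ---------------------------------------------------------------------------
# membrane integration
# ---------------------------------------------------------------------------

try:
    from numba import njit

    @njit(cache=True)
    def _integrate_v(decay, vinf, v0):
        n = decay.size
        v = np.empty(n + 1)
        v[0] = v0
        for i in range(n):
            v[i + 1] = vinf[i] + (v[i] - vinf[i]) * decay[i]
        return v
except ImportError:  # pragma: no cover
    def _integrate_v(decay, vinf, v0):
        n = decay.size
        v = np.empty(n + 1)
        v[0] = v0
        for i in range(n):
            v[i + 1] = vinf[i] + (v[i] - vinf[i]) * decay[i]
        return v


def _gate_filters(events: SpikeEvents, layout: SynapseLayout, tau_d, tau_r,
                  sel, n_steps, dt_ms):
    """Scalar and direction-weighted difference-of-exponentials gate sums.

    Gates are normalised to unit peak.  Returns (s_tot, s_vec) with shapes
    (n_steps,) and (n_steps, 3).
    """
    tpk = np.log(tau_d / tau_r) * tau_d * tau_r / (tau_d - tau_r)
    norm = 1.0 / (np.exp(-tpk / tau_d) - np.exp(-tpk / tau_r))
    idx = sel[events.synapse]
    bins = np.minimum((events.t_ms[idx] / dt_ms).astype(np.int64), n_steps - 1)
    syn = events.synapse[idx]
    imp = np.zeros(n_steps)
    np.add.at(imp, bins, 1.0)
    impv = np.zeros((n_steps, 3))
    np.add.at(impv, bins, layout.directions[syn])
    out = []
    for x in (imp, impv[:, 0], impv[:, 1], impv[:, 2]):
        yd = signal.lfilter([1.0], [1.0, -np.exp(-dt_ms / (tau_d * 1e3))], x)
        yr = signal.lfilter([1.0], [1.0, -np.exp(-dt_ms / (tau_r * 1e3))], x)
        out.append((yd - yr) * norm)
    return out[0], np.stack(out[1:], axis=1)


def simulate_dipole(params: BiophysParams, layout: SynapseLayout,
                    events: SpikeEvents, dt: float = 1e-4,
                    clamp_voltage: float | None = None) -> DipoleTrace:
    """Integrate the conductance-based point neuron and read out the dipole.

    Exponential-Euler on the membrane; synaptic gates are exact discrete
    difference-of-exponentials filters of the spike impulse trains.  With
    ``clamp_voltage`` set, V is held fixed and the dipole is exactly linear
    in the input (used for superposition and scaling tests).
    """
    dt_ms = dt * 1000.0
    n_steps = int(round(events.T / dt))
    sE_tot, sE_vec = _gate_filters(events, layout, params.tauE, params.riseE,
                                   ~layout.is_inh, n_steps, dt_ms)
    sI_tot, sI_vec = _gate_filters(events, layout, params.tauI, params.riseI,
                                   layout.is_inh, n_steps, dt_ms)
    GL = params.gL * _AREA_CM2 * 1e6   # mS/cm^2 * cm^2 -> uS -> *1e3 = nS
    Cpf = params.Cm * _AREA_CM2 * 1e6  # uF/cm^2 * cm^2 -> uF -> *1e6 = pF
    gE_t = params.gE * sE_tot
    gI_t = params.gI * sI_tot
    if clamp_voltage is not None:
        v = np.full(n_steps, float(clamp_voltage))
    else:
        g_tot = GL + gE_t + gI_t                       # nS
        vinf = (GL * params.EL + gE_t * params.EE + gI_t * params.EI) / g_tot
        decay = np.exp(-g_tot * dt_ms / Cpf)           # nS*ms/pF dimensionless
        v = _integrate_v(decay, vinf, params.EL)[:-1]
        if np.max(np.abs(v)) > 200.0:
            raise FloatingPointError(
                f"membrane integration unstable: |V| reached {np.max(np.abs(v)):.1f} mV")
    Q = (params.gE * (params.EE - v))[:, None] * sE_vec \
        + (params.gI * (params.EI - v))[:, None] * sI_vec
    return DipoleTrace(t_ms=np.arange(n_steps) * dt_ms, Q=Q, Vm=v)


@dataclass(frozen=True)
class GainSampler:
    """Scalar lead-field gain (log-normal) and uniform projection direction,
    standing in for location averaging through a head model."""

    sigma_log: float = 0.5
    median: float = 1.0

    def sample(self, rng):
        g = self.median * np.exp(self.sigma_log * rng.standard_normal())
        u = rng.standard_normal(3)
        return g, u / np.linalg.norm(u)


def unitary_spectrum(params: BiophysParams, layout: SynapseLayout | None = None,
                     rates: RateFunction | None = None, T: float = 10.0,
                     dt: float = 1e-4, n_trials: int = 4,
                     gain: GainSampler | None = None, rng_seed=0,
                     fmax: float = 500.0, nperseg_s: float = 2.0,
                     external_trains: list | None = None,
                     clamp_voltage: float | None = None,
                     input_factory=None) -> Spectrum:
    """Location/trial-averaged single-neuron EEG power spectrum.

    Each trial draws fresh input, integrates the dipole, projects it on a
    random direction with a sampled lead-field gain, and Welch-averages
    (2 s segments, 50% overlap).  Trials are averaged in power.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rates is None:
        rates = RateFunction()
    if gain is None:
        gain = GainSampler()
    ss = np.random.SeedSequence(rng_seed)
    fs = 1.0 / dt
    nperseg = int(round(nperseg_s * fs))
    acc = None
    for child in ss.spawn(n_trials):
        rng = np.random.default_rng(child)
        lay = layout if layout is not None else SynapseLayout.random(
            rng_seed=rng.integers(2 ** 31))
        if input_factory is not None:
            ev = input_factory(lay, rng.integers(2 ** 31))
        else:
            ev = generate_input(lay, params, rates, T, dt,
                                rng.integers(2 ** 31),
                                external_trains=external_trains)
        tr = simulate_dipole(params, lay, ev, dt, clamp_voltage=clamp_voltage)
        g, u = gain.sample(rng)
        x = g * (tr.Q @ u)
        f, p = signal.welch(x - x.mean(), fs=fs, nperseg=min(nperseg, x.size))
        acc = p if acc is None else acc + p
    m = (f <= fmax) & (f > 0)
    return Spectrum(f[m], acc[m] / n_trials)


# ---------------------------------------------------------------------------
# variance-based sensitivity of the spectral slope
# ---------------------------------------------------------------------------

def sobol_indices(func, k: int, n_base: int, rng_seed, second_order_pairs=()):
    """Saltelli-design Sobol indices of ``func`` over the unit hypercube.

    ``func`` maps an (n, k) array of unit-cube rows to n outputs.  First
    order uses the Saltelli 2010 estimator, total order the Jansen
    estimator; closed second-order indices are computed for the requested
    pairs from the radial AB/BA design (cost: n_base * (2k + 2) calls).
    Returns dict with "S1", "ST" (length-k arrays) and "S2" {pair: value}.
    """
    if n_base < 2:
        raise ValueError("n_base must be >= 2")
    rng = np.random.default_rng(rng_seed)
    A = rng.random((n_base, k))
    B = rng.random((n_base, k))
    fA, fB = func(A), func(B)
    fAB = np.empty((k, n_base))
    fBA = np.empty((k, n_base))
    for i in range(k):
        ABi = A.copy(); ABi[:, i] = B[:, i]
        BAi = B.copy(); BAi[:, i] = A[:, i]
        fAB[i] = func(ABi)
        fBA[i] = func(BAi)
    allf = np.concatenate([fA, fB])
    V = np.var(allf)
    mu = np.mean(allf)
    S1 = np.array([np.mean(fB * (fAB[i] - fA)) / V for i in range(k)])
    ST = np.array([0.5 * np.mean((fA - fAB[i]) ** 2) / V for i in range(k)])
    S2 = {}
    for (i, j) in second_order_pairs:
        Vij = np.mean(fBA[i] * fAB[j]) - mu ** 2  # closed effect of {i, j}
        S2[(i, j)] = Vij / V - S1[i] - S1[j]
    return {"S1": S1, "ST": ST, "S2": S2, "V": V}


def slope_sensitivity(n_samples: int = 256, rng_seed=0, simulator=None,
                      T: float = 4.0, n_trials: int = 1,
                      include_dummy: bool = False,
                      second_order_pairs=(("gL", "lamE"), ("gL", "lamI"))):
    """First/total (and selected second) order Sobol indices of the
    spectral slope beta (1-40 Hz power-law fit) w.r.t. the eight sampled
    biophysical parameters.

    ``simulator`` maps a BiophysParams to a beta value; the default runs
    ``unitary_spectrum`` + ``fit_slope``.  ``include_dummy`` appends an
    inert parameter whose indices should vanish (estimator check).
    Returns a pandas DataFrame indexed by parameter name.
    """
    import pandas as pd

    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    names = list(SAMPLING_RANGES)
    if include_dummy:
        names = names + ["dummy"]
    k = len(names)
    ss = np.random.SeedSequence(rng_seed)
    sim_seed = ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31)

    if simulator is None:
        # common random numbers: a fixed simulation seed makes beta a
        # deterministic function of the parameters, so simulation noise does
        # not leak into the variance decomposition
        def simulator(p):
            spec = unitary_spectrum(p, T=T, n_trials=n_trials, rng_seed=sim_seed)
            return fit_slope(spec, (1.0, 40.0)).beta

    def func(U):
        out = np.empty(U.shape[0])
        for r, row in enumerate(U):
            kw = {nm: _from_unit(nm, row[j]) for j, nm in enumerate(names)
                  if nm != "dummy"}
            out[r] = simulator(BiophysParams(**kw))
        return out

    pairs_ix = [(names.index(a), names.index(b)) for a, b in second_order_pairs]
    res = sobol_indices(func, k, n_samples, ss.spawn(1)[0], pairs_ix)
    df = pd.DataFrame({"S1": res["S1"], "ST": res["ST"]}, index=names)
    s2 = {f"{names[i]}x{names[j]}": v for (i, j), v in res["S2"].items()}
    df.attrs["S2"] = s2
    df.attrs["V"] = res["V"]
    return df
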