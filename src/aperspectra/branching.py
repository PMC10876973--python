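"""Spatial subcritical branching network of binary neurons.

Neurons live on a unit square with torus topology.  Connectivity (Rule #1):
each neuron projects to exactly ``d_out`` others, sampled without
replacement with probability decaying exponentially with distance.
Dynamics (Rule #2): every neuron fires baseline Poisson spikes at rate
``lam0*(1-m)``; each spike gives each out-neighbour an independent
probability ``m/d_out`` of firing within the following ``prop_window``
(4 ms).  The branching number ``m`` tunes the network from fully
asynchronous (m=0) to near avalanche criticality (m -> 1), while the
stationary per-neuron rate stays at ``lam0`` (subcritical branching
identity: lam0*(1-m)/(1-m)).

Inhibitory units (15% of the network) are not wired into the graph; their
influence is folded into ``m``.  Their spike trains are composed of a
fraction ``m`` thinned from nearby excitatory units plus a fraction
``1-m`` of independent Poisson spikes, so that they follow network
activity to the same degree as excitatory units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["BranchingParams", "SpikeRaster", "build_network", "simulate",
           "attach_inhibitory", "sttc", "sttc_matrix", "population_rate"]


@dataclass(frozen=True)
class BranchingParams:
    N: int = 2000
    m: float = 0.98
    lam0: float = 1.0          # target stationary rate per neuron, Hz (= lamE)
    lam_i: float = 5.0         # inhibitory unit rate, Hz
    d_out: int = 10
    kernel_scale: float = 0.05  # exponential connection kernel, unit-square units
    inh_fraction: float = 0.15
    dt: float = 0.25           # simulation bin, ms; same-bin spike merges
                               # depress the realised branching ratio by
                               # O(dt), which is amplified ~(1-m)^-1 near
                               # criticality, so keep bins fine
    prop_window: float = 4.0   # spike propagation window, ms
    k_nearest: int = 20        # E units pooled per inhibitory unit

    def __post_init__(self):
        if not 0.0 <= self.m < 1.0:
            raise ValueError("branching number m must satisfy 0 <= m < 1")
        if self.d_out < 1 or not 0.0 <= self.inh_fraction < 1.0:
            raise ValueError("invalid d_out or inh_fraction")


@dataclass
class SpikeRaster:
    """Per-neuron spike trains (ms, sorted) with planar positions and E/I labels."""

    trains: list
    positions: np.ndarray
    kind: np.ndarray  # 'E' or 'I' per neuron
    T: float          # duration, s

    @property
    def n(self):
        return len(self.trains)

    def rates(self):
        return np.array([len(t) for t in self.trains]) / self.T


def _torus_dist(pos):
    d = np.abs(pos[:, None, :] - pos[None, :, :])
    d = np.minimum(d, 1.0 - d)
    return np.sqrt((d ** 2).sum(-1))


def build_network(params: BranchingParams, rng_seed) -> tuple:
    """Place neurons uniformly on the unit torus and wire ``d_out`` targets
    per neuron with probability proportional to exp(-d/kernel_scale).

    Returns ``(targets, positions)`` where ``targets`` has shape
    ``(N, d_out)``.
    """
    if params.N < params.d_out + 1:
        raise ValueError("need N >= d_out + 1")
    rng = np.random.default_rng(rng_seed)
    pos = rng.random((params.N, 2))
    dist = _torus_dist(pos)
    targets = np.empty((params.N, params.d_out), dtype=np.int64)
    for i in range(params.N):
        w = np.exp(-dist[i] / params.kernel_scale)
        w[i] = 0.0
        w /= w.sum()
        targets[i] = rng.choice(params.N, size=params.d_out, replace=False, p=w)
    return targets, pos


def simulate(targets: np.ndarray, params: BranchingParams, T: float,
             rng_seed, positions: np.ndarray | None = None) -> SpikeRaster:
    """Discrete-time branching simulation over ``T`` seconds.

    Each bin, a neuron fires if it draws a baseline Poisson event (rate
    lam0*(1-m)) or has a pending propagated spike; a neuron fires at most
    once per bin.  Every spike schedules, per out-neighbour, an independent
    Bernoulli(m/d_out) spike placed uniformly within the next
    ``prop_window`` ms.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    rng = np.random.default_rng(rng_seed)
    N, m, dt = params.N, params.m, params.dt
    n_bins = int(round(T * 1000.0 / dt))
    horizon = max(int(np.ceil(params.prop_window / dt)), 1)
    p_base = params.lam0 * (1.0 - m) * dt / 1000.0
    p_prop = m / params.d_out

    pending = np.zeros((horizon + 1, N), dtype=bool)
    spike_bins, spike_ids = [], []
    for t in range(n_bins):
        slot = t % (horizon + 1)
        fire = pending[slot] | (rng.random(N) < p_base)
        pending[slot] = False
        idx = np.flatnonzero(fire)
        if idx.size:
            spike_bins.append(np.full(idx.size, t, dtype=np.int64))
            spike_ids.append(idx)
            if m > 0.0:
                tg = targets[idx].ravel()
                hit = tg[rng.random(tg.size) < p_prop]
                if hit.size:
                    delay = rng.integers(1, horizon + 1, size=hit.size)
                    pending[(t + delay) % (horizon + 1), hit] = True
    if spike_bins:
        bins = np.concatenate(spike_bins)
        ids = np.concatenate(spike_ids)
        times = (bins + rng.random(bins.size)) * dt  # uniform jitter within bin
        times = np.minimum(times, T * 1000.0 - 1e-9)
    else:
        ids = np.empty(0, dtype=np.int64)
        times = np.empty(0)
    order = np.lexsort((times, ids))
    ids, times = ids[order], times[order]
    cuts = np.searchsorted(ids, np.arange(N + 1))
    trains = [times[cuts[i]:cuts[i + 1]] for i in range(N)]
    if positions is None:
        positions = np.full((N, 2), np.nan)
    return SpikeRaster(trains=trains, positions=positions,
                       kind=np.full(N, "E"), T=T)


def attach_inhibitory(raster: SpikeRaster, params: BranchingParams,
                      rng_seed) -> SpikeRaster:
    """Append inhibitory units (``inh_fraction`` of the final network).

    Each inhibitory train pools the spikes of its ``k_nearest`` excitatory
    neighbours thinned to contribute ``m*lam_i`` of its rate, plus an
    independent Poisson train at ``(1-m)*lam_i``, matching the recurrent
    drive proportion of excitatory units.
    """
    if np.any(raster.kind != "E"):
        raise ValueError("raster must contain only excitatory units")
    rng = np.random.default_rng(rng_seed)
    nE = raster.n
    nI = int(round(params.inh_fraction * nE / (1.0 - params.inh_fraction)))
    T_ms = raster.T * 1000.0
    pos_i = rng.random((nI, 2))
    new_trains = list(raster.trains)
    have_pos = bool(np.all(np.isfinite(raster.positions)))
    for j in range(nI):
        if params.lam_i <= 0:
            new_trains.append(np.empty(0))
            continue
        if have_pos:
            d = np.abs(raster.positions - pos_i[j])
            d = np.minimum(d, 1.0 - d)
            near = np.argsort((d ** 2).sum(1))[:params.k_nearest]
        else:
            near = rng.choice(nE, size=min(params.k_nearest, nE), replace=False)
        pooled = np.concatenate([raster.trains[i] for i in near]) if near.size else np.empty(0)
        target_rec = params.m * params.lam_i
        pool_rate = pooled.size / raster.T if raster.T > 0 else 0.0
        p_keep = min(target_rec / pool_rate, 1.0) if pool_rate > 0 else 0.0
        rec = pooled[rng.random(pooled.size) < p_keep]
        n_ind = rng.poisson((1.0 - params.m) * params.lam_i * raster.T)
        ind = rng.random(n_ind) * T_ms
        new_trains.append(np.sort(np.concatenate([rec, ind])))
    return SpikeRaster(
        trains=new_trains,
        positions=np.vstack([raster.positions, pos_i]),
        kind=np.concatenate([raster.kind, np.full(nI, "I")]),
        T=raster.T,
    )


def _tiled_fraction(train, delta_t, T_ms):
    """Fraction of [0, T] covered by the union of +/- delta_t windows."""
    lo = np.clip(train - delta_t, 0.0, T_ms)
    hi = np.clip(train + delta_t, 0.0, T_ms)
    total, cur_lo, cur_hi = 0.0, lo[0], hi[0]
    for a, b in zip(lo[1:], hi[1:]):
        if a <= cur_hi:
            cur_hi = max(cur_hi, b)
        else:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = a, b
    total += cur_hi - cur_lo
    return total / T_ms


def _prop_within(a, b, delta_t):
    """Fraction of spikes in a within +/- delta_t of any spike in b."""
    pos = np.searchsorted(b, a)
    left = np.where(pos > 0, a - b[np.maximum(pos - 1, 0)], np.inf)
    right = np.where(pos < b.size, b[np.minimum(pos, b.size - 1)] - a, np.inf)
    return float(np.mean(np.minimum(left, right) <= delta_t))


def sttc(train_a, train_b, delta_t: float = 10.0, T: float = 40.0) -> float:
    """Spike time tiling coefficient of two sorted trains (ms) on [0, T s].

    STTC = ((PA - TB)/(1 - PA*TB) + (PB - TA)/(1 - PB*TA)) / 2, where PA is
    the fraction of A spikes within +/- delta_t of a B spike and TB the
    fraction of the recording tiled by +/- delta_t windows around B spikes.
    Rate-insensitive, bounded in [-1, 1]; an empty train gives 0.
    """
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    T_ms = T * 1000.0
    if a.size == 0 or b.size == 0:
        warnings.warn("STTC of an empty train is defined as 0")
        return 0.0
    TA = _tiled_fraction(a, delta_t, T_ms)
    TB = _tiled_fraction(b, delta_t, T_ms)
    PA = _prop_within(a, b, delta_t)
    PB = _prop_within(b, a, delta_t)
    term1 = (PA - TB) / (1.0 - PA * TB) if PA * TB != 1.0 else 0.0
    term2 = (PB - TA) / (1.0 - PB * TA) if PB * TA != 1.0 else 0.0
    return 0.5 * (term1 + term2)


try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _sttc_pairs(flat, offsets, tiled, delta_t):
        n = offsets.size - 1
        C = np.eye(n)
        for i in range(n):
            a0, a1 = offsets[i], offsets[i + 1]
            for j in range(i + 1, n):
                b0, b1 = offsets[j], offsets[j + 1]
                if a1 == a0 or b1 == b0:
                    continue
                # two-pointer nearest-neighbour scan both ways
                ca = 0
                k = b0
                for ia in range(a0, a1):
                    t = flat[ia]
                    while k + 1 < b1 and flat[k + 1] <= t:
                        k += 1
                    d = abs(t - flat[k])
                    if k + 1 < b1:
                        d2 = abs(flat[k + 1] - t)
                        if d2 < d:
                            d = d2
                    if d <= delta_t:
                        ca += 1
                cb = 0
                k = a0
                for ib in range(b0, b1):
                    t = flat[ib]
                    while k + 1 < a1 and flat[k + 1] <= t:
                        k += 1
                    d = abs(t - flat[k])
                    if k + 1 < a1:
                        d2 = abs(flat[k + 1] - t)
                        if d2 < d:
                            d = d2
                    if d <= delta_t:
                        cb += 1
                PA = ca / (a1 - a0)
                PB = cb / (b1 - b0)
                TA, TB = tiled[i], tiled[j]
                v = 0.0
                if PA * TB != 1.0:
                    v += (PA - TB) / (1.0 - PA * TB)
                if PB * TA != 1.0:
                    v += (PB - TA) / (1.0 - PB * TA)
                C[i, j] = C[j, i] = 0.5 * v
        return C
except ImportError:  # pragma: no cover
    _sttc_pairs = None


def sttc_matrix(raster: SpikeRaster, delta_t: float = 10.0) -> np.ndarray:
    """Pairwise STTC matrix (unit diagonal) of all trains in a raster.

    Uses a compiled two-pointer kernel when numba is available; it agrees
    with the scalar ``sttc`` to floating-point accuracy.
    """
    n = raster.n
    T_ms = raster.T * 1000.0
    if _sttc_pairs is not None:
        offsets = np.zeros(n + 1, dtype=np.int64)
        for i, tr in enumerate(raster.trains):
            offsets[i + 1] = offsets[i] + len(tr)
        flat = (np.concatenate(raster.trains) if offsets[-1]
                else np.empty(0))
        tiled = np.array([_tiled_fraction(np.asarray(tr, float), delta_t, T_ms)
                          if len(tr) else 0.0 for tr in raster.trains])
        return _sttc_pairs(flat.astype(float), offsets, tiled, float(delta_t))
    C = np.eye(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                C[i, j] = C[j, i] = sttc(raster.trains[i], raster.trains[j],
                                         delta_t=delta_t, T=raster.T)
    return C


def population_rate(raster: SpikeRaster, bin_ms: float = 1.0) -> tuple:
    """Binned population spike count per neuron per second; returns (t_s, rate_hz)."""
    T_ms = raster.T * 1000.0
    edges = np.arange(0.0, T_ms + bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    for tr in raster.trains:
        c, _ = np.histogram(tr, bins=edges)
        counts += c
    rate = counts / raster.n / (bin_ms / 1000.0)
    t = (edges[:-1] + edges[1:]) / 2.0 / 1000.0
    return t, rate


def save_raster_tsv(raster: SpikeRaster, path):
    """Write (neuron_id, time_ms) rows; positions/kinds go to a JSON sidecar."""
    import json

    with open(path, "w") as fh:
        fh.write("neuron_id\ttime_ms\n")
        for i, tr in enumerate(raster.trains):
            for t in tr:
                fh.write(f"{i}\t{t:.6f}\n")
    side = {"T": raster.T, "kind": list(map(str, raster.kind)),
            "positions": np.asarray(raster.positions).tolist()}
    with open(str(path) + ".json", "w") as fh:
        json.dump(side, fh)


def load_raster_tsv(path) -> SpikeRaster:
    import json

    with open(str(path) + ".json") as fh:
        side = json.load(fh)
    ids, times = [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            i, t = line.split("\t")
            ids.append(int(i))
            times.append(float(t))
    ids_a = np.array(ids, dtype=np.int64)
    times_a = np.array(times)
    n = len(side["kind"])
    trains = [np.sort(times_a[ids_a == i]) for i in range(n)]
    return SpikeRaster(trains=trains, positions=np.array(side["positions"]),
                       kind=np.array(side["kind"]), T=side["T"])
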