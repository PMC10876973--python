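"""Dipole-coherence machinery: spherical embedding of presynaptic
populations by correlation, synapse assignment, optimality perturbation,
the minimal correlated-synapse model, and dyad dipole correlation.

Coherent single-neuron dipoles require synaptic inputs that are correlated
in time *and* aligned in space.  The pipeline here: (1) embed the
presynaptic population on a sphere so that strongly correlated units sit
at small angular distances; (2) map each postsynaptic synapse to the
nearest embedded unit; (3) optionally degrade the geometric alignment with
an optimality index X in [0, 1] (X=1: untouched; X=0: uniform
re-scatter); (4) drive two postsynaptic neurons from the shared source and
measure the correlation of their dipole projections.

The minimal model bypasses network simulation entirely: binary spike
trains whose pairwise count correlations follow R_max * exp(-theta_ij)
(angular separation on the sphere), generated by a dichotomised Gaussian
so the trains are white in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from aperspectra.branching import SpikeRaster, sttc_matrix
from aperspectra.neuron import (BiophysParams, SynapseLayout, generate_input,
                                simulate_dipole)

__all__ = [
    "SphericalEmbedding", "MinimalModelParams", "embed_on_sphere",
    "perturb_embedding", "assign_synapses", "minimal_correlated_trains",
    "dyad_dipole_correlation", "embedding_contract_rho",
]


@dataclass(frozen=True)
class SphericalEmbedding:
    """Unit vectors per presynaptic unit, plus the correlation matrix the
    embedding was built from."""

    points: np.ndarray
    source_corr: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        c = np.asarray(self.source_corr, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or c.shape != (p.shape[0], p.shape[0]):
            raise ValueError("points must be (n, 3) matching corr dimension")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "source_corr", c)

    @property
    def n(self):
        return self.points.shape[0]

    def angles(self) -> np.ndarray:
        g = np.clip(self.points @ self.points.T, -1.0, 1.0)
        return np.arccos(g)

    def save_tsv(self, path):
        np.savetxt(path, np.column_stack([np.arange(self.n), self.points]),
                   delimiter="\t", header="unit_id\tx\ty\tz", comments="",
                   fmt=("%d", "%.8f", "%.8f", "%.8f"))


@dataclass(frozen=True)
class MinimalModelParams:
    """Maximal synapse-input correlation with angular kernel exp(-theta)."""

    R_max: float = 0.3

    def __post_init__(self):
        if not 0.0 <= self.R_max < 1.0:
            raise ValueError("R_max must be in [0, 1)")


def embedding_contract_rho(emb: SphericalEmbedding) -> float:
    """Spearman rank correlation between pairwise source correlation and
    angular distance (the embedding contract: should be < -0.3)."""
    iu = np.triu_indices(emb.n, 1)
    return float(stats.spearmanr(emb.source_corr[iu], emb.angles()[iu]).statistic)


def embed_on_sphere(corr: np.ndarray, rng_seed=0) -> SphericalEmbedding:
    """Project units onto the unit sphere so that high-correlation pairs
    have small angular separation.

    A deterministic spectral embedding: rows of the top-3 eigenvector
    basis, scaled by sqrt of (clipped) eigenvalues and normalised to the
    sphere.  Any method passing the rank-correlation contract would do;
    the seed only resolves degenerate (zero-norm) rows.
    """
    C = np.asarray(corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("corr must be a symmetric square matrix")
    rng = np.random.default_rng(rng_seed)
    vals, vecs = np.linalg.eigh((C + C.T) / 2.0)
    top = np.argsort(vals)[::-1][:3]
    coords = vecs[:, top] * np.sqrt(np.maximum(vals[top], 0.0))
    norms = np.linalg.norm(coords, axis=1)
    bad = norms < 1e-12
    if np.any(bad):
        r = rng.standard_normal((bad.sum(), 3))
        coords[bad] = r / np.linalg.norm(r, axis=1, keepdims=True)
        norms = np.linalg.norm(coords, axis=1)
    pts = coords / norms[:, None]
    emb = SphericalEmbedding(points=pts, source_corr=C)
    return emb


def perturb_embedding(emb: SphericalEmbedding, X: float, rng_seed=0) -> SphericalEmbedding:
    """Displace each point along a uniformly random great-circle bearing by
    an angle theta = arccos(1 - 2*alpha*(1-X)), alpha ~ Uniform[0, 1].

    X is the optimality index: X=1 leaves points untouched; X=0 yields
    cos(theta) ~ Uniform[-1, 1], i.e. a uniform re-scatter over the sphere.
    """
    if not 0.0 <= X <= 1.0:
        raise ValueError("optimality index X must lie in [0, 1]")
    if X == 1.0:
        return emb
    rng = np.random.default_rng(rng_seed)
    p = emb.points
    alpha = rng.random(emb.n)
    theta = np.arccos(np.clip(1.0 - 2.0 * alpha * (1.0 - X), -1.0, 1.0))
    # random unit tangent per point
    r = rng.standard_normal((emb.n, 3))
    t = r - (np.sum(r * p, axis=1, keepdims=True)) * p
    tn = np.linalg.norm(t, axis=1, keepdims=True)
    # regenerate the rare tangent that collapsed
    for i in np.flatnonzero(tn[:, 0] < 1e-12):
        while tn[i, 0] < 1e-12:
            r_i = rng.standard_normal(3)
            t[i] = r_i - (r_i @ p[i]) * p[i]
            tn[i, 0] = np.linalg.norm(t[i])
    t /= tn
    new = np.cos(theta)[:, None] * p + np.sin(theta)[:, None] * t
    new /= np.linalg.norm(new, axis=1, keepdims=True)
    return SphericalEmbedding(points=new, source_corr=emb.source_corr)


def assign_synapses(emb: SphericalEmbedding, layout: SynapseLayout,
                    weights=None, rng_seed=0, kind=None) -> np.ndarray:
    """Map each synapse to a presynaptic unit: synapses are visited in
    area-weighted random order (with replacement) and connected to the
    closest unit on the sphere, until every synapse is mapped.

    Since units are never consumed, the visiting order does not change the
    outcome: every synapse ends up at its nearest unit (ties to the lowest
    index).  ``kind`` optionally restricts candidate units per synapse
    ('E'/'I' array over units, matched against layout.is_inh).
    """
    if emb.n == 0:
        raise ValueError("empty embedding")
    rng = np.random.default_rng(rng_seed)
    w = np.ones(layout.n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (layout.n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative, one per synapse")
    # area-weighted sampling with replacement until all synapses visited
    # (kept for fidelity to the generative procedure; outcome == nearest unit)
    visited = np.zeros(layout.n, dtype=bool)
    order = []
    p = w / w.sum()
    while not visited.all():
        draw = rng.choice(layout.n, size=layout.n, p=p)
        for s in draw:
            if not visited[s]:
                visited[s] = True
                order.append(s)

    gram = layout.directions @ emb.points.T  # cos(angle), higher = closer
    if kind is not None:
        kind = np.asarray(kind)
        mask_i = kind == "I"
        penal = np.where(mask_i[None, :] != layout.is_inh[:, None], -np.inf, 0.0)
        gram = gram + penal
    mapping = np.empty(layout.n, dtype=np.int64)
    for s in order:
        mapping[s] = int(np.argmax(gram[s]))
    return mapping


def save_mapping_tsv(mapping: np.ndarray, path):
    """Write a synapse -> presynaptic-unit assignment as (synapse_id,
    unit_id) rows."""
    np.savetxt(path, np.column_stack([np.arange(len(mapping)), mapping]),
               delimiter="\t", header="synapse_id\tunit_id", comments="",
               fmt="%d")


def _latent_corr_tables(p_by_kind, n_grid=61):
    """Latent Gaussian correlation required to realise a binary count
    correlation, tabulated per (kind, kind) pair of firing probabilities."""
    from scipy.stats import multivariate_normal, norm

    grid = np.linspace(-0.999, 0.999, n_grid)
    tables = {}
    for ka, pa in p_by_kind.items():
        for kb, pb in p_by_kind.items():
            if (kb, ka) in tables:
                tables[(ka, kb)] = tables[(kb, ka)]
                continue
            za, zb = norm.ppf(1 - pa), norm.ppf(1 - pb)
            r_bin = np.empty(n_grid)
            for g, lam in enumerate(grid):
                mvn = multivariate_normal([0.0, 0.0], [[1.0, lam], [lam, 1.0]],
                                          allow_singular=True)
                p11 = mvn.cdf([-za, -zb])
                r_bin[g] = (p11 - pa * pb) / np.sqrt(pa * (1 - pa) * pb * (1 - pb))
            tables[(ka, kb)] = (r_bin, grid)
    return tables


def minimal_correlated_trains(layout: SynapseLayout, params: MinimalModelParams,
                              lamE: float, lamI: float, T: float,
                              dt: float = 1e-3, rng_seed=0,
                              return_binary: bool = False):
    """Binary spike trains per 1 ms bin whose pairwise count correlations
    follow R_max * exp(-theta_ij) and which are white in time.

    Mechanism: dichotomised Gaussian.  The target binary correlation is
    converted pairwise (via the bivariate normal orthant probability) into
    a latent Gaussian correlation; the latent matrix is repaired to the
    nearest PSD matrix by eigenvalue clipping, and thresholded Gaussian
    draws per bin produce the spikes.  Infeasible targets are repaired with
    a warning rather than rejected.
    """
    rng = np.random.default_rng(rng_seed)
    n = layout.n
    n_bins = int(round(T / dt))
    p_e, p_i = lamE * dt, lamI * dt
    if max(p_e, p_i) >= 0.5:
        raise ValueError("rate*dt too high for binary bins")
    p_syn = np.where(layout.is_inh, p_i, p_e)
    if np.all(p_syn <= 0):
        return [np.empty(0) for _ in range(n)]

    g = np.clip(layout.directions @ layout.directions.T, -1.0, 1.0)
    target = params.R_max * np.exp(-np.arccos(g))
    np.fill_diagonal(target, 1.0)

    if params.R_max == 0.0:
        lam = np.eye(n)
    else:
        kinds = np.where(layout.is_inh, "I", "E")
        p_by_kind = {}
        if (~layout.is_inh).any() and p_e > 0:
            p_by_kind["E"] = p_e
        if layout.is_inh.any() and p_i > 0:
            p_by_kind["I"] = p_i
        tables = _latent_corr_tables(p_by_kind)
        lam = np.eye(n)
        iu = np.triu_indices(n, 1)
        # interpolate latent corr per pair, by kind pair
        for ka in p_by_kind:
            for kb in p_by_kind:
                r_bin, grid = tables[(ka, kb)]
                sel = (kinds[iu[0]] == ka) & (kinds[iu[1]] == kb)
                if not sel.any():
                    continue
                tgt = target[iu][sel]
                lam_vals = np.interp(tgt, r_bin, grid)
                rows, cols = iu[0][sel], iu[1][sel]
                lam[rows, cols] = lam_vals
                lam[cols, rows] = lam_vals
        # PSD repair by eigenvalue clipping
        vals, vecs = np.linalg.eigh(lam)
        if vals.min() < 0:
            if vals.min() < -1e-8:
                warnings.warn("latent correlation not PSD; repairing by "
                              "eigenvalue clipping")
            vals = np.maximum(vals, 0.0)
            lam = vecs @ np.diag(vals) @ vecs.T
            d = np.sqrt(np.diag(lam))
            lam = lam / np.outer(d, d)

    L = np.linalg.cholesky(lam + 1e-10 * np.eye(n))
    z_thr = stats.norm.ppf(1.0 - p_syn)
    trains = [[] for _ in range(n)]
    binary = np.zeros((n_bins, n), dtype=bool) if return_binary else None
    chunk = max(int(2e7 // n), 1)
    for start in range(0, n_bins, chunk):
        m = min(chunk, n_bins - start)
        Z = rng.standard_normal((m, n)) @ L.T
        hits = Z > z_thr[None, :]
        if return_binary:
            binary[start:start + m] = hits
        rows, cols = np.nonzero(hits)
        t_ms = (start + rows + rng.random(rows.size)) * dt * 1000.0
        for c in np.unique(cols):
            trains[c].append(t_ms[cols == c])
    out = [np.sort(np.concatenate(tr)) if tr else np.empty(0) for tr in trains]
    if return_binary:
        return out, binary
    return out


def dyad_dipole_correlation(biophys: BiophysParams, layout_a: SynapseLayout,
                            layout_b: SynapseLayout, trains_a: list,
                            trains_b: list, T: float, dt: float = 1e-4,
                            rng_seed=0, shuffle: bool = False,
                            axis="common_z") -> float:
    """Pearson correlation between matched scalar dipole projections of two
    neurons driven by per-synapse spike trains.

    ``axis``: "common_z" (default) projects both dipoles on the z axis —
    the dyad stands for neighbouring neurons with aligned apical-basal
    axes, as in the ensemble correlation model's cos(theta) factor;
    "apical" uses each neuron's own mean synapse direction; or pass an
    explicit 3-vector.  ``shuffle`` permutes each neuron's synapse
    directions, destroying the geometric alignment while preserving every
    train (control condition).
    """
    rng = np.random.default_rng(rng_seed)
    xs = []
    for layout, trains in ((layout_a, trains_a), (layout_b, trains_b)):
        if shuffle:
            perm = rng.permutation(layout.n)
            layout = SynapseLayout(layout.directions[perm], layout.is_inh)
        ev = generate_input(layout, biophys, None, T, dt, 0,
                            external_trains=trains)
        tr = simulate_dipole(biophys, layout, ev, dt)
        if isinstance(axis, str):
            u = np.array([0.0, 0.0, 1.0]) if axis == "common_z" else layout.apical_axis
        else:
            u = np.asarray(axis, dtype=float)
            u = u / np.linalg.norm(u)
        x = tr.Q @ u
        xs.append(x - x.mean())
    va, vb = np.var(xs[0]), np.var(xs[1])
    if va == 0.0 or vb == 0.0:
        warnings.warn("zero-variance dipole projection; correlation undefined")
        return np.nan
    return float(np.corrcoef(xs[0], xs[1])[0, 1])


def dyad_from_minimal_model(R_max: float, biophys: BiophysParams | None = None,
                            n_e: int = 400, T: float = 40.0, rng_seed=0,
                            shuffle: bool = False, dt: float = 2e-4) -> float:
    """Convenience driver: two neurons share a sphere of synapse positions;
    inputs are minimal-model correlated trains over the union of synapses."""
    if biophys is None:
        biophys = BiophysParams()
    ss = np.random.SeedSequence(rng_seed)
    s = [c.generate_state(1)[0] % (2 ** 31) for c in ss.spawn(4)]
    lay_a = SynapseLayout.random(n_e, rng_seed=s[0])
    lay_b = SynapseLayout.random(n_e, rng_seed=s[1])
    union = SynapseLayout(np.vstack([lay_a.directions, lay_b.directions]),
                          np.concatenate([lay_a.is_inh, lay_b.is_inh]))
    trains = minimal_correlated_trains(union, MinimalModelParams(R_max),
                                       biophys.lamE, biophys.lamI, T,
                                       rng_seed=s[2])
    na = lay_a.n
    return dyad_dipole_correlation(biophys, lay_a, lay_b, trains[:na],
                                   trains[na:], T, dt=dt, rng_seed=s[3],
                                   shuffle=shuffle)


def dyad_from_raster(raster: SpikeRaster, biophys: BiophysParams | None = None,
                     n_e: int = 800, optimality: float = 1.0, rng_seed=0,
                     shuffle: bool = False, delta_t: float = 10.0,
                     corr: np.ndarray | None = None,
                     unit_fraction: float = 0.5, dt: float = 2e-4,
                     emb: SphericalEmbedding | None = None) -> float:
    """Dyad dipole correlation from a presynaptic network raster: STTC ->
    spherical embedding -> optionally perturbed -> kind-matched nearest-unit
    synapse assignment per neuron -> dipole simulation and correlation.

    ``corr`` may supply a precomputed STTC matrix to avoid recomputation.
    ``unit_fraction`` restricts each postsynaptic neuron to a random subset
    of presynaptic units (axonal reach): without it, two neurons sampling
    nearest units from the same embedding share most inputs, which
    manufactures dipole correlation from common wiring even for an
    asynchronous (m=0) source.
    """
    if biophys is None:
        biophys = BiophysParams()
    ss = np.random.SeedSequence(rng_seed)
    s = [c.generate_state(1)[0] % (2 ** 31) for c in ss.spawn(6)]
    if emb is None:
        if corr is None:
            corr = sttc_matrix(raster, delta_t=delta_t)
        emb = embed_on_sphere(corr, rng_seed=s[0])
    emb = perturb_embedding(emb, optimality, rng_seed=s[1])
    kinds = np.asarray(raster.kind)
    trains_by = []
    for seed_lay, seed_asn in ((s[2], s[3]), (s[4], s[5])):
        rng = np.random.default_rng(seed_asn)
        lay = SynapseLayout.random(n_e, rng_seed=seed_lay)
        if unit_fraction < 1.0:
            keep = rng.random(emb.n) < unit_fraction
            # keep at least one unit of each kind
            for kd in ("E", "I"):
                kd_ix = np.flatnonzero(kinds == kd)
                if kd_ix.size and not keep[kd_ix].any():
                    keep[rng.choice(kd_ix)] = True
            sub_ix = np.flatnonzero(keep)
            sub = SphericalEmbedding(emb.points[sub_ix],
                                     emb.source_corr[np.ix_(sub_ix, sub_ix)])
            mp = sub_ix[assign_synapses(sub, lay, rng_seed=seed_asn,
                                        kind=kinds[sub_ix])]
        else:
            mp = assign_synapses(emb, lay, rng_seed=seed_asn, kind=kinds)
        trains_by.append((lay, [raster.trains[u] for u in mp]))
    (lay_a, tr_a), (lay_b, tr_b) = trains_by
    return dyad_dipole_correlation(biophys, lay_a, lay_b, tr_a, tr_b,
                                   raster.T, dt=dt, rng_seed=s[0],
                                   shuffle=shuffle)
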