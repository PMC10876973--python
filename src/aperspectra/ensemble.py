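"""Ensemble EEG power from single-neuron contributions on a cortical mesh.

The EEG is the linear superposition of N single-neuron signals, so its
spectrum is

    S_N(f) = sum_i S_i(f) + 2 sum_{i<j} gamma_ij(f) sqrt(S_i S_j)

and its total power sigma_N^2 = N sigma_0^2 + N (N-1) rho_bar sigma_0^2,
where rho_bar is the mean pairwise correlation of single-neuron signals.
Pairwise dipole correlation is modelled by a Gaussian spatial kernel times
the alignment of apical axes:

    rho_ij = rho_max exp(-d_ij^2 / sigma^2) cos(theta_ij)

with apical axes taken normal to the cortical surface.  rho_bar is then a
Stieltjes integral of the kernel against the mean "signed neuron count"
nu_bar(r): the surface-density-weighted, normal-alignment-signed number of
neurons within distance r of a sampled surface point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

from aperspectra.spectral import Spectrum

__all__ = ["CorticalMesh", "CouplingKernel", "EnsembleSpec",
           "ensemble_spectrum", "signed_neuron_count",
           "mean_pairwise_correlation", "ensemble_power"]


@dataclass(frozen=True)
class CouplingKernel:
    """Gaussian dipole-correlation kernel: peak rho_max, spatial variance
    sigma2 (mm^2; the study's plausible range for sigma is 5-13 mm)."""

    rho_max: float
    sigma2: float

    def __post_init__(self):
        if not 0.0 <= self.rho_max <= 1.0 or self.sigma2 <= 0:
            raise ValueError("require 0 <= rho_max <= 1 and sigma2 > 0")


@dataclass(frozen=True)
class EnsembleSpec:
    """Ensemble summary: neuron count, mean single-neuron EEG power (uV^2),
    mean pairwise correlation."""

    N: float = 16e9
    sigma0_sq: float = 1.0
    rho_bar: float = 0.0

    def __post_init__(self):
        if self.N < 1 or self.sigma0_sq < 0 or abs(self.rho_bar) > 1:
            raise ValueError("invalid ensemble specification")


class CorticalMesh:
    """Triangular cortical surface with a uniform neuron surface density.

    Wraps a :class:`trimesh.Trimesh`; face areas (mm^2) and unit normals
    come from the mesh.  ``mu`` is neurons per mm^2 (default 100,000).
    """

    def __init__(self, mesh: trimesh.Trimesh, mu: float = 1e5):
        if mu <= 0:
            raise ValueError("mu must be positive")
        self.mesh = mesh
        self.mu = float(mu)
        self.watertight = bool(mesh.is_watertight)

    @property
    def areas(self):
        return self.mesh.area_faces

    @property
    def normals(self):
        return self.mesh.face_normals

    @property
    def triangles(self):
        return self.mesh.triangles

    @property
    def n_neurons(self):
        return self.mu * self.mesh.area

    @classmethod
    def flat_square(cls, extent: float = 100.0, n: int = 40, mu: float = 1e5):
        """Flat square patch of side ``extent`` mm in the z=0 plane with
        aligned +z normals, triangulated on an n x n grid."""
        g = np.linspace(-extent / 2, extent / 2, n + 1)
        xx, yy = np.meshgrid(g, g)
        verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        faces = []
        for i in range(n):
            for j in range(n):
                a = i * (n + 1) + j
                b, c, d = a + 1, a + n + 1, a + n + 2
                faces.append([a, b, d])
                faces.append([a, d, c])
        m = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
        # orient all normals to +z
        flip = m.face_normals[:, 2] < 0
        f = m.faces.copy()
        f[flip] = f[flip][:, ::-1]
        m = trimesh.Trimesh(vertices=verts, faces=f, process=False)
        return cls(m, mu=mu)

    @classmethod
    def icosphere(cls, radius: float = 50.0, subdivisions: int = 4, mu: float = 1e5):
        m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        return cls(m, mu=mu)

    @classmethod
    def load(cls, path, mu: float = 1e5):
        """Read an OFF or PLY (ASCII) surface; any trimesh-supported format
        works, including a user-supplied anatomical template."""
        m = trimesh.load(path, force="mesh", process=False)
        return cls(m, mu=mu)

    def save(self, path):
        self.mesh.export(path)

    def sample_surface(self, k: int, rng):
        """Area-weighted random surface points; returns (points, face index)."""
        w = self.areas / self.areas.sum()
        fi = rng.choice(len(w), size=k, p=w)
        u = rng.random((k, 2))
        flip = u.sum(1) > 1
        u[flip] = 1.0 - u[flip]
        tri = self.triangles[fi]
        pts = tri[:, 0] + u[:, [0]] * (tri[:, 1] - tri[:, 0]) \
            + u[:, [1]] * (tri[:, 2] - tri[:, 0])
        return pts, fi


def ensemble_spectrum(spectra: list, gamma) -> Spectrum:
    """Coherence superposition of single-neuron spectra.

    ``gamma``: (n, n) array (frequency-constant) or (n, n, F) array of
    pairwise coherences, |gamma| <= 1.  A coherence assignment that drives
    the total negative is flagged with a warning (inconsistent coherence
    matrix), not clipped.
    """
    freqs = spectra[0].freqs
    P = np.stack([s.power for s in spectra])
    if any(s.freqs.shape != freqs.shape or not np.allclose(s.freqs, freqs)
           for s in spectra[1:]):
        raise ValueError("spectra must share a common frequency grid")
    g = np.asarray(gamma, dtype=float)
    n = P.shape[0]
    if np.any(np.abs(g) > 1.0 + 1e-12):
        raise ValueError("|gamma| must not exceed 1")
    A = np.sqrt(P)  # (n, F)
    if g.shape == (n, n):
        g3 = np.broadcast_to(g[:, :, None], (n, n, freqs.size))
    elif g.shape == (n, n, freqs.size):
        g3 = g
    else:
        raise ValueError("gamma must be (n, n) or (n, n, F)")
    cross = np.einsum("ijf,if,jf->f", g3, A, A) - np.einsum("iif,if->f", g3, A ** 2)
    total = P.sum(0) + cross  # cross already counts i<j twice (symmetric sum)
    if np.any(total < 0):
        warnings.warn("coherence assignment yields negative ensemble power "
                      "(inconsistent gamma)")
    return Spectrum(freqs, total)


def _tri_ball_fraction(tri, center, r, depth):
    """Fraction of a triangle inside the ball |x - center| <= r, by
    recursive 4-way subdivision."""
    d = np.linalg.norm(tri - center, axis=1)
    inside = d <= r
    if inside.all():
        return 1.0
    edges = np.linalg.norm(tri - np.roll(tri, 1, axis=0), axis=1)
    if d.min() - edges.max() > r:   # every interior point is > r away
        return 0.0
    if depth == 0:
        return inside.mean()
    m01 = (tri[0] + tri[1]) / 2.0
    m12 = (tri[1] + tri[2]) / 2.0
    m20 = (tri[2] + tri[0]) / 2.0
    subs = (np.array([tri[0], m01, m20]), np.array([m01, tri[1], m12]),
            np.array([m20, m12, tri[2]]), np.array([m01, m12, m20]))
    return sum(_tri_ball_fraction(s, center, r, depth - 1) for s in subs) / 4.0


def signed_neuron_count(mesh: CorticalMesh, x_i, normal_i, r: float,
                        rel_tol: float = 1e-3, max_depth: int = 8) -> float:
    """Signed number of neurons within radius ``r`` of surface point ``x_i``:

        nu_i(r) = sum_j mu * A_j * f_j(r, x_i) * (N_j . N_i)

    where f_j is the fraction of face j inside the ball.  Fractions use
    adaptive triangle subdivision, deepening until the relative change of
    nu falls below ``rel_tol`` (capped at ``max_depth``).
    """
    if r < 0:
        raise ValueError("radius must be non-negative")
    if r == 0:
        return 0.0
    x = np.asarray(x_i, dtype=float)
    ni = np.asarray(normal_i, dtype=float)
    ni = ni / np.linalg.norm(ni)
    tris = mesh.triangles
    # candidate faces: bounding check
    dmin = np.linalg.norm(tris - x, axis=2).min(1) - \
        np.linalg.norm(tris - np.roll(tris, 1, axis=1), axis=2).max(1)
    cand = np.flatnonzero(dmin <= r)
    align = mesh.normals @ ni
    w = mesh.mu * mesh.areas * align
    prev = None
    for depth in range(2, max_depth + 1):
        nu = 0.0
        for j in cand:
            fj = _tri_ball_fraction(tris[j], x, r, depth)
            if fj:
                nu += w[j] * fj
        if prev is not None and abs(nu - prev) <= rel_tol * max(abs(nu), 1e-300):
            return nu
        prev = nu
    return nu


def _refined_face_samples(mesh: CorticalMesh, max_edge: float):
    """Subdivide faces until edges < max_edge; return piece centroids,
    signed weights mu*A*(N_j .) split per piece (areas only; alignment
    applied later)."""
    tris = mesh.triangles
    cents, areas, fidx = [], [], []
    for j, tri in enumerate(tris):
        stack = [tri]
        while stack:
            t = stack.pop()
            e = np.linalg.norm(t - np.roll(t, 1, axis=0), axis=1).max()
            if e <= max_edge:
                cents.append(t.mean(0))
                areas.append(np.linalg.norm(np.cross(t[1] - t[0], t[2] - t[0])) / 2.0)
                fidx.append(j)
            else:
                m01, m12, m20 = (t[0] + t[1]) / 2, (t[1] + t[2]) / 2, (t[2] + t[0]) / 2
                stack += [np.array([t[0], m01, m20]), np.array([m01, t[1], m12]),
                          np.array([m20, m12, t[2]]), np.array([m01, m12, m20])]
    return np.array(cents), np.array(areas), np.array(fidx, dtype=np.int64)


def mean_pairwise_correlation(mesh: CorticalMesh, kernel: CouplingKernel,
                              k_samples: int = 2000, rng_seed=0,
                              n_r: int = 120, return_nu: bool = False,
                              sample_points=None):
    """Monte-Carlo estimate of the mean pairwise dipole correlation rho_bar.

    Averages the signed neuron count nu_i(r) over ``k_samples``
    area-weighted surface points onto an r-grid out to 5 sigma, then
    integrates rho_max*exp(-r^2/sigma^2) against d nu_bar(r) by the
    trapezoid (midpoint Stieltjes) rule.  Normalised by N - 1 with
    N = mu * total area.

    ``sample_points`` = (points, face_indices) overrides the area-weighted
    sampling — e.g. interior-only points of an open flat patch, whose
    boundary would otherwise truncate nu_bar.
    """
    rng = np.random.default_rng(rng_seed)
    sigma = float(np.sqrt(kernel.sigma2))
    r_max = 5.0 * sigma
    r_grid = np.linspace(0.0, r_max, n_r + 1)
    cents, areas, fidx = _refined_face_samples(mesh, max_edge=r_max / 15.0)
    if sample_points is None:
        pts, pfi = mesh.sample_surface(k_samples, rng)
    else:
        pts, pfi = sample_points
        k_samples = len(pts)
    normals = mesh.normals
    nu_bar = np.zeros(n_r + 1)
    for p, fi in zip(pts, pfi):
        d = np.linalg.norm(cents - p, axis=1)
        wt = mesh.mu * areas * (normals[fidx] @ normals[fi])
        hist, _ = np.histogram(d, bins=r_grid, weights=wt)
        nu_bar[1:] += np.cumsum(hist)
    nu_bar /= k_samples
    d_nu = np.diff(nu_bar)
    r_mid = (r_grid[:-1] + r_grid[1:]) / 2.0
    N = mesh.n_neurons
    rho_bar = kernel.rho_max * np.sum(np.exp(-r_mid ** 2 / kernel.sigma2) * d_nu) / (N - 1.0)
    if return_nu:
        return float(rho_bar), (r_grid, nu_bar)
    return float(rho_bar)


def ensemble_power(spec: EnsembleSpec) -> float:
    """Total ensemble EEG power: N sigma0^2 + N (N-1) rho_bar sigma0^2 (uV^2)."""
    return spec.N * spec.sigma0_sq * (1.0 + (spec.N - 1.0) * spec.rho_bar)
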