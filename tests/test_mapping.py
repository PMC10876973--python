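"""Spherical embedding, optimality perturbation, synapse assignment,
minimal correlated-train model and dyad dipole correlations."""

import numpy as np
import pytest
from scipy import stats

from aperspectra.mapping import (MinimalModelParams, SphericalEmbedding,
                                 assign_synapses, dyad_dipole_correlation,
                                 dyad_from_minimal_model, dyad_from_raster,
                                 embed_on_sphere, embedding_contract_rho,
                                 minimal_correlated_trains, perturb_embedding)
from aperspectra.neuron import SynapseLayout


def block_corr(sizes, within, between):
    n = sum(sizes)
    C = np.full((n, n), between, dtype=float)
    start = 0
    for s in sizes:
        C[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(C, 1.0)
    return C


class TestEmbedOnSphere:
    def test_anticorrelated_clusters_on_opposite_hemispheres(self):
        C = block_corr([30, 30], 0.9, -0.9)
        emb = embed_on_sphere(C, 0)
        ang = emb.angles()
        assert ang[:30, 30:].mean() > np.pi / 2

    def test_three_cluster_structure(self):
        C = block_corr([20, 20, 20], 0.8, 0.05)
        emb = embed_on_sphere(C, 1)
        ang = emb.angles()
        within = np.concatenate([ang[:20, :20].ravel(), ang[20:40, 20:40].ravel(),
                                 ang[40:, 40:].ravel()])
        between = np.concatenate([ang[:20, 20:].ravel(), ang[20:40, 40:].ravel()])
        assert within.mean() < between.mean()

    def test_contract_on_network_correlations(self, small_sttc_matrix):
        emb = embed_on_sphere(small_sttc_matrix, 2)
        assert embedding_contract_rho(emb) < -0.3

    def test_asymmetric_matrix_rejected(self):
        C = np.eye(4)
        C[0, 1] = 0.5
        with pytest.raises(ValueError):
            embed_on_sphere(C, 0)


class TestPerturbEmbedding:
    @pytest.fixture()
    def emb(self):
        C = block_corr([40, 40], 0.8, -0.5)
        return embed_on_sphere(C, 3)

    def test_identity_at_full_optimality(self, emb):
        out = perturb_embedding(emb, 1.0, 4)
        np.testing.assert_array_equal(out.points, emb.points)

    def test_uniform_rescatter_at_zero_optimality(self):
        rng = np.random.default_rng(5)
        pts = np.tile([[0.0, 0.0, 1.0]], (5000, 1))  # everything at the pole
        emb = SphericalEmbedding(pts, np.eye(5000))
        out = perturb_embedding(emb, 0.0, 6)
        z = out.points[:, 2]
        phi = np.arctan2(out.points[:, 1], out.points[:, 0])
        assert stats.kstest(z, stats.uniform(-1, 2).cdf).pvalue > 0.01
        assert stats.kstest(phi, stats.uniform(-np.pi, 2 * np.pi).cdf).pvalue > 0.01

    def test_displacement_monotone_in_optimality(self, emb):
        disp = []
        for X in (0.0, 0.25, 0.5, 1.0):
            out = perturb_embedding(emb, X, 7)
            cosang = np.sum(out.points * emb.points, axis=1)
            disp.append(np.arccos(np.clip(cosang, -1, 1)).mean())
        assert disp[0] > disp[1] > disp[2] > disp[3]
        assert disp[3] < 1e-6


class TestAssignSynapses:
    def test_single_unit_takes_everything(self):
        emb = SphericalEmbedding(np.array([[0.0, 0.0, 1.0]]), np.eye(1))
        lay = SynapseLayout.random(20, rng_seed=8)
        mapping = assign_synapses(emb, lay, rng_seed=9)
        assert np.all(mapping == 0)

    def test_colocated_units_map_identically(self):
        lay = SynapseLayout.random(30, rng_seed=10)
        emb = SphericalEmbedding(lay.directions.copy(),
                                 np.eye(lay.n))
        mapping = assign_synapses(emb, lay, rng_seed=11)
        np.testing.assert_array_equal(mapping, np.arange(lay.n))

    def test_angles_smaller_than_random_assignment(self):
        rng = np.random.default_rng(12)
        pts = rng.standard_normal((100, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        emb = SphericalEmbedding(pts, np.eye(100))
        lay = SynapseLayout.random(200, rng_seed=13)
        mapping = assign_synapses(emb, lay, rng_seed=14)
        ang = np.arccos(np.clip(np.sum(lay.directions * pts[mapping], axis=1),
                                -1, 1))
        rand = np.arccos(np.clip(
            np.sum(lay.directions * pts[rng.permutation(mapping)], axis=1),
            -1, 1))
        assert ang.mean() < rand.mean() - 0.2

    def test_empty_embedding_rejected(self):
        lay = SynapseLayout.random(10, rng_seed=15)
        with pytest.raises(ValueError):
            assign_synapses(SphericalEmbedding(np.empty((0, 3)),
                                               np.empty((0, 0))), lay)


class TestMinimalModel:
    def test_independent_at_zero_rmax(self):
        lay = SynapseLayout.random(30, rng_seed=16)
        trains, B = minimal_correlated_trains(
            lay, MinimalModelParams(0.0), 20.0, 20.0, T=30.0, rng_seed=17,
            return_binary=True)
        C = np.corrcoef(B.astype(float).T)
        iu = np.triu_indices(lay.n, 1)
        assert np.abs(C[iu]).max() < 3.0 / np.sqrt(B.shape[0]) * 3

    def test_calibration_of_aligned_pair(self):
        """Two synapses at zero angular distance reach the target count
        correlation R_max."""
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1, 0, 0], [0, 1, 0.0]])
        lay = SynapseLayout(d, np.array([False, False, False, True]))
        trains, B = minimal_correlated_trains(
            lay, MinimalModelParams(0.3), 30.0, 30.0, T=100.0, rng_seed=18,
            return_binary=True)
        r = np.corrcoef(B[:, 0].astype(float), B[:, 1].astype(float))[0, 1]
        assert r == pytest.approx(0.3, abs=0.03)

    def test_kernel_decay_with_angle(self):
        rng = np.random.default_rng(19)
        lay = SynapseLayout.random(40, rng_seed=19)
        trains, B = minimal_correlated_trains(
            lay, MinimalModelParams(0.3), 25.0, 25.0, T=60.0, rng_seed=20,
            return_binary=True)
        C = np.corrcoef(B.astype(float).T)
        g = np.clip(lay.directions @ lay.directions.T, -1, 1)
        target = 0.3 * np.exp(-np.arccos(g))
        iu = np.triu_indices(lay.n, 1)
        err = C[iu] - target[iu]
        assert np.abs(err).mean() < 0.02

    def test_trains_white_in_time(self):
        lay = SynapseLayout.random(10, rng_seed=21)
        trains, B = minimal_correlated_trains(
            lay, MinimalModelParams(0.3), 40.0, 40.0, T=60.0, rng_seed=22,
            return_binary=True)
        x = B[:, 0].astype(float)
        x -= x.mean()
        ac = np.correlate(x, x, "full")[x.size - 1:x.size + 9] / (x @ x)
        assert np.abs(ac[1:]).max() < 0.02


class TestDyadCorrelation:
    def test_identical_input_and_layout_fully_correlated(self):
        lay = SynapseLayout.random(60, rng_seed=23)
        rng = np.random.default_rng(24)
        trains = [np.sort(rng.random(20) * 5000) for _ in range(lay.n)]
        from aperspectra.neuron import REFERENCE_PARAMS

        rho = dyad_dipole_correlation(REFERENCE_PARAMS, lay, lay, trains,
                                      trains, T=5.0, rng_seed=25)
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_flagged(self):
        lay = SynapseLayout.random(10, rng_seed=26)
        empty = [np.array([]) for _ in range(lay.n)]
        from aperspectra.neuron import REFERENCE_PARAMS

        with pytest.warns(UserWarning):
            rho = dyad_dipole_correlation(REFERENCE_PARAMS, lay, lay, empty,
                                          empty, T=1.0, rng_seed=27)
        assert np.isnan(rho)

    def test_minimal_model_monotone_in_rmax(self):
        rhos = [dyad_from_minimal_model(R, n_e=200, T=20.0, rng_seed=28)
                for R in (0.0, 0.1, 0.3)]
        assert rhos[0] < rhos[1] < rhos[2]
        assert rhos[2] > 0.3

    def test_minimal_model_shuffle_abolishes_correlation(self):
        rho = dyad_from_minimal_model(0.3, n_e=200, T=20.0, rng_seed=29)
        sh = [dyad_from_minimal_model(0.3, n_e=200, T=20.0, rng_seed=29 + k,
                                      shuffle=True) for k in range(6)]
        assert rho > 0.3
        assert abs(np.mean(sh)) < rho / 3

    def test_raster_dyad_and_optimality(self, subcritical_net_2000):
        """Subcritical input drives dyad correlation; degrading synapse
        placement (lower optimality index) lowers it monotonically;
        shuffling synapse locations destroys it."""
        r, _, emb = subcritical_net_2000
        means = {}
        for X in (1.0, 0.5, 0.25):
            means[X] = np.mean([dyad_from_raster(r, emb=emb, optimality=X,
                                                 rng_seed=600 + k)
                                for k in range(6)])
        shuf = np.mean([dyad_from_raster(r, emb=emb, shuffle=True,
                                         rng_seed=700 + k) for k in range(10)])
        assert means[1.0] > means[0.5] > means[0.25] > 0.0
        assert abs(shuf) < means[1.0] / 2
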