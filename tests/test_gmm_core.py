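import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from _oracles import random_mixture, riemann_inner_product
from shapesearch.errors import InfeasibleFitError
from shapesearch.gmm_core import (
    GaussianComponent,
    GaussianMixture,
    RigidTransform,
    fit_gmm,
    gmm_inner_product,
    gmm_overlap_cc,
    pairwise_cc_matrix,
    superpose_gmms,
    transform_mixture,
)
from shapesearch.synthetic_shapes import ShapeSpec, make_density
from shapesearch.volumes import DensityMap


def iso(weight, mean, sigma):
    return GaussianComponent(weight, mean, sigma**2 * np.eye(3))


class TestFitGmm:
    def test_k1_recovers_blob_moments(self, gaussian_blob_map):
        gmm = fit_gmm(gaussian_blob_map, K=1, seed=0)
        np.testing.assert_allclose(gmm.means[0], [3.0, -2.0, 0.0], atol=0.1)
        np.testing.assert_allclose(
            np.diag(gmm.covariances[0]), 36.0, rtol=0.05
        )

    def test_k1_mean_is_weighted_com(self, dumbbell_map):
        gmm = fit_gmm(dumbbell_map, K=1, seed=3)
        # K=1 EM: responsibilities are all 1, so the mean is the exact COM
        # of the (downsampled) voxel cloud -- compare against the full map
        # COM, which differs only by interpolation.
        com = (dumbbell_map.grid.ravel() @ dumbbell_map.voxel_centers()) / dumbbell_map.grid.sum()
        np.testing.assert_allclose(gmm.means[0], com, atol=0.05)

    def test_two_disjoint_blobs(self):
        ax = (np.arange(100) + 0.5) - 50.0
        xs, ys, zs = np.meshgrid(ax, ax, ax, indexing="ij")
        g = np.exp(-((xs - 20) ** 2 + ys**2 + zs**2) / (2 * 5.0**2))
        g += np.exp(-((xs + 20) ** 2 + ys**2 + zs**2) / (2 * 5.0**2))
        m = DensityMap(grid=g, origin=np.full(3, -50.0), name="two")
        gmm = fit_gmm(m, K=2, seed=1)
        w = np.sort(gmm.weights)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=0.02)
        x_means = np.sort(gmm.means[:, 0])
        np.testing.assert_allclose(x_means, [-20.0, 20.0], atol=0.5)

    def test_weights_sum_to_one(self, dumbbell_map):
        gmm = fit_gmm(dumbbell_map, K=4, seed=0)
        assert abs(gmm.weights.sum() - 1.0) < 1e-9

    def test_k_exceeding_voxels_rejected(self):
        g = np.zeros((8, 8, 8))
        g[4, 4, 4] = 1.0
        g[4, 4, 5] = 1.0
        with pytest.raises(InfeasibleFitError):
            fit_gmm(DensityMap(grid=g), K=5, seed=0)

    def test_determinism(self, dumbbell_map):
        a = fit_gmm(dumbbell_map, K=3, seed=7)
        b = fit_gmm(dumbbell_map, K=3, seed=7)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.covariances, b.covariances)


class TestInnerProduct:
    def test_coincident_unit_pair_closed_form(self):
        a = GaussianMixture([iso(1.0, [0, 0, 0], 1.0)])
        assert gmm_inner_product(a, a) == pytest.approx((4 * np.pi) ** -1.5, rel=1e-12)

    def test_separation_factor(self):
        a = GaussianMixture([iso(1.0, [0, 0, 0], 1.0)])
        for s in (1.0, 2.0, 3.5):
            b = GaussianMixture([iso(1.0, [s, 0, 0], 1.0)])
            expected = (4 * np.pi) ** -1.5 * np.exp(-(s**2) / 4.0)
            assert gmm_inner_product(a, b) == pytest.approx(expected, rel=1e-12)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(5)
        a, b = random_mixture(rng), random_mixture(rng)
        assert gmm_inner_product(a, b) == gmm_inner_product(b, a)

    def test_matches_quadrature(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a, b = random_mixture(rng), random_mixture(rng)
            exact = gmm_inner_product(a, b)
            approx = riemann_inner_product(a, b)
            assert abs(approx / exact - 1) <= 1e-6


class TestOverlapCC:
    def test_self_cc_is_one(self):
        rng = np.random.default_rng(2)
        a = random_mixture(rng)
        assert gmm_overlap_cc(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_pair_closed_form(self):
        sigma = 2.0
        a = GaussianMixture([iso(1.0, [0, 0, 0], sigma)])
        b = GaussianMixture([iso(1.0, [2 * sigma, 0, 0], sigma)])
        assert gmm_overlap_cc(a, b) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_monotone_decay_to_zero(self):
        a = GaussianMixture([iso(1.0, [0, 0, 0], 1.5)])
        prev = 1.0
        for s in (1.0, 3.0, 6.0, 12.0, 24.0):
            cc = gmm_overlap_cc(a, GaussianMixture([iso(1.0, [s, 0, 0], 1.5)]))
            assert cc < prev
            prev = cc
        assert prev < 1e-8

    def test_invariant_under_common_rigid_transform(self):
        rng = np.random.default_rng(9)
        a, b = random_mixture(rng), random_mixture(rng)
        t = RigidTransform.from_rotation(Rotation.random(random_state=rng), [4.0, -2.0, 7.0])
        cc0 = gmm_overlap_cc(a, b)
        cc1 = gmm_overlap_cc(transform_mixture(a, t), transform_mixture(b, t))
        assert abs(cc1 - cc0) < 1e-9


class TestSuperpose:
    def test_recovers_applied_transform(self):
        rng = np.random.default_rng(21)
        a = random_mixture(rng, k=4)
        applied = RigidTransform.from_rotation(
            Rotation.from_euler("z", 30, degrees=True), [5.0, -3.0, 2.0]
        )
        b = transform_mixture(a, applied.inverse())
        res = superpose_gmms(a, b, n_starts=8, seed=0)
        assert res.cc >= 0.999
        residual = res.transform.compose(applied.inverse())
        assert np.degrees(np.linalg.norm(residual.rotation.as_rotvec())) <= 1.0
        assert np.linalg.norm(residual.translation) <= 0.5

    def test_identity_for_equal_mixtures(self):
        rng = np.random.default_rng(3)
        a = random_mixture(rng)
        res = superpose_gmms(a, a, n_starts=4, seed=0)
        assert res.cc == pytest.approx(1.0, abs=1e-9)

    def test_mirror_image_not_reachable(self):
        # chiral 4-component shape; reflections are not searched
        comps = [
            iso(0.4, [0, 0, 0], 2.0),
            iso(0.3, [8, 0, 0], 2.0),
            iso(0.2, [0, 6, 0], 2.0),
            iso(0.1, [0, 0, 4], 2.0),
        ]
        a = GaussianMixture(comps)
        mirrored = GaussianMixture(
            [GaussianComponent(c.weight, c.mean * np.array([-1, 1, 1]), c.covariance) for c in comps]
        )
        res = superpose_gmms(a, mirrored, n_starts=12, seed=1)
        assert res.cc < 0.999

    def test_never_below_unaligned_cc(self):
        rng = np.random.default_rng(17)
        for _ in range(3):
            a, b = random_mixture(rng), random_mixture(rng)
            res = superpose_gmms(a, b, n_starts=4, seed=0)
            assert res.cc >= gmm_overlap_cc(a, b) - 1e-12


class TestPairwiseMatrix:
    def test_identical_mixtures_near_one(self):
        rng = np.random.default_rng(4)
        a = random_mixture(rng)
        M = pairwise_cc_matrix([a, a, a], seed=0, n_starts=4)
        assert (M >= 0.999).all()

    def test_diagonal_exactly_one(self):
        rng = np.random.default_rng(6)
        M = pairwise_cc_matrix([random_mixture(rng) for _ in range(3)], seed=0, n_starts=4)
        np.testing.assert_array_equal(np.diag(M), 1.0)
        np.testing.assert_array_equal(M, M.T)

    def test_shape_distortion_ordering(self):
        sphere = make_density(ShapeSpec("sphere", (16.0,), name="s"))
        ell = make_density(ShapeSpec("ellipsoid", (19.2, 16.0, 16.0), name="e"))
        rod = make_density(ShapeSpec("cylinder", (6.0, 60.0), name="r"))
        gs = [fit_gmm(m, K=4, seed=0) for m in (sphere, ell, rod)]
        M = pairwise_cc_matrix(gs, seed=0, n_starts=6)
        assert M[0, 2] < M[0, 1]  # sphere-rod < sphere-near-sphere


class TestSerialization:
    def test_table_roundtrip_exact(self, tmp_path):
        rng = np.random.default_rng(8)
        a = random_mixture(rng, k=4)
        a.to_table(tmp_path / "g.tsv")
        b = GaussianMixture.from_table(tmp_path / "g.tsv")
        np.testing.assert_allclose(b.weights, a.weights, atol=1e-12)
        np.testing.assert_allclose(b.means, a.means, atol=1e-12)
        np.testing.assert_allclose(b.covariances, a.covariances, atol=1e-12)

    def test_json_roundtrip_exact(self, tmp_path):
        rng = np.random.default_rng(8)
        a = random_mixture(rng, k=2)
        a.to_json(tmp_path / "g.json")
        b = GaussianMixture.from_json(tmp_path / "g.json")
        np.testing.assert_array_equal(b.weights, a.weights)
        np.testing.assert_array_equal(b.means, a.means)
        np.testing.assert_array_equal(b.covariances, a.covariances)

    def test_quaternion_normalized(self):
        t = RigidTransform(np.array([0.0, 0.0, 0.0, 2.0]))
        assert np.linalg.norm(t.quaternion) == pytest.approx(1.0, abs=1e-9)
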