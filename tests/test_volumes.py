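import numpy as np
import pytest
from scipy.stats import chi2

from shapesearch import mrcio
from shapesearch.errors import (
    DegenerateMapError,
    ImplausibleVolumeError,
    MapFormatError,
    NumericalDegeneracyError,
)
from shapesearch.gmm_core import GaussianComponent, GaussianMixture, fit_gmm
from shapesearch.synthetic_shapes import ShapeSpec, make_density
from shapesearch.volumes import (
    DensityMap,
    ResizeSpec,
    estimate_volume,
    load_density_map,
    normalize_grid,
    rescale_axis_dimension,
    resize_to_common_volume,
    save_density_map,
)


class TestMrcRoundtrip:
    def test_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = rng.random((10, 10, 10))
        path = tmp_path / "m.mrc"
        mrcio.write_mrc(path, grid, 1.0, origin=(1.0, 2.0, 3.0))
        back, spacing, origin = mrcio.read_mrc(path)
        np.testing.assert_allclose(back, grid.astype(np.float32), rtol=0, atol=0)
        np.testing.assert_allclose(spacing, 1.0)
        np.testing.assert_allclose(origin, [1.0, 2.0, 3.0])

    def test_negative_values_clamped_on_load(self, tmp_path):
        grid = np.full((5, 5, 5), 0.25)
        grid[2, 2, 2] = -0.5
        path = tmp_path / "neg.mrc"
        mrcio.write_mrc(path, grid, 1.0)
        dmap = load_density_map(path)
        assert dmap.grid[2, 2, 2] == 0.0
        assert dmap.grid.min() >= 0.0

    def test_anisotropic_spacing_recorded_and_resampled(self, tmp_path):
        # ellipsoidal blob on an anisotropic grid; downstream resample keeps mass
        ax = lambda n, s: (np.arange(n) + 0.5) * s - n * s / 2  # noqa: E731
        xs, ys, zs = np.meshgrid(ax(40, 2.0), ax(80, 1.0), ax(40, 1.5), indexing="ij")
        grid = np.exp(-(xs**2 + ys**2 + zs**2) / (2 * 8.0**2))
        path = tmp_path / "aniso.mrc"
        mrcio.write_mrc(path, grid, (2.0, 1.0, 1.5), origin=(-40, -40, -30))
        dmap = load_density_map(path)
        np.testing.assert_allclose(dmap.spacing, [2.0, 1.0, 1.5])
        norm = normalize_grid(dmap)
        assert norm.grid.shape == (100, 100, 100)
        assert abs(norm.total_mass / dmap.total_mass - 1) <= 0.01

    def test_truncated_header_names_problem(self, tmp_path):
        path = tmp_path / "trunc.mrc"
        path.write_bytes(b"\x00" * 100)
        with pytest.raises(MapFormatError, match="truncated header"):
            mrcio.read_mrc(path)

    def test_truncated_data_reported(self, tmp_path):
        path = tmp_path / "short.mrc"
        mrcio.write_mrc(path, np.ones((6, 6, 6)), 1.0)
        raw = path.read_bytes()
        path.write_bytes(raw[:-40])
        with pytest.raises(MapFormatError, match="data section"):
            mrcio.read_mrc(path)

    def test_bad_mode_named(self, tmp_path):
        path = tmp_path / "mode.mrc"
        mrcio.write_mrc(path, np.ones((4, 4, 4)), 1.0)
        raw = bytearray(path.read_bytes())
        raw[12:16] = (99).to_bytes(4, "little")
        path.write_bytes(bytes(raw))
        with pytest.raises(MapFormatError, match="mode"):
            mrcio.read_mrc(path)

    def test_density_map_roundtrip_via_api(self, tmp_path):
        m = make_density(ShapeSpec("sphere", (12.0,), name="s"))
        save_density_map(m, tmp_path / "s.mrc")
        back = load_density_map(tmp_path / "s.mrc", name="s")
        np.testing.assert_allclose(back.grid, m.grid, atol=1e-6)


class TestNormalizeGrid:
    def test_identity_on_canonical_grid(self, dumbbell_map):
        out = normalize_grid(dumbbell_map)
        np.testing.assert_allclose(out.grid, dumbbell_map.grid, atol=1e-9)

    def test_upsample_50_at_2A_preserves_mass(self):
        ax = (np.arange(50) + 0.5) * 2.0 - 50.0
        xs, ys, zs = np.meshgrid(ax, ax, ax, indexing="ij")
        grid = np.exp(-(xs**2 + ys**2 + zs**2) / (2 * 10.0**2))
        m = DensityMap(grid=grid, spacing=np.full(3, 2.0), origin=np.full(3, -50.0))
        out = normalize_grid(m)
        assert out.grid.shape == (100, 100, 100)
        np.testing.assert_allclose(out.spacing, 1.0)
        assert 0.99 <= out.total_mass / m.total_mass <= 1.01

    def test_sphere_radius_preserved(self):
        m = make_density(ShapeSpec("sphere", (20.0,), name="s20"), box=50, spacing=2.0)
        out = normalize_grid(m)

        def halfmax_radius(dm):
            half = dm.grid.max() / 2.0
            centers = dm.voxel_centers() - (dm.origin + np.asarray(dm.grid.shape) * dm.spacing / 2)
            r = np.linalg.norm(centers, axis=1)
            return r[dm.grid.ravel() >= half].max()

        assert abs(halfmax_radius(out) - halfmax_radius(m)) <= 1.0

    def test_zero_mass_rejected(self):
        m = DensityMap(grid=np.zeros((10, 10, 10)))
        with pytest.raises(DegenerateMapError):
            normalize_grid(m)


class TestRescaleAxisDimension:
    @pytest.mark.parametrize(
        "v_old,expected",
        [(125000.0, 100.0), (1_000_000.0, 50.0), (8000.0, 250.0)],
    )
    def test_formula(self, v_old, expected):
        spec = ResizeSpec(v_old=v_old, d_old=100.0, d_ref=50.0)
        assert rescale_axis_dimension(spec) == pytest.approx(expected)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            ResizeSpec(v_old=0.0)


class TestResizeToCommonVolume:
    def test_near_identity_when_already_at_target(self):
        # a shape whose 95%-mass volume is already ~50^3
        m = make_density(ShapeSpec("sphere", (28.0,), soft_edge=2.0, name="s28"))
        gmm = fit_gmm(normalize_grid(m), K=5, seed=0)
        v_old = estimate_volume(gmm)
        out = resize_to_common_volume(normalize_grid(m), v_old)
        v_new = estimate_volume(fit_gmm(out, K=5, seed=0))
        assert 0.9 * 50**3 <= v_new <= 1.1 * 50**3

    def test_sphere_halfmax_radii_match(self, resized_spheres):
        radii = {}
        for r, d in resized_spheres.items():
            dm = d["resized"]
            half = dm.grid.max() / 2.0
            centers = dm.voxel_centers()
            rr = np.linalg.norm(centers, axis=1)
            radii[r] = rr[dm.grid.ravel() >= half].max()
        assert abs(radii[10] - radii[20]) <= 1.0

    def test_mass_preserved(self, dumbbell_map):
        norm = normalize_grid(dumbbell_map)
        out = resize_to_common_volume(norm, v_old=60.0**3)
        assert abs(out.total_mass / norm.total_mass - 1) <= 0.01

    def test_implausible_volume_rejected(self, dumbbell_map):
        with pytest.raises(ImplausibleVolumeError):
            resize_to_common_volume(normalize_grid(dumbbell_map), v_old=10.0**3)

    def test_pipeline_volume_invariant_and_idempotence(self, resized_spheres):
        for d in resized_spheres.values():
            v1 = estimate_volume(d["gmm"])
            assert 0.9 * 50**3 <= v1 <= 1.1 * 50**3
            twice = resize_to_common_volume(d["resized"], v1)
            v2 = estimate_volume(fit_gmm(twice, K=5, seed=0))
            assert abs(v2 / v1 - 1) < 0.02


class TestEstimateVolume:
    def test_single_isotropic_closed_form(self):
        sigma = 5.0
        gmm = GaussianMixture([GaussianComponent(1.0, [0, 0, 0], sigma**2 * np.eye(3))])
        r = sigma * np.sqrt(chi2.ppf(0.95, df=3))  # ~2.80 sigma
        expected = 4.0 / 3.0 * np.pi * r**3
        assert estimate_volume(gmm, 0.95) == pytest.approx(expected, rel=0.05)

    def test_doubling_sigma_scales_volume_8x(self):
        g1 = GaussianMixture([GaussianComponent(1.0, [0, 0, 0], 9.0 * np.eye(3))])
        g2 = GaussianMixture([GaussianComponent(1.0, [0, 0, 0], 36.0 * np.eye(3))])
        assert estimate_volume(g2) == pytest.approx(8 * estimate_volume(g1), rel=0.05)

    def test_disjoint_components_additive(self):
        one = GaussianMixture([GaussianComponent(1.0, [0, 0, 0], 9.0 * np.eye(3))])
        two = GaussianMixture(
            [
                GaussianComponent(0.5, [0, 0, 0], 9.0 * np.eye(3)),
                GaussianComponent(0.5, [60.0, 0, 0], 9.0 * np.eye(3)),
            ]
        )
        assert estimate_volume(two) == pytest.approx(2 * estimate_volume(one), rel=0.05)

    def test_singular_covariance_rejected(self):
        gmm = GaussianMixture.__new__(GaussianMixture)
        gmm.weights = np.array([1.0])
        gmm.means = np.zeros((1, 3))
        gmm.covariances = np.zeros((1, 3, 3))
        gmm.name = "bad"
        with pytest.raises(NumericalDegeneracyError):
            estimate_volume(gmm)

    def test_bad_mass_fraction(self):
        gmm = GaussianMixture([GaussianComponent(1.0, [0, 0, 0], np.eye(3))])
        with pytest.raises(ValueError):
            estimate_volume(gmm, mass_fraction=1.5)
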