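"""Surface detection, distance volumes and band extraction.

The distance transform is checked against an exhaustive brute-force
oracle (minimum Euclidean distance over all surface points) and the band
selection against per-voxel enumeration.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epiredox.io import ChannelName, DEFAULT_CHANNELS, ImageStack
from epiredox.surfaces import (
    BandDirection,
    HeightMap,
    LayerBand,
    SurfaceReference,
    air_surface,
    collagen_mask,
    dermis_surface,
    distance_to_surface,
    extract_band,
)
from epiredox.synthetic import NoiseModel, RedoxModel, TissueModel, generate_stack

from conftest import flat_stack


def brute_force_distance(shape, voxel_size, height):
    """Oracle: signed min-Euclidean distance over every surface point."""
    nz, ny, nx = shape
    dz, dy, dx = voxel_size
    pts = np.array(
        [[height[y, x], y * dy, x * dx] for y in range(ny) for x in range(nx)]
    )
    out = np.empty(shape)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = np.array([z * dz, y * dy, x * dx])
                d = np.sqrt(((pts - v) ** 2).sum(axis=1)).min()
                out[z, y, x] = d if z * dz <= height[y, x] else -d
    return out


class TestCollagenMask:
    def test_fixed_threshold_recovers_interface_region(self):
        stack = flat_stack(depth_um=10.0, shg_value=100.0)
        mask = collagen_mask(stack, method="fixed", fixed_threshold=50.0)
        zs = np.arange(stack.shape_zyx[0]) * 0.5
        expected = np.broadcast_to((zs >= 10.0)[:, None, None], mask.shape)
        np.testing.assert_array_equal(mask, expected)

    def test_constant_channel_otsu_raises(self):
        stack = flat_stack()
        stack.voxels[1] = 7.0  # constant SHG
        with pytest.raises(ValueError, match="fixed"):
            collagen_mask(stack, method="otsu")

    def test_missing_shg_channel(self):
        voxels = np.ones((1, 4, 4, 4), dtype=np.float32)
        stack = ImageStack(voxels, (0.5, 0.5, 0.5),
                           [DEFAULT_CHANNELS[ChannelName.NADPH]])
        with pytest.raises(ValueError, match="SHG"):
            collagen_mask(stack)

    def test_noisy_stack_mask_jaccard(self, noisy_mosaic):
        stack, truth = noisy_mosaic
        mask = collagen_mask(stack)
        dz = stack.voxel_size_um[0]
        zs = np.arange(stack.shape_zyx[0])[:, None, None] * dz
        truth_region = zs >= truth.interface.depth_um[None]
        jaccard = (mask & truth_region).sum() / (mask | truth_region).sum()
        assert jaccard >= 0.95


class TestDermisSurface:
    def test_flat_interface_exact(self):
        stack = flat_stack(depth_um=10.0, dz=0.5)
        mask = collagen_mask(stack, method="fixed", fixed_threshold=50.0)
        surface = dermis_surface(mask, stack.voxel_size_um)
        np.testing.assert_allclose(surface.depth_um, 10.0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            dermis_surface(np.zeros((4, 4, 4), dtype=bool), (0.5, 0.5, 0.5))

    def test_sinusoid_rmse_below_dz(self):
        # analytic sinusoidal interface, mean 20 um amplitude 5 um
        dz, d_lat = 0.5, 1.0
        ny = nx = 64
        ys, xs = np.arange(ny) * d_lat, np.arange(nx) * d_lat
        gy, gx = np.meshgrid(ys, xs, indexing="ij")
        height = 20.0 + 5.0 * np.sin(2 * np.pi * gy / 32.0) * np.sin(2 * np.pi * gx / 32.0)
        nz = 60
        zs = np.arange(nz)[:, None, None] * dz
        mask = zs >= height[None]
        surface = dermis_surface(mask, (dz, d_lat, d_lat))
        rmse = np.sqrt(np.mean((surface.depth_um - height) ** 2))
        assert rmse <= dz

    def test_majority_missing_raises(self):
        mask = np.zeros((4, 10, 10), dtype=bool)
        mask[2, :2, :] = True  # 20% of columns defined
        with pytest.raises(ValueError, match="not detectable"):
            dermis_surface(mask, (0.5, 0.5, 0.5))

    def test_translation_equivariance(self):
        """Shifting the stack one z-slice shifts detected depths by dz."""
        dz = 0.5
        rng = np.random.default_rng(4)
        height = 6.0 + rng.uniform(-1, 1, (12, 12))
        zs = np.arange(24)[:, None, None] * dz
        mask = zs >= height[None]
        shifted = np.zeros_like(mask)
        shifted[1:] = mask[:-1]
        s0 = dermis_surface(mask, (dz, 0.5, 0.5), median_window=0)
        s1 = dermis_surface(shifted, (dz, 0.5, 0.5), median_window=0)
        np.testing.assert_allclose(s1.depth_um - s0.depth_um, dz)


class TestAirSurface:
    def test_flat_tissue_start(self):
        voxels = np.zeros((1, 12, 6, 6), dtype=np.float32)
        zs = np.arange(12) * 0.5
        voxels[0, zs >= 2.0] = 1.0
        stack = ImageStack(voxels, (0.5, 0.5, 0.5),
                           [DEFAULT_CHANNELS[ChannelName.MCHERRY]])
        surface = air_surface(stack)
        np.testing.assert_allclose(surface.depth_um, 2.0)

    def test_all_zero_channel_raises(self):
        voxels = np.zeros((1, 6, 4, 4), dtype=np.float32)
        stack = ImageStack(voxels, (0.5, 0.5, 0.5),
                           [DEFAULT_CHANNELS[ChannelName.MCHERRY]])
        with pytest.raises(ValueError, match="all zero"):
            air_surface(stack)

    def test_planted_cornified_undulation(self):
        tissue = TissueModel(
            field_um=(40.0, 40.0), n_basal_cells=25,
            interface_mean_depth_um=14.0, interface_amplitude_um=1.0,
            interface_wavelength_um=20.0, air_depth_um=3.0,
            air_amplitude_um=1.0, suprabasal_layers=0,
        )
        stack, truth = generate_stack(
            tissue, RedoxModel(noise_model=NoiseModel(0, 0)), seed=5
        )
        surface = air_surface(stack)
        rmse = np.sqrt(np.nanmean((surface.depth_um - truth.air.depth_um) ** 2))
        assert rmse <= stack.voxel_size_um[0]


class TestDistanceToSurface:
    def test_flat_surface_vertical_case(self):
        height = np.full((4, 4), 10.0)
        dist = distance_to_surface((30, 4, 4), (0.5, 0.5, 0.5),
                                   HeightMap(height, (0.5, 0.5)))
        # voxel at depth 7 um -> +3 um; at 12 um -> -2 um
        assert dist[14, 2, 2] == pytest.approx(3.0)
        assert dist[24, 2, 2] == pytest.approx(-2.0)

    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(7)
        for trial in range(4):
            shape = (6, 6, 6)
            voxel = (0.7, 0.4, 0.5)
            height = rng.uniform(0.5, 3.5, shape[1:])
            dist = distance_to_surface(shape, voxel, HeightMap(height, voxel[1:]))
            oracle = brute_force_distance(shape, voxel, height)
            np.testing.assert_allclose(dist, oracle, atol=1e-9)

    def test_steep_step_never_exceeds_vertical(self):
        height = np.full((8, 8), 2.0)
        height[:, 4:] = 6.0  # steep step
        hm = HeightMap(height, (0.5, 0.5))
        shape = (16, 8, 8)
        dist = distance_to_surface(shape, (0.5, 0.5, 0.5), hm)
        vertical = distance_to_surface(shape, (0.5, 0.5, 0.5), hm, mode="vertical")
        assert np.all(np.abs(dist) <= np.abs(vertical) + 1e-12)

    def test_missing_columns_are_interpolated(self):
        height = np.full((6, 6), 4.0)
        height[2, 2] = np.nan
        dist = distance_to_surface((10, 6, 6), (0.5, 0.5, 0.5),
                                   HeightMap(height, (0.5, 0.5)))
        assert np.isfinite(dist).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 1_000_000))
    def test_brute_force_property(self, seed):
        rng = np.random.default_rng(seed)
        shape = (4, 3, 3)
        voxel = tuple(rng.uniform(0.3, 1.0, 3))
        height = rng.uniform(0.2, 2.5, shape[1:])
        dist = distance_to_surface(shape, voxel, HeightMap(height, voxel[1:]))
        oracle = brute_force_distance(shape, voxel, height)
        np.testing.assert_allclose(dist, oracle, atol=1e-9)


class TestExtractBand:
    def _flat(self):
        stack = flat_stack(depth_um=10.0, dz=0.5, n_z=26)
        hm = HeightMap(np.full((8, 8), 10.0), (0.5, 0.5))
        dist = distance_to_surface(stack.shape_zyx, stack.voxel_size_um, hm)
        return stack, dist

    def test_flat_band_contributing_slices(self):
        """Band [0, 3] um above a flat 10 um surface at dz 0.5: exactly the
        7 slices at depths 7.0-10.0 um contribute (brute-force check)."""
        stack, dist = self._flat()
        band = LayerBand(SurfaceReference.DERMIS_SURFACE, 0.0, 3.0)
        proj = extract_band(stack, dist, band, method="mean")
        assert np.all(proj.n_voxels_map == 7)
        # brute-force voxel enumeration
        zs = np.arange(stack.shape_zyx[0]) * 0.5
        included = [z for z in zs if 0.0 <= 10.0 - z <= 3.0]
        assert included == [7.0, 7.5, 8.0, 8.5, 9.0, 9.5, 10.0]

    def test_epsilon_band_selects_interface_slice_only(self):
        stack, dist = self._flat()
        band = LayerBand(SurfaceReference.DERMIS_SURFACE, 0.0, 0.25)
        proj = extract_band(stack, dist, band)
        assert np.all(proj.n_voxels_map == 1)

    def test_band_outside_stack_raises(self):
        stack, dist = self._flat()
        band = LayerBand(SurfaceReference.DERMIS_SURFACE, 100.0, 120.0)
        with pytest.raises(ValueError, match="outside"):
            extract_band(stack, dist, band)

    def test_band_nesting(self):
        """Band [0, a] voxel sets are nested in [0, b] for a <= b."""
        stack, dist = self._flat()
        n_prev = None
        for upper in (1.0, 2.0, 3.0, 5.0):
            band = LayerBand(SurfaceReference.DERMIS_SURFACE, 0.0, upper)
            proj = extract_band(stack, dist, band)
            n = proj.n_voxels_map.sum()
            if n_prev is not None:
                assert n >= n_prev
            n_prev = n

    def test_nuclear_band_contains_all_basal_centroids(self, noise_free_mosaic):
        """Noise-free stack: every basal nucleus centroid falls inside the
        0-5 um nuclear band; none in the suprabasal region."""
        stack, truth = noise_free_mosaic
        mask = collagen_mask(stack)
        surf = dermis_surface(mask, stack.voxel_size_um)
        dist = distance_to_surface(stack.shape_zyx, stack.voxel_size_um, surf)
        dz, dy, dx = stack.voxel_size_um
        for _, cell in truth.cells.iterrows():
            iz = int(round(cell.depth_um / dz))
            iy = int(round(cell.y_um / dy))
            ix = int(round(cell.x_um / dx))
            assert 0.0 <= dist[iz, iy, ix] <= 5.0
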