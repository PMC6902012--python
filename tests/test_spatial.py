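import numpy as np
import pytest

from normcomp import (
    DeformationField,
    GridSpec,
    ScalarMap,
    SeedROI,
    SimulationParams,
    compute_alff,
    compute_tsnr,
    constant_map,
    generate_constant_tsnr_image,
    generate_deformation,
    inverse_map_roi,
    sphere_voxels,
    warp_timeseries,
    warp_volume,
)


def translation_field(grid, offset_mm):
    """Pure translation: every output voxel samples source at +offset."""
    disp = np.tile(np.asarray(offset_mm, float), tuple(grid.shape) + (1,))
    inv = np.tile(-np.asarray(offset_mm, float), tuple(grid.shape) + (1,))
    return DeformationField(disp, grid, inv)


def brute_force_trilinear(data, mask, coords):
    """Naive per-point 8-corner weighted sum; the oracle for the resampler."""
    out = np.empty(coords.shape[1])
    support = np.empty(coords.shape[1])
    shape = data.shape
    for i in range(coords.shape[1]):
        x, y, z = coords[:, i]
        fx, fy, fz = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
        tx, ty, tz = x - fx, y - fy, z - fz
        val = 0.0
        sup = 0.0
        for dx, wx in ((0, 1 - tx), (1, tx)):
            for dy, wy in ((0, 1 - ty), (1, ty)):
                for dz, wz in ((0, 1 - tz), (1, tz)):
                    w = wx * wy * wz
                    if w == 0.0:
                        continue
                    cx, cy, cz = fx + dx, fy + dy, fz + dz
                    if 0 <= cx < shape[0] and 0 <= cy < shape[1] and 0 <= cz < shape[2]:
                        val += w * data[cx, cy, cz]
                        sup += w * mask[cx, cy, cz]
        out[i] = val
        support[i] = sup
    return out, support


class TestWarpVolume:
    def test_matches_brute_force_oracle(self):
        grid = GridSpec.from_shape((5, 5, 5))
        rng = np.random.default_rng(1)
        data = rng.normal(size=grid.shape)
        mask = np.ones(grid.shape, bool)
        field = generate_deformation(grid, 2.0, 12.0, rng_seed=2, invert=False)
        warped = warp_volume(ScalarMap(data, grid, mask), field, "trilinear")

        out_world = grid.voxel_centers_world() + field.displacement
        coords = grid.world_to_voxel(out_world).reshape(-1, 3).T
        expected, support = brute_force_trilinear(data, mask, coords)
        expected = expected.reshape(grid.shape)
        valid = (support > 1 - 1e-9).reshape(grid.shape)
        assert np.array_equal(warped.mask, valid)
        assert np.allclose(warped.data[valid], expected[valid], atol=1e-12)

    @pytest.mark.parametrize("kind", ["trilinear", "nearest"])
    def test_constant_map_preserved(self, desk_grid, smooth_field, kind):
        warped = warp_volume(constant_map(desk_grid, 100.0), smooth_field, kind)
        assert warped.mask.sum() > 1000
        assert np.allclose(warped.valid_values(), 100.0, rtol=1e-12)

    def test_identity_field_is_bit_exact(self, desk_grid):
        rng = np.random.default_rng(3)
        data = rng.normal(size=desk_grid.shape)
        m = ScalarMap(data, desk_grid, np.ones(desk_grid.shape, bool))
        identity = translation_field(desk_grid, (0.0, 0.0, 0.0))
        warped = warp_volume(m, identity, "trilinear")
        assert np.array_equal(warped.data, data)

    def test_out_of_mask_support_invalidates(self, desk_grid, desk_mask):
        m = constant_map(desk_grid, 1.0, desk_mask)
        field = translation_field(desk_grid, (3.0, 0.0, 0.0))
        warped = warp_volume(m, field, "trilinear")
        # voxels sampling across the mask edge must be invalid, not blended
        assert warped.mask.sum() < desk_mask.sum()
        assert np.allclose(warped.valid_values(), 1.0)

    def test_variance_reduction_for_iid_noise(self, desk_grid, smooth_field):
        """Trilinear output variance never exceeds input variance for white noise."""
        img = generate_constant_tsnr_image(SimulationParams(rng_seed=5), desk_grid)
        warped = warp_timeseries(img, smooth_field, "trilinear")
        var_out = warped.data[warped.mask].var(axis=1, ddof=1)
        assert np.all(var_out <= 100.0 + 1e-6)  # input SD 10 => variance 100


class TestWarpTimeseries:
    def test_equals_per_volume_loop(self):
        grid = GridSpec.from_shape((4, 4, 4))
        rng = np.random.default_rng(4)
        from normcomp.images import TimeSeriesImage

        img = TimeSeriesImage(
            rng.normal(size=tuple(grid.shape) + (10,)), grid, 2.0,
            np.ones(grid.shape, bool),
        )
        field = generate_deformation(grid, 1.5, 12.0, rng_seed=5, invert=False)
        warped = warp_timeseries(img, field, "trilinear")
        for t in range(10):
            vol = ScalarMap(img.data[..., t], grid, img.mask)
            wv = warp_volume(vol, field, "trilinear")
            assert np.array_equal(warped.data[..., t], wv.data)
            assert np.array_equal(warped.mask, wv.mask)
        assert warped.tr == img.tr

    def test_nearest_neighbour_commutes_with_voxelwise_features(
        self, default_image, smooth_field
    ):
        """warp o tSNR == tSNR o warp (and likewise ALFF) under nearest neighbour."""
        warped_first = compute_tsnr(warp_timeseries(default_image, smooth_field, "nearest"))
        warped_last = warp_volume(compute_tsnr(default_image), smooth_field, "nearest")
        assert np.array_equal(warped_first.mask, warped_last.mask)
        assert np.array_equal(
            warped_first.data[warped_first.mask], warped_last.data[warped_last.mask]
        )
        a = compute_alff(warp_timeseries(default_image, smooth_field, "nearest"))
        b = warp_volume(compute_alff(default_image), smooth_field, "nearest")
        common = a.mask & b.mask
        assert np.array_equal(a.data[common], b.data[common])

    def test_half_voxel_shift_variance_factor(self):
        """A half-voxel translation on all axes averages 8 i.i.d. corners with
        weight 1/8 each: variance shrinks by 1/8 and tSNR grows by sqrt(8)."""
        grid = GridSpec.from_shape((8, 8, 8))
        n_t = 10_000
        rng = np.random.default_rng(6)
        from normcomp.images import TimeSeriesImage

        img = TimeSeriesImage(
            1000.0 + 10.0 * rng.standard_normal(tuple(grid.shape) + (n_t,)),
            grid, 2.0, np.ones(grid.shape, bool),
        )
        field = translation_field(grid, (1.5, 1.5, 1.5))  # half of a 3 mm voxel
        warped = warp_timeseries(img, field, "trilinear")
        ratio = (
            warped.data[warped.mask].var(axis=1, ddof=1)
            / img.data[warped.mask].var(axis=1, ddof=1)
        )
        assert ratio.mean() == pytest.approx(1.0 / 8.0, rel=0.02)
        tsnr_in = compute_tsnr(img)
        tsnr_out = compute_tsnr(warped)
        tsnr_ratio = tsnr_out.data[warped.mask] / tsnr_in.data[warped.mask]
        assert tsnr_ratio.mean() == pytest.approx(np.sqrt(8.0), rel=0.02)

    def test_uniform_offset_expected_variance_factor(self):
        """Random sub-voxel translations: E[variance factor] = (2/3)^3.

        Per axis the trilinear factor is (1-t)^2 + t^2 with t ~ U(0,1), whose
        mean is 2/3; axes are independent, so the product has mean (2/3)^3.
        """
        grid = GridSpec.from_shape((6, 6, 6))
        n_t = 2000
        rng = np.random.default_rng(7)
        from normcomp.images import TimeSeriesImage

        ratios = []
        for _ in range(40):
            offset = rng.uniform(0.0, 3.0, size=3)
            img = TimeSeriesImage(
                rng.standard_normal(tuple(grid.shape) + (n_t,)),
                grid, 2.0, np.ones(grid.shape, bool),
            )
            field = translation_field(grid, tuple(offset))
            warped = warp_timeseries(img, field, "trilinear")
            ratios.append(
                (warped.data[warped.mask].var(axis=1, ddof=1)
                 / img.data[warped.mask].var(axis=1, ddof=1)).mean()
            )
        ratios = np.asarray(ratios)
        expected = (2.0 / 3.0) ** 3
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - expected) < max(3 * se, 0.01)


class TestInverseMapRoi:
    def test_identity_field_returns_standard_sphere(self, desk_grid):
        roi = SeedROI((-6.0, -18.0, 12.0), 6.0)
        field = translation_field(desk_grid, (0.0, 0.0, 0.0))
        got = inverse_map_roi(roi, field)
        expected = sphere_voxels(desk_grid, roi)
        assert np.array_equal(np.sort(got, axis=0), np.sort(expected, axis=0))

    def test_translation_field_shifts_sphere(self, desk_grid):
        roi = SeedROI((-6.0, -18.0, 12.0), 6.0)
        field = translation_field(desk_grid, (3.0, 0.0, 0.0))
        got = inverse_map_roi(roi, field)
        # native voxel y maps to standard at y - 3mm (inverse of +3), so the
        # native sphere sits at center + 3mm = one voxel along x
        expected = sphere_voxels(desk_grid, SeedROI((-3.0, -18.0, 12.0), 6.0))
        assert np.array_equal(np.sort(got, axis=0), np.sort(expected, axis=0))

    def test_agrees_with_exhaustive_oracle(self, desk_grid, smooth_field):
        roi = SeedROI((-6.0, -18.0, 12.0), 6.0)
        got = {tuple(v) for v in inverse_map_roi(roi, smooth_field)}
        centers = desk_grid.voxel_centers_world()
        expected = set()
        # voxel centers are lattice nodes, where interpolating the inverse
        # field reduces to reading it directly - an independent per-voxel loop
        for idx in np.ndindex(*desk_grid.shape):
            mapped = centers[idx] + smooth_field.inverse_displacement[idx]
            if np.linalg.norm(mapped - np.asarray(roi.center)) <= roi.radius:
                expected.add(idx)
        assert got == expected

    def test_empty_result_raises(self, desk_grid):
        # a huge translation pushes the sphere far outside the native box
        field = translation_field(desk_grid, (500.0, 0.0, 0.0))
        with pytest.raises(RuntimeError, match="no native voxels"):
            inverse_map_roi(SeedROI((-6.0, -18.0, 12.0), 6.0), field)
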