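import numpy as np
import pytest
from scipy.stats import rankdata

from normcomp import (
    BandSpec,
    GridSpec,
    ScalarMap,
    SimulationParams,
    bandpass,
    compute_alff,
    compute_dmn_mask,
    compute_fc,
    compute_reho,
    compute_tsnr,
    generate_constant_tsnr_image,
    kendalls_w,
    regress_confounds,
)
from normcomp.images import TimeSeriesImage
from normcomp.stats import CohortMaps


def make_image(data, tr=2.0, mask=None):
    data = np.asarray(data, dtype=float)
    grid = GridSpec.from_shape(data.shape[:3])
    if mask is None:
        mask = np.ones(data.shape[:3], bool)
    return TimeSeriesImage(data, grid, tr, mask)


class TestRegressConfounds:
    def test_no_regressors_is_identity(self):
        rng = np.random.default_rng(0)
        img = make_image(rng.normal(size=(3, 3, 3, 40)))
        out = regress_confounds(img, None, include_linear_trend=False)
        assert np.array_equal(out.data, img.data)

    def test_perfect_fit_leaves_constant(self):
        rng = np.random.default_rng(1)
        conf = rng.normal(size=(50, 1))
        data = np.zeros((2, 2, 2, 50))
        data[0, 0, 0] = conf[:, 0] + 1000.0
        out = regress_confounds(make_image(data), conf)
        assert np.allclose(out.data[0, 0, 0], 1000.0, atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        n_t = 50
        conf = rng.normal(size=(n_t, 3))
        data = 1000.0 + rng.normal(size=(3, 3, 3, n_t))
        out = regress_confounds(make_image(data), conf, include_linear_trend=True)

        x = np.column_stack(
            [np.ones(n_t), conf, np.linspace(-1, 1, n_t)]
        )
        xtx_inv = np.linalg.inv(x.T @ x)
        for idx in [(0, 0, 0), (1, 2, 0), (2, 2, 2)]:
            y = data[idx]
            beta = xtx_inv @ (x.T @ y)
            expected = y - x @ beta + beta[0]
            assert np.allclose(out.data[idx], expected, atol=1e-8)
            resid = out.data[idx] - beta[0]
            assert np.max(np.abs(x.T @ resid)) < 1e-7  # orthogonality

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(40, 1))
        conf = np.hstack([base, 2.0 * base])
        img = make_image(1000.0 + rng.normal(size=(2, 2, 2, 40)))
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_confounds(img, conf)
        single = regress_confounds(img, base)
        assert np.allclose(out.data, single.data, atol=1e-10)

    def test_row_mismatch_rejected(self):
        img = make_image(np.zeros((2, 2, 2, 30)) + 1.0)
        with pytest.raises(ValueError, match="rows"):
            regress_confounds(img, np.zeros((20, 2)))


class TestBandpass:
    def test_in_band_sinusoid_is_eigenfunction(self):
        n_t, tr = 190, 2.0
        t = np.arange(n_t)
        freq = 10.0 / (n_t * tr)  # an exact DFT bin inside 0.01-0.08 Hz
        sig = np.sin(2 * np.pi * freq * t * tr)
        img = make_image(np.broadcast_to(sig, (2, 2, 2, n_t)).copy())
        out = bandpass(img)
        assert np.max(np.abs(out.data - img.data)) < 1e-9 * np.max(np.abs(sig))

    def test_out_of_band_sinusoid_removed(self):
        n_t, tr = 190, 2.0
        t = np.arange(n_t)
        sig = np.cos(2 * np.pi * 0.2 * t * tr)  # bin 76, far above 0.08 Hz
        img = make_image(np.broadcast_to(sig, (2, 2, 2, n_t)).copy())
        out = bandpass(img)
        assert np.linalg.norm(out.data[0, 0, 0]) < 1e-9 * np.linalg.norm(sig)

    def test_dc_retained(self):
        img = make_image(np.full((2, 2, 2, 190), 7.5) + 0.0)
        out = bandpass(img)
        assert np.allclose(out.data, 7.5, atol=1e-9)

    def test_white_noise_variance_matches_parseval(self):
        """Ideal filtering keeps the in-band share of spectral energy."""
        n_t, tr = 190, 2.0
        rng = np.random.default_rng(4)
        img = make_image(rng.standard_normal((6, 6, 6, n_t)))
        out = bandpass(img)
        keep = BandSpec().bins(n_t, tr)
        expected = 2.0 * keep.sum() / (n_t - 1)  # complex bins count twice
        ratios = out.data.var(axis=3, ddof=1) / img.data.var(axis=3, ddof=1)
        se = ratios.std(ddof=1) / np.sqrt(ratios.size)
        assert abs(ratios.mean() - expected) < 4 * se

    def test_invalid_band_rejected(self):
        img = make_image(np.ones((2, 2, 2, 20)))
        with pytest.raises(ValueError):
            bandpass(img, BandSpec(0.08, 0.01))
        with pytest.raises(ValueError):
            bandpass(img, BandSpec(0.01, 0.5))  # above Nyquist for TR 2


class TestTsnr:
    def test_generator_default_voxel_is_100(self, default_image):
        tsnr = compute_tsnr(default_image)
        assert np.allclose(tsnr.valid_values(), 100.0, rtol=1e-9)

    def test_constant_series_masked(self):
        data = np.ones((2, 2, 2, 10))
        data[0, 0, 0] += np.arange(10) * 0.1
        tsnr = compute_tsnr(make_image(data))
        assert tsnr.mask[0, 0, 0]
        assert not tsnr.mask[1, 1, 1]

    def test_two_point_closed_form(self):
        data = np.zeros((1, 1, 1, 2))
        data[0, 0, 0] = [998.0, 1002.0]
        tsnr = compute_tsnr(make_image(data))
        assert tsnr.data[0, 0, 0] == pytest.approx(1000.0 / (2.0 * np.sqrt(2.0)), rel=1e-12)


class TestAlff:
    def test_single_bin_sinusoid_closed_form(self):
        n_t, tr = 190, 2.0
        band = BandSpec()
        k = 10
        amp = 3.7
        t = np.arange(n_t)
        sig = 1000.0 + amp * np.sin(2 * np.pi * k * t / n_t)
        img = make_image(np.broadcast_to(sig, (2, 2, 2, n_t)).copy(), tr=tr)
        n_band_bins = int(band.bins(n_t, tr).sum())
        alff = compute_alff(img, band)
        assert np.allclose(alff.valid_values(), amp / n_band_bins, rtol=1e-9)

    def test_zero_series_gives_zero(self):
        alff = compute_alff(make_image(np.zeros((2, 2, 2, 50))))
        assert np.all(alff.data == 0)

    def test_scaling_is_linear(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(3, 3, 3, 190))
        a1 = compute_alff(make_image(data))
        a3 = compute_alff(make_image(3.0 * data))
        assert np.allclose(a3.data, 3.0 * a1.data, rtol=1e-12)


class TestReho:
    def test_identical_series_give_w_one(self):
        sig = np.sin(np.arange(30))
        data = np.broadcast_to(sig, (3, 3, 3, 30)).copy()
        reho = compute_reho(make_image(data))
        assert reho.data[1, 1, 1] == pytest.approx(1.0, rel=1e-12)

    def test_reversed_pair_gives_w_zero(self):
        """Two series with exactly reversed rankings: rank sums are constant."""
        series = np.arange(10, dtype=float)
        assert kendalls_w(np.stack([series, series[::-1]])) == pytest.approx(0.0, abs=1e-12)

    def test_kendalls_w_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            series = rng.normal(size=(27, 20))
            k, n = series.shape
            ranks = np.array([rankdata(s) for s in series])
            r_sums = ranks.sum(axis=0)
            s = ((r_sums - r_sums.mean()) ** 2).sum()
            expected = 12.0 * s / (k**2 * (n**3 - n))
            assert kendalls_w(series) == pytest.approx(expected, abs=1e-12)

    def test_map_matches_per_voxel_loop(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(5, 5, 5, 15))
        mask = np.ones((5, 5, 5), bool)
        mask[0, 0, :] = False  # carve an edge notch to exercise K < 27
        img = make_image(data, mask=mask)
        reho = compute_reho(img, min_neighbors=8)
        for idx in [(2, 2, 2), (1, 1, 1), (3, 1, 2), (1, 0, 0)]:
            xs = slice(max(idx[0] - 1, 0), idx[0] + 2)
            ys = slice(max(idx[1] - 1, 0), idx[1] + 2)
            zs = slice(max(idx[2] - 1, 0), idx[2] + 2)
            block = data[xs, ys, zs]
            bmask = mask[xs, ys, zs]
            series = block[bmask]
            assert reho.data[idx] == pytest.approx(kendalls_w(series), abs=1e-12)

    def test_min_neighbor_threshold_masks_edges(self):
        data = np.random.default_rng(8).normal(size=(4, 4, 4, 12))
        reho = compute_reho(make_image(data))  # default threshold 14
        assert not reho.mask[0, 0, 0]  # corner has only 8 cube voxels
        assert reho.mask[1, 1, 1]


class TestFc:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(9)
        img = make_image(rng.normal(size=(3, 3, 3, 40)))
        fc = compute_fc(img, np.array([[1, 1, 1]]))
        assert fc.data[1, 1, 1] == pytest.approx(1.0, rel=1e-12)

    def test_negated_seed_gives_minus_one(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(2, 2, 2, 30))
        data[0, 0, 1] = -data[0, 0, 0]
        fc = compute_fc(make_image(data), np.array([[0, 0, 0]]))
        assert fc.data[0, 0, 1] == pytest.approx(-1.0, rel=1e-12)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(4, 4, 4, 60))
        seed_vox = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]])
        fc = compute_fc(make_image(data), seed_vox)
        seed_mean = data[tuple(seed_vox.T)].mean(axis=0)
        for idx in [(3, 3, 3), (0, 1, 2), (2, 0, 1)]:
            y = data[idx]
            expected = (
                np.sum((y - y.mean()) * (seed_mean - seed_mean.mean()))
                / np.sqrt(np.sum((y - y.mean()) ** 2) * np.sum((seed_mean - seed_mean.mean()) ** 2))
            )
            assert fc.data[idx] == pytest.approx(expected, abs=1e-12)

    def test_empty_seed_rejected(self):
        img = make_image(np.ones((2, 2, 2, 10)))
        with pytest.raises(ValueError, match="empty"):
            compute_fc(img, np.empty((0, 3), dtype=int))


class TestDmnMask:
    def _cohort(self, data):
        grid = GridSpec.from_shape(data.shape[1:])
        return CohortMaps(data, grid, np.ones(data.shape[1:], bool))

    def test_uniformly_positive_stacks_select_everything(self):
        rng = np.random.default_rng(12)
        data = 0.5 + 0.01 * rng.normal(size=(10, 4, 4, 4))
        mask = compute_dmn_mask([self._cohort(data)])
        assert mask.all()

    def test_null_stacks_select_almost_nothing(self):
        rng = np.random.default_rng(13)
        data = rng.normal(size=(12, 8, 8, 8))
        mask = compute_dmn_mask([self._cohort(data)], alpha=0.05)
        assert mask.mean() <= 0.05

    def test_union_contains_single_strategy_mask(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=(10, 5, 5, 5)) + 0.8
        b = rng.normal(size=(10, 5, 5, 5))
        single = compute_dmn_mask([self._cohort(a)])
        union = compute_dmn_mask([self._cohort(a), self._cohort(b)])
        assert np.all(union[single])
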