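"""Autocorrelation estimators: FFT vs direct sums, lag mapping, image
splitting and downsampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import corrspec as cs
from corrspec.correlate import acf_fcs_direct, acf_rics_direct
from corrspec.datatypes import ScanGeometry


def _geom(n_cols=8, n_rows=8, alpha=0.0):
    return ScanGeometry(t_pix=2e-6, t_line=2e-3, s_xi=0.05, s_psi=0.05,
                        alpha=alpha, n_cols=n_cols, n_rows=n_rows)


class TestAcfFcs:
    def test_constant_trace_has_zero_correlation(self):
        tr = cs.PhotonTrace(counts=np.full(1000, 7), bin_dt=1e-3)
        acf = cs.acf_fcs(tr, max_lag=0.05)
        assert np.allclose(acf.g, 0.0, atol=1e-12)

    def test_matches_brute_force_on_toy_trace(self):
        tr = cs.PhotonTrace(counts=np.array([2, 0, 2, 0, 2, 0, 2, 0]),
                            bin_dt=1.0)
        fast = cs.acf_fcs(tr, max_lag=3.0)
        slow = acf_fcs_direct(tr, max_lag=3.0)
        # alternating trace: delta = ±1, mean 1; biased-normalized sums
        assert np.allclose(fast.g, slow.g, rtol=0, atol=1e-12)
        assert fast.g[0] == pytest.approx(-7.0 / 8.0)

    def test_fft_equals_direct_estimator_on_random_trace(self):
        rng = np.random.default_rng(3)
        tr = cs.PhotonTrace(counts=rng.poisson(4.0, 4096), bin_dt=1e-4)
        fast = cs.acf_fcs(tr, max_lag=0.03)
        slow = acf_fcs_direct(tr, max_lag=0.03)
        assert np.allclose(fast.g, slow.g, rtol=1e-10, atol=1e-14)

    def test_window_restricts_the_analyzed_segment(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(3.0, 10000)
        tr = cs.PhotonTrace(counts=counts, bin_dt=1e-3)
        win = cs.acf_fcs(tr, window=(1.0, 7.0), max_lag=0.2)
        manual = cs.acf_fcs(cs.PhotonTrace(counts=counts[1000:7000],
                                           bin_dt=1e-3), max_lag=0.2)
        assert np.allclose(win.g, manual.g)

    def test_zero_mean_window_is_rejected(self):
        tr = cs.PhotonTrace(counts=np.zeros(100, dtype=int), bin_dt=1e-3)
        with pytest.raises(ValueError, match="mean"):
            cs.acf_fcs(tr, max_lag=0.01)

    def test_poisson_noise_decorrelates_at_nonzero_lag(self):
        rng = np.random.default_rng(5)
        n = 200_000
        tr = cs.PhotonTrace(counts=rng.poisson(5.0, n), bin_dt=1e-5)
        acf = cs.acf_fcs(tr, max_lag=2e-4)
        assert np.all(np.abs(acf.g) < 4.0 / np.sqrt(n))


class TestLagTime:
    @pytest.mark.parametrize("xi, psi, t_pix, t_line, expected", [
        (0, 0, 2e-6, 2e-3, 0.0),
        (2, 1, 2e-6, 2e-3, 2.004e-3),
        (100, 2, 3.5e-6, 3.5e-3, 7.35e-3),
    ])
    def test_scan_timing_maps_pixel_lags_to_seconds(self, xi, psi, t_pix,
                                                    t_line, expected):
        geom = ScanGeometry(t_pix=t_pix, t_line=t_line, s_xi=0.05,
                            s_psi=0.05)
        assert cs.lag_time(xi, psi, geom) == pytest.approx(expected)

    @given(xi=st.integers(0, 500), psi=st.integers(0, 500))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_lag_time_is_linear_in_both_displacements(self, xi, psi):
        geom = _geom()
        assert cs.lag_time(xi, psi, geom) == pytest.approx(
            xi * geom.t_pix + psi * geom.t_line)


class TestAcfRics:
    def test_constant_frames_have_zero_correlation(self):
        stack = cs.ImageStack(frames=np.full((3, 8, 8), 5), geometry=_geom())
        acf = cs.acf_rics(stack)
        assert np.allclose(acf.g, 0.0, atol=1e-12)

    def test_matches_brute_force_double_sum_on_single_frame(self):
        frame = np.zeros((4, 4))
        frame[1, 2] = 9.0
        stack = cs.ImageStack(frames=frame[None], geometry=_geom(4, 4))
        acf = cs.acf_rics(stack, xi_max=2, psi_max=2)
        oracle = acf_rics_direct(frame, acf.xi_range, acf.psi_range)
        assert np.allclose(acf.g, oracle, rtol=1e-10, atol=1e-12)

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(6)
        frames = rng.poisson(3.0, (2, 6, 7)).astype(float)
        stack = cs.ImageStack(frames=frames, geometry=_geom(7, 6))
        acf = cs.acf_rics(stack, xi_max=3, psi_max=2)
        oracle = np.mean([acf_rics_direct(f, acf.xi_range, acf.psi_range)
                          for f in frames], axis=0)
        assert np.allclose(acf.g, oracle, rtol=1e-10, atol=1e-12)

    def test_iid_poisson_frames_decorrelate_off_zero_lag(self):
        rng = np.random.default_rng(7)
        stack = cs.ImageStack(frames=rng.poisson(8.0, (20, 32, 32)),
                              geometry=_geom(32, 32))
        acf = cs.acf_rics(stack, xi_max=5, psi_max=3)
        off = acf.g.copy()
        off[0, acf.xi_range == 0] = 0.0
        n_samples = 20 * 32 * 32
        assert np.all(np.abs(off) < 4.0 / np.sqrt(n_samples))

    def test_background_subtract_requires_background(self):
        stack = cs.ImageStack(frames=np.ones((2, 4, 4)), geometry=_geom(4, 4))
        with pytest.raises(ValueError, match="background"):
            cs.acf_rics(stack, mode="background_subtract")

    def test_zero_lag_element_sits_at_psi0_xi0(self):
        rng = np.random.default_rng(8)
        stack = cs.ImageStack(frames=rng.poisson(3.0, (1, 8, 8)),
                              geometry=_geom())
        acf = cs.acf_rics(stack, xi_max=3, psi_max=2)
        i0 = np.where(acf.xi_range == 0)[0][0]
        assert acf.g[0, i0] == acf.g.max()


class TestSplitSectors:
    def test_single_sector_covers_the_whole_image(self):
        grid = cs.SectorGrid(config="sector_self", n_x=1, n_y=1,
                             sector_size=50.0)
        regions = cs.split_sectors((1000, 1000), grid, pixel_size=0.05)
        assert len(regions) == 1
        (r0, r1), (c0, c1) = regions[0]["region"]
        assert (r0, r1, c0, c1) == (0, 1000, 0, 1000)

    def test_even_centers_touch_but_do_not_cross_borders(self):
        grid = cs.SectorGrid(config="larger_self", n_x=3, n_y=3,
                             sector_size=0.8, corr_size=400 * 0.05)
        regions = cs.split_sectors((1000, 1000), grid, pixel_size=0.05)
        centers = sorted({r["center"][1] for r in regions})
        assert centers == [200, 500, 800]
        for r in regions:
            (r0, r1), (c0, c1) = r["region"]
            assert 0 <= r0 < r1 <= 1000 and 0 <= c0 < c1 <= 1000

    def test_fig7_style_grid_produces_625_regions(self):
        grid = cs.SectorGrid(config="larger_self", n_x=25, n_y=25,
                             sector_size=0.8, corr_size=3.0)
        regions = cs.split_sectors((1000, 1000), grid, pixel_size=0.04)
        assert len(regions) == 625

    def test_sector_self_regions_tile_disjointly(self):
        grid = cs.SectorGrid(config="sector_self", n_x=4, n_y=4,
                             sector_size=0.25 * 64 * 0.05)
        regions = cs.split_sectors((64, 64), grid, pixel_size=0.05)
        covered = np.zeros((64, 64), dtype=int)
        for r in regions:
            (r0, r1), (c0, c1) = r["region"]
            covered[r0:r1, c0:c1] += 1
        assert covered.max() == 1

    def test_pair_config_has_concentric_reference(self):
        grid = cs.SectorGrid(config="pair", n_x=2, n_y=2, sector_size=0.4,
                             corr_size=1.2)
        regions = cs.split_sectors((100, 100), grid, pixel_size=0.05)
        for r in regions:
            assert r["reference"] is not None
            (rr0, rr1), (rc0, rc1) = r["reference"]
            (q0, q1), (c0, c1) = r["region"]
            assert q0 <= rr0 and rr1 <= q1 and c0 <= rc0 and rc1 <= c1

    def test_oversized_region_is_rejected(self):
        grid = cs.SectorGrid(config="larger_self", n_x=1, n_y=1,
                             sector_size=1.0, corr_size=200.0)
        with pytest.raises(ValueError):
            cs.split_sectors((100, 100), grid, pixel_size=0.05)


class TestCropAndDownsample:
    def test_identity_when_nothing_requested(self):
        acf = cs.AcfCurve(lags=np.arange(1, 11.0), g=np.linspace(1, 0, 10))
        out = cs.crop_and_downsample(acf, drop_first=0)
        assert np.array_equal(out.lags, acf.lags)
        assert np.array_equal(out.g, acf.g)

    def test_log_bin_means_match_direct_averaging(self):
        rng = np.random.default_rng(9)
        n = 100_000
        lags = 1e-6 * np.arange(1, n + 1)
        g = 1.0 / (1.0 + lags / 1e-3) + 0.01 * rng.standard_normal(n)
        acf = cs.AcfCurve(lags=lags, g=g)
        out = cs.crop_and_downsample(acf, log_bins=150)
        assert len(out) <= 150
        edges = np.geomspace(lags[0], lags[-1], 151)
        edges[-1] *= 1 + 1e-12
        idx = np.clip(np.searchsorted(edges, lags, side="right") - 1, 0, 149)
        expected = [g[idx == b].mean() for b in range(150) if np.any(idx == b)]
        assert np.allclose(out.g, expected)

    def test_rics_quadrant_flattens_to_three_hundred_points(self):
        geom = _geom(1000, 1000)
        xi = np.arange(-500, 501)
        psi = np.arange(0, 11)
        acf = cs.Acf2D(g=np.random.default_rng(0).random((11, 1001)),
                       xi_range=xi, psi_range=psi, geometry=geom)
        out = cs.crop_and_downsample(acf, drop_first=4, n_lines=3,
                                     points_per_line=100)
        assert out.g.shape == (3, 100)
        assert out.g.size == 300

    def test_everything_cropped_raises(self):
        acf = cs.AcfCurve(lags=np.arange(1, 5.0), g=np.ones(4))
        with pytest.raises(ValueError):
            cs.crop_and_downsample(acf, drop_first=4)
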