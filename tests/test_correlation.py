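"""Correlation estimators against closed forms and a brute-force oracle."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from clustersense import correlation as corr
from clustersense.synthetic import generate_bead_field, generate_point_pattern


def brute_force_pair_correlation(points, window, pixel_size):
    """O(n^2) pair-displacement oracle with the same window normalization.

    Rasterizes pairwise displacement vectors onto the lag grid and
    divides by rho^2 times the window autocorrelation, i.e. exactly the
    quantity the FFT estimator computes, obtained without FFTs.
    """
    w = np.asarray(window, bool)
    ny, nx = w.shape
    idx = np.floor(points / pixel_size).astype(int)
    inside = w[idx[:, 1], idx[:, 0]]
    idx = idx[inside]
    n = len(idx)
    acc = np.zeros((2 * ny - 1, 2 * nx - 1))
    cy, cx = ny - 1, nx - 1
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dy = idx[j, 1] - idx[i, 1]
            dx = idx[j, 0] - idx[i, 0]
            acc[cy + dy, cx + dx] += 1
    ac_w = corr._fft_autocorr(w.astype(float))
    rho = n / w.sum()
    yy, xx = np.mgrid[0:2 * ny - 1, 0:2 * nx - 1]
    r = np.hypot(yy - cy, xx - cx)
    nb = int(r.max()) + 1
    b = np.floor(r + 0.5).astype(int)
    ok = ac_w > 0.5
    num = np.bincount(b[ok], weights=acc[ok], minlength=nb)
    den = np.bincount(b[ok], weights=ac_w[ok], minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = num / (rho ** 2 * den)
    g[0] = np.nan
    return g


class TestPixelAutocorrelation:
    def test_white_noise_is_delta_correlated(self, rng):
        img = rng.standard_normal((200, 200))
        c = corr.pixel_autocorrelation(img, max_lag=10)
        assert c.value[0] == pytest.approx(1.0)
        assert np.all(np.abs(c.value[1:]) < 0.05)

    def test_blurred_noise_matches_gaussian_closed_form(self, rng):
        sigma = 3.0
        img = gaussian_filter(rng.standard_normal((600, 600)), sigma)
        c = corr.pixel_autocorrelation(img, max_lag=12, voxel_nm=1.0)
        expected = np.exp(-c.lag_px ** 2 / (4 * sigma ** 2))
        np.testing.assert_allclose(c.value, expected, atol=0.03)

    def test_isotropy_row_vs_column(self, rng):
        img = gaussian_filter(rng.standard_normal((500, 500)), 3.0)
        c = corr.pixel_autocorrelation(img, max_lag=20, voxel_nm=1.0)
        fx = corr.fit_correlation_length(
            corr.CorrelationCurve(c.lag_px, c.lag_nm, c.value_x, c.value_x,
                                  c.value_x, c.n_samples))
        fy = corr.fit_correlation_length(
            corr.CorrelationCurve(c.lag_px, c.lag_nm, c.value_y, c.value_y,
                                  c.value_y, c.n_samples))
        assert fx.lambda_corr == pytest.approx(fy.lambda_corr, rel=0.05)

    def test_affine_intensity_rescale_invariance(self, rng):
        img = gaussian_filter(rng.standard_normal((300, 300)), 2.5)
        c1 = corr.pixel_autocorrelation(img, max_lag=15, voxel_nm=1.0)
        c2 = corr.pixel_autocorrelation(3.7 * img + 11.0, max_lag=15,
                                        voxel_nm=1.0)
        l1 = corr.fit_correlation_length(c1).lambda_corr
        l2 = corr.fit_correlation_length(c2).lambda_corr
        assert l1 == pytest.approx(l2, rel=1e-6)

    def test_degenerate_mask_rejected(self, rng):
        img = rng.standard_normal((50, 50))
        mask = np.zeros((50, 50), bool)
        mask[10, 10:14] = True
        with pytest.raises(ValueError):
            corr.pixel_autocorrelation(img, mask)

    def test_zero_variance_image_flagged(self):
        c = corr.pixel_autocorrelation(np.ones((60, 60)), max_lag=5)
        assert c.degenerate


class TestCorrelationLengthFit:
    def test_exact_exponential_curve(self):
        x = np.arange(0, 30)
        y = 0.1 + 0.9 * np.exp(-x / 0.3 / 10)  # decay scale 3 px
        curve = corr.CorrelationCurve(x, x.astype(float), y, y, y,
                                      np.ones_like(x))
        fit = corr.fit_correlation_length(curve, lag_min_px=0, use_nm=False)
        assert fit.x0 == 0
        assert fit.lambda_corr == pytest.approx(np.log(2) * 3.0, rel=1e-6)

    def test_bead_field_recovers_psf_reference_length(self, acq):
        lams = []
        for s in range(4):
            stack, _ = generate_bead_field(acq, 40, seed=s, fov_px=420)
            c = corr.pixel_autocorrelation(stack["beads"], max_lag=25,
                                           voxel_nm=acq.voxel_xy_nm)
            lams.append(corr.fit_correlation_length(
                c, lag_min_px=1, lag_max_px=25).lambda_corr)
        # isolated PSF spots on a full frame: length ~ the unmasked
        # blurred-noise mapping of the calibrated PSF sigma
        assert np.mean(lams) == pytest.approx(
            1.665 * acq.psf_sigma_lateral_nm, rel=0.15)

    def test_clustered_texture_longer_than_psf_only(self, sim, acq):
        from clustersense.synthetic import generate_nucleus_stack
        from scipy.ndimage import binary_erosion
        diffs = []
        for s in range(4):
            s_cl, t_cl = generate_nucleus_stack(sim, acq, 0.15, s)
            s_no, t_no = generate_nucleus_stack(sim, acq, 0.15, s,
                                                n_clusters=0)
            vals = []
            for stack, truth in ((s_cl, t_cl), (s_no, t_no)):
                z = stack["tf"].shape[0] // 2
                m = binary_erosion(truth.extras["nucleus_mask"][z],
                                   iterations=10)
                c = corr.pixel_autocorrelation(stack["tf"][z], m, max_lag=25,
                                               voxel_nm=acq.voxel_xy_nm)
                vals.append(corr.fit_correlation_length(
                    c, lag_min_px=1).lambda_corr)
            diffs.append(vals[0] - vals[1])
        assert np.mean(diffs) > 0

    def test_nonconvergent_fit_raises(self):
        x = np.arange(6)
        y = np.array([1.0, np.nan, np.nan, np.nan, np.nan, np.nan])
        curve = corr.CorrelationCurve(x, x.astype(float), y, y, y,
                                      np.ones_like(x))
        with pytest.raises(ValueError):
            corr.fit_correlation_length(curve)


class TestPairCorrelation:
    def test_poisson_pattern_is_flat(self):
        win = corr.disk_window(2.5, 0.043)
        pcs = []
        for s in range(10):
            pts, _ = generate_point_pattern(4.0, 0.0, 0.37, 0, win, 0.043,
                                            seed=s)
            pcs.append(corr.pair_correlation_map(pts, win, 0.043,
                                                 r_max_um=2.0))
        avg = corr.average_pair_correlations(pcs)
        sel = (avg.r_um > 0.1) & (avg.r_um < 1.8) & np.isfinite(avg.g)
        assert np.nanmean(avg.g[sel]) == pytest.approx(1.0, abs=0.08)

    def test_fft_matches_brute_force(self):
        win = corr.disk_window(1.5, 0.06)
        pts, _ = generate_point_pattern(8.0, 6.0, 0.3, 2, win, 0.06, seed=3)
        assert len(pts) <= 500
        fft_pc = corr.pair_correlation_map(pts, win, 0.06)
        bf = brute_force_pair_correlation(pts, win, 0.06)
        k = min(len(bf), len(fft_pc.g), int(len(win) / 4))
        sel = np.isfinite(fft_pc.g[:k]) & np.isfinite(bf[:k])
        np.testing.assert_allclose(fft_pc.g[:k][sel], bf[:k][sel],
                                   rtol=0.05, atol=0.05)

    def test_coincident_points_flagged_degenerate(self):
        win = np.ones((64, 64), bool)
        pts = np.tile([[1.0, 1.0]], (30, 1))
        with pytest.warns(UserWarning):
            pc = corr.pair_correlation_map(pts, win, 0.05)
        assert pc.degenerate

    def test_too_few_points_rejected(self):
        win = np.ones((32, 32), bool)
        with pytest.raises(ValueError):
            corr.pair_correlation_map(np.zeros((4, 2)), win, 0.05)


class TestClumpModelFit:
    def test_analytic_curve_recovered_to_machine_precision(self):
        r = np.arange(0, 60) * 0.043
        g = 8.0 * np.exp(-(r / 0.37) ** 2) + 1.0
        g[0] = np.nan
        pc = corr.PairCorrelation(r_um=r, g=g, n_pairs_weight=np.ones_like(r),
                                  pixel_size_um=0.043, n_points=100)
        fit = corr.fit_pair_correlation(pc)
        assert fit.rho_prime == pytest.approx(8.0, rel=1e-6)
        assert fit.sigma_um == pytest.approx(0.37, rel=1e-6)
        assert fit.xi_pair_um == fit.sigma_um

    def test_planted_clumps_recovered_within_twenty_percent(self):
        win = corr.disk_window(2.5, 0.043)
        pcs = []
        for s in range(12):
            pts, _ = generate_point_pattern(2.0, 8.0, 0.37, 3, win, 0.043,
                                            seed=40 + s)
            pcs.append(corr.pair_correlation_map(pts, win, 0.043,
                                                 r_max_um=2.0))
        fit = corr.fit_pair_correlation(corr.average_pair_correlations(pcs),
                                        r_max_um=1.8)
        assert fit.rho_prime == pytest.approx(8.0, rel=0.20)
        assert fit.sigma_um == pytest.approx(0.37, rel=0.20)

    def test_poisson_pattern_has_zero_excess(self):
        win = corr.disk_window(2.5, 0.043)
        pcs = []
        for s in range(8):
            pts, _ = generate_point_pattern(4.0, 0.0, 0.37, 0, win, 0.043,
                                            seed=60 + s)
            pcs.append(corr.pair_correlation_map(pts, win, 0.043,
                                                 r_max_um=2.0))
        fit = corr.fit_pair_correlation(corr.average_pair_correlations(pcs),
                                        r_max_um=1.8)
        assert fit.rho_prime < 0.3


class TestPsfCalibration:
    def test_inversion_round_trip(self):
        lags = np.arange(26)
        sigma = corr.psf_sigma_for_corr_length(200.0, voxel_nm=43.0)
        c = np.exp(-(lags * 43.0) ** 2 / (4 * sigma ** 2))
        curve = corr.CorrelationCurve(lags, lags * 43.0, c, c, c,
                                      np.ones_like(lags))
        fit = corr.fit_correlation_length(curve, lag_min_px=1, lag_max_px=25)
        assert fit.lambda_corr == pytest.approx(200.0, abs=0.5)

    def test_masked_calibration_accounts_for_row_taper(self):
        rows = corr.disk_row_lengths(48.0)
        s_masked = corr.psf_sigma_for_corr_length(200.0, row_lengths=rows)
        s_free = corr.psf_sigma_for_corr_length(200.0)
        assert s_masked > s_free  # finite rows shorten the apparent length
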