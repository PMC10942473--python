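"""3D cluster detection, 2D Gaussian fitting and derived properties."""

import math

import numpy as np
import pytest

from clustersense import synthetic
from clustersense.clusters import (ClusterRecord, _gauss2d,
                                   cluster_properties, detect_clusters_3d,
                                   fit_cluster_2d, nuclear_cluster_summary,
                                   quantify_nucleus, records_to_frame,
                                   threshold_effective_diameter_px)


def gaussian_window(Ia=5.0, Ibg=1.0, x0=0.0, y0=0.0, s1=3.0, s2=2.0,
                    th=0.3, n=41):
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2
    return _gauss2d((xx - c, yy - c), Ia, Ibg, x0, y0, s1, s2, th).reshape(n, n)


class TestThresholdRule:
    def test_effective_diameter_of_18_voxels(self):
        assert threshold_effective_diameter_px() == pytest.approx(3.25, abs=0.01)

    def test_single_slice_speckle_rejected(self):
        """A bright blob confined to one z-slice fails the z-extent rule,
        while its two-slice twin passes."""
        img = np.zeros((12, 60, 60))
        img[5, 10:19, 10:19] = 100.0            # one-slice speckle (81 vox)
        img[5:7, 35:42, 35:42] = 100.0          # two-slice spot (98 vox)
        mask = np.ones_like(img, dtype=bool)
        cands = detect_clusters_3d(img, mask, percentile=99.5)
        assert len(cands) == 1
        z, y, x = cands[0].centroid_px
        assert abs(y - 38) < 2 and abs(x - 38) < 2


class TestFit:
    def test_noiseless_parameters_recovered_exactly(self):
        img = gaussian_window()
        rec = fit_cluster_2d(img, (20, 20), w=12)
        assert rec.accepted
        assert rec.Ia == pytest.approx(5.0, rel=1e-4)
        assert rec.Ibg == pytest.approx(1.0, rel=1e-4)
        assert rec.sigma1_px == pytest.approx(3.0, rel=1e-4)
        assert rec.sigma2_px == pytest.approx(2.0, rel=1e-4)
        assert rec.theta == pytest.approx(0.3, rel=1e-3)

    def test_background_offset_identified_separately(self):
        """Adding a constant shifts Ibg only: Ia is background-corrected."""
        img = gaussian_window()
        r1 = fit_cluster_2d(img, (20, 20), w=12)
        r2 = fit_cluster_2d(img + 7.5, (20, 20), w=12)
        assert r2.Ibg - r1.Ibg == pytest.approx(7.5, abs=1e-6)
        assert r2.Ia == pytest.approx(r1.Ia, abs=1e-6)

    def test_window_outside_image_not_accepted(self):
        img = gaussian_window()
        rec = fit_cluster_2d(img, (3, 3), w=12)
        assert not rec.accepted

    def test_theta_constrained_to_octant(self):
        img = gaussian_window(th=0.2)
        rec = fit_cluster_2d(img, (20, 20), w=12)
        assert 0 < rec.theta < np.pi / 4
        assert rec.sigma1_px >= rec.sigma2_px

    def test_quadratic_form_coefficients_consistent(self):
        img = gaussian_window()
        rec = fit_cluster_2d(img, (20, 20), w=12)
        a, b, c = rec.abc
        # rebuild the window from (a, b, c) and compare
        yy, xx = np.mgrid[0:41, 0:41].astype(float)
        dx = xx - 20 - rec.x0c_px
        dy = yy - 20 - rec.y0c_px
        rebuilt = rec.Ia * np.exp(-(a * dx ** 2 + 2 * b * dx * dy
                                    + c * dy ** 2)) + rec.Ibg
        np.testing.assert_allclose(rebuilt, img, rtol=1e-3, atol=1e-3)

    def test_discard_rate_small_at_study_snr(self, sim, acq):
        """Fits on detected in-window candidates rarely fail. The only
        rejection mode at this SNR is the width bound, which trims the
        large-size tail of the planted population."""
        attempted = 0
        discarded = 0
        for s in range(12):
            stack, truth = synthetic.generate_nucleus_stack(
                sim, acq, 0.15, seed=s, n_clusters=5)
            recs = quantify_nucleus(stack["tf"], truth.extras["nucleus_mask"],
                                    acq, percentile=92.0,
                                    inuc=float(truth.nuclei["Inuc"].iloc[0]))
            fitted = [r for r in recs if not np.isnan(r.Ia) or r.accepted]
            attempted += len(fitted)
            discarded += sum(1 for r in fitted if not r.accepted)
        assert attempted > 40
        assert discarded / attempted < 0.15


class TestDerivedProperties:
    def _accepted(self, s1, s2, Ia=1.0, Ibg=0.5):
        rec = ClusterRecord(nucleus_label=1, centroid_px=(0, 0, 0), Ia=Ia,
                            Ibg=Ibg, sigma1_px=s1, sigma2_px=s2, theta=0.1,
                            accepted=True)
        return rec

    def test_three_four_five_size(self, acq):
        rec = cluster_properties(self._accepted(3.0, 4.0), acq)
        assert rec.d_um == pytest.approx(5.0 * acq.voxel_xy_nm / 1000)

    def test_unit_sigma_integrated_intensity_is_two_pi(self, acq):
        px_um = acq.voxel_xy_nm / 1000
        rec = cluster_properties(self._accepted(1.0, 1.0, Ia=1.0), acq)
        assert rec.Ic == pytest.approx(2 * math.pi * px_um ** 2)

    def test_rejected_fit_has_no_properties(self, acq):
        rec = ClusterRecord(nucleus_label=1, centroid_px=(0, 0, 0))
        with pytest.raises(ValueError):
            cluster_properties(rec, acq)

    def test_amp_ratio_population_mean_matches_preset(self, sim, acq):
        """Fitted amplification averages ~2.2 on calibrated populations."""
        ratios = []
        for s in range(8):
            stack, truth = synthetic.generate_nucleus_stack(
                sim, acq, 0.15, seed=100 + s, n_clusters=8)
            recs = quantify_nucleus(stack["tf"], truth.extras["nucleus_mask"],
                                    acq, percentile=92.0,
                                    inuc=float(truth.nuclei["Inuc"].iloc[0]))
            ratios.extend(r.amp_ratio for r in recs if r.accepted)
        assert np.mean(ratios) == pytest.approx(sim.amp_ratio_mean, rel=0.25)


class TestRoundTrip:
    def test_detection_and_fit_recover_planted_shapes(self, sim, acq):
        """Planted (Ia, sigma1, sigma2) recovered with small bias on
        sparse calibrated nuclei."""
        fit_d, planted_d = [], []
        ia_err = []
        for s in range(30):
            stack, truth = synthetic.generate_nucleus_stack(
                sim, acq, 0.15, seed=200 + s, n_clusters=5)
            recs = quantify_nucleus(stack["tf"], truth.extras["nucleus_mask"],
                                    acq, percentile=92.0,
                                    inuc=float(truth.nuclei["Inuc"].iloc[0]))
            tr = truth.clusters
            for r in recs:
                if not r.accepted:
                    continue
                z, y, x = r.centroid_px
                d = np.sqrt((tr.z_px - z) ** 2 * acq.z_anisotropy ** 2
                            + (tr.y_px - y) ** 2 + (tr.x_px - x) ** 2)
                j = d.idxmin()
                if d[j] > 12:
                    continue
                fit_d.append(r.d_um * 1000)
                planted_d.append(tr.d_nm[j])
                ia_err.append((r.Ia - tr.Ia[j]) / tr.Ia[j])
        assert len(fit_d) > 80
        bias = np.mean(np.array(fit_d) - np.array(planted_d))
        assert abs(bias) < 0.05 * np.mean(planted_d)
        assert abs(np.mean(ia_err)) < 0.15

    def test_fitted_size_independent_of_fitted_amplitude(self, sim, acq):
        rows = []
        for s in range(25):
            stack, truth = synthetic.generate_nucleus_stack(
                sim, acq, 0.15, seed=300 + s, n_clusters=5)
            recs = quantify_nucleus(stack["tf"], truth.extras["nucleus_mask"],
                                    acq, percentile=92.0,
                                    inuc=float(truth.nuclei["Inuc"].iloc[0]))
            rows.extend((r.d_um, r.Ia) for r in recs if r.accepted)
        d, ia = np.array(rows).T
        r = np.corrcoef(d, ia)[0, 1]
        assert abs(r) < 0.15

    def test_fitted_sizes_do_not_reach_below_psf_scale(self, sim, acq):
        """The left tail of the fitted-size histogram vanishes near the
        diffraction limit."""
        sizes = []
        for s in range(6):
            stack, truth = synthetic.generate_nucleus_stack(
                sim, acq, 0.15, seed=400 + s, n_clusters=8)
            recs = quantify_nucleus(stack["tf"], truth.extras["nucleus_mask"],
                                    acq, percentile=92.0,
                                    inuc=float(truth.nuclei["Inuc"].iloc[0]))
            sizes.extend(r.d_um * 1000 for r in recs if r.accepted)
        psf_size = math.sqrt(2) * acq.psf_sigma_lateral_nm
        assert np.quantile(sizes, 0.02) > 0.8 * psf_size


class TestSummary:
    def test_mean_of_sizes(self):
        df = records_to_frame([])
        import pandas as pd
        df = pd.DataFrame({"d_um": [2.0, 4.0, 6.0], "Ia": [1, 1, 1],
                           "Ibg": [1, 1, 1], "Ic": [1, 1, 1],
                           "accepted": [True, True, True]})
        s = nuclear_cluster_summary(df, inuc=10.0, x_over_L=0.3)
        assert s["n_clusters"] == 3
        assert s["mean_d_um"] == pytest.approx(4.0)

    def test_empty_nucleus_counts_zero(self):
        import pandas as pd
        s = nuclear_cluster_summary(pd.DataFrame(), inuc=10.0, x_over_L=0.3)
        assert s["n_clusters"] == 0
        assert np.isnan(s["mean_d_um"])
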