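"""Generator contracts: determinism, planted statistics, independence."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from clustersense import synthetic
from clustersense.params import EmbryoSimParams
from clustersense.synthetic import (generate_bead_field, generate_embryo_field,
                                    generate_nucleus_stack,
                                    generate_point_pattern,
                                    generate_timelapse, generate_two_channel,
                                    sample_cluster_population,
                                    sample_coupling_distances,
                                    sample_gradient_field,
                                    simulate_telegraph_trace)


class TestNucleusStack:
    def test_same_seed_bit_identical(self, sim, acq):
        s1, t1 = generate_nucleus_stack(sim, acq, 0.3, seed=7)
        s2, t2 = generate_nucleus_stack(sim, acq, 0.3, seed=7)
        np.testing.assert_array_equal(s1["tf"], s2["tf"])
        assert t1.clusters.equals(t2.clusters)

    def test_noiseless_argmax_at_planted_centroid(self, sim, acq):
        stack, truth = generate_nucleus_stack(sim, acq, 0.2, seed=3,
                                              n_clusters=1, noise=False,
                                              mol_noise=False)
        img = stack["tf"]
        z, y, x = np.unravel_index(np.argmax(img), img.shape)
        c = truth.clusters.iloc[0]
        assert abs(z - c.z_px) <= 1 and abs(y - c.y_px) <= 1 and abs(x - c.x_px) <= 1

    def test_planted_size_distribution_matches_preset(self, sim, acq, rng):
        pop = sample_cluster_population(sim, acq, rng, 2000, ibg=100.0)
        se = sim.d_sd_nm / np.sqrt(len(pop))
        # lognormal floored at the PSF-limited width: mean within a few SE
        assert abs(pop["d_nm"].mean() - sim.d_mean_nm) < 4 * se + 15
        assert abs(pop["d_nm"].std() - sim.d_sd_nm) < 0.15 * sim.d_sd_nm
        assert abs(pop["amp_ratio"].mean() - sim.amp_ratio_mean) < 3 * 0.8 / np.sqrt(2000)

    def test_size_amplitude_independence(self, sim, acq, rng):
        pop = sample_cluster_population(sim, acq, rng, 3000, ibg=100.0)
        r = np.corrcoef(pop["d_nm"], pop["Ia"])[0, 1]
        assert abs(r) < 0.1

    def test_size_floor_respected(self, sim, acq, rng):
        pop = sample_cluster_population(sim, acq, rng, 1000, ibg=100.0)
        floor = max(sim.d_floor_nm, np.sqrt(2) * acq.psf_sigma_lateral_nm)
        assert (pop["d_nm"] >= floor).all()
        assert (pop["sigma2_nm"] >= acq.psf_sigma_lateral_nm).all()

    def test_degenerate_truncation_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            EmbryoSimParams(d_mean_nm=140.0, d_floor_nm=150.0)

    def test_clusters_inside_nucleus(self, sim, acq):
        _, truth = generate_nucleus_stack(sim, acq, 0.1, seed=11)
        nuc = truth.nuclei.iloc[0]
        c = truth.clusters
        r = np.sqrt(((c.z_px - nuc.z_px) / nuc.radius_z_px) ** 2
                    + ((c.y_px - nuc.y_px) / nuc.radius_px) ** 2
                    + ((c.x_px - nuc.x_px) / nuc.radius_px) ** 2)
        assert (r <= 1.0).all()

    def test_intensity_conservation_noiseless(self, sim, acq):
        """Total added intensity equals the 3D Gaussian integrals."""
        stack, truth = generate_nucleus_stack(sim, acq, 0.2, seed=5,
                                              n_clusters=4, noise=False,
                                              mol_noise=False)
        bg, _ = generate_nucleus_stack(sim, acq, 0.2, seed=5, n_clusters=0,
                                       noise=False, mol_noise=False)
        added = stack["tf"].sum() - bg["tf"].sum()
        vxy = acq.voxel_xy_nm
        expected = 0.0
        for _, c in truth.clusters.iterrows():
            s1, s2 = c.sigma1_nm / vxy, c.sigma2_nm / vxy
            sz = c.sigma_z_nm / acq.voxel_z_nm
            expected += 2 * np.pi * c.Ia * s1 * s2 * np.sqrt(2 * np.pi) * sz
        assert added == pytest.approx(expected, rel=0.02)


class TestEmbryoField:
    def test_noiseless_gradient_recovers_lambda_exactly(self, sim):
        df = sample_gradient_field(sim, 100, (0.1, 0.7), seed=0, cv_inuc=0.0)
        slope = np.polyfit(df["x_over_L"], np.log(df["Inuc"]), 1)[0]
        assert -1 / slope == pytest.approx(sim.lambda_gradient, rel=1e-9)

    def test_noisy_gradient_lambda_within_ten_percent(self, sim):
        df = sample_gradient_field(sim, 200, (0.1, 0.7), seed=1, cv_inuc=0.14)
        slope = np.polyfit(df["x_over_L"], np.log(df["Inuc"]), 1)[0]
        assert -1 / slope == pytest.approx(sim.lambda_gradient, rel=0.10)

    def test_zero_nuclei_rejected(self, sim, acq):
        with pytest.raises(ValueError):
            generate_embryo_field(sim, acq, 0, (0.1, 0.7), seed=0)

    def test_empty_x_range_rejected(self, sim):
        with pytest.raises(ValueError):
            sample_gradient_field(sim, 10, (0.5, 0.5), seed=0)

    def test_rendered_field_uses_field_inuc(self, sim, coarse_acq):
        stacks, truth = generate_embryo_field(sim, coarse_acq, 2, (0.2, 0.4),
                                              seed=2, render=True,
                                              n_clusters=0)
        assert len(stacks) == 2
        assert len(truth.nuclei) == 2


class TestTimelapse:
    def test_infinite_ton_always_on(self, rng):
        tr = simulate_telegraph_trace(rng, np.inf, 1.6, 60, 0.497)
        assert tr.all()

    def test_occupancy_matches_closed_form(self, sim, acq):
        rng = np.random.default_rng(0)
        occ = np.mean([simulate_telegraph_trace(rng, sim.ton_s, sim.toff_s,
                                                60, acq.frame_time_s).mean()
                       for _ in range(400)])
        p = sim.ton_s / (sim.ton_s + sim.toff_s)
        assert occ == pytest.approx(p, abs=0.02)

    def test_fixed_seed_identical_traces(self, sim, acq):
        _, t1 = generate_timelapse(sim, acq, 20, seed=4, n_clusters=3)
        _, t2 = generate_timelapse(sim, acq, 20, seed=4, n_clusters=3)
        np.testing.assert_array_equal(t1.traces, t2.traces)

    def test_too_few_frames_rejected(self, sim, acq):
        with pytest.raises(ValueError):
            generate_timelapse(sim, acq, 1, seed=0)


class TestTwoChannel:
    def test_full_coupling_places_nearest_inside_r0(self, sim, acq):
        for s in range(5):
            _, truth = generate_two_channel(sim, acq, "target-strong", seed=s,
                                            coupling_fraction=1.0,
                                            n_clusters=8, noise=False)
            h = truth.hotspots.iloc[0]
            c = truth.clusters
            vz, vxy = acq.voxel_z_nm / 1000, acq.voxel_xy_nm / 1000
            d = np.sqrt(((c.z_px - h.z_px) * vz) ** 2
                        + ((c.y_px - h.y_px) * vxy) ** 2
                        + ((c.x_px - h.x_px) * vxy) ** 2)
            assert d.min() < sim.accumulation_radius_r0_um

    def test_planted_coupling_fraction_recovered(self, sim):
        df = sample_coupling_distances(sim, 400, seed=9, coupling_fraction=0.57)
        frac = (df["distance_um"] < sim.accumulation_radius_r0_um).mean()
        assert frac == pytest.approx(df["coupled"].mean(), abs=1e-12)
        se = np.sqrt(0.57 * 0.43 / 400)
        assert abs(frac - 0.57) < 3 * se

    def test_unknown_mode_rejected(self, sim, acq):
        with pytest.raises(ValueError):
            generate_two_channel(sim, acq, "bogus", seed=0)


class TestPointPattern:
    def test_zero_rho_prime_is_pure_poisson(self):
        from clustersense.correlation import disk_window
        win = disk_window(2.5, 0.043)
        pts, _ = generate_point_pattern(3.0, 0.0, 0.37, 0, win, 0.043, seed=0)
        area = win.sum() * 0.043 ** 2
        assert abs(len(pts) / area - 3.0) < 3 * np.sqrt(3.0 / area)

    def test_zero_clumps_equals_zero_rho_prime(self):
        from clustersense.correlation import disk_window
        win = disk_window(2.5, 0.043)
        p1, _ = generate_point_pattern(3.0, 8.0, 0.37, 0, win, 0.043, seed=5)
        p2, _ = generate_point_pattern(3.0, 0.0, 0.37, 3, win, 0.043, seed=5)
        np.testing.assert_allclose(p1, p2)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            generate_point_pattern(1.0, 0.0, 0.37, 0,
                                   np.zeros((10, 10), bool), 0.043, seed=0)

    def test_infeasible_clump_density_rejected(self):
        from clustersense.correlation import disk_window
        win = disk_window(2.5, 0.043)
        with pytest.raises(ValueError, match="infeasible"):
            generate_point_pattern(2.0, 8.0, 0.37, 50, win, 0.043, seed=0)


class TestBeadField:
    def test_minimum_separation_contract(self, acq):
        stack, truth = generate_bead_field(acq, 15, seed=2)
        pts = truth.points
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        d[np.diag_indices(len(pts))] = np.inf
        assert d.min() >= 3 * 2.355 * acq.psf_sigma_lateral_px - 1e-9

    def test_single_noiseless_bead_is_radially_symmetric(self, acq):
        stack, truth = generate_bead_field(acq, 1, seed=0, noise=False)
        img = stack["beads"]
        y0, x0 = truth.points[0, 1], truth.points[0, 0]
        yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        r = np.hypot(yy - y0, xx - x0)
        ring = (r > 2) & (r < 2.5)
        vals = img[ring]
        assert vals.std() / vals.mean() < 0.05

    def test_needs_at_least_one_bead(self, acq):
        with pytest.raises(ValueError):
            generate_bead_field(acq, 0, seed=0)
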