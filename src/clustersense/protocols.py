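"""End-to-end measurement protocols on paper-calibrated synthetic data.

Each function generates its own synthetic inputs with the calibrated
presets, runs the corresponding analysis chain, and returns the headline
quantity plus context. These are the reproducible "experiments" of the
package: the worked molecule budget, the gradient decay constant and
positional error, population cluster-size recovery through the full
detect-and-fit chain, the PSF-limited pixel-correlation length, and the
confinement radius of projected-maxima point patterns.

Problem sizes default to desk scale (seconds to a few minutes on one
core); all randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.ndimage import binary_erosion

from . import clusters as cl
from . import correlation as corr
from . import gradient, synthetic
from .params import paper_preset


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed).spawn(n)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]


def molecule_budget_protocol() -> dict:
    """The worked absolute-count example: flat-line count to budget chain."""
    budget = gradient.molecule_budget(n0_flat=8000.0, lam_over_L=0.2)
    return dataclasses.asdict(budget)


def gradient_protocol(seed: int, *, n_nuclei: int = 400,
                      x_range: tuple[float, float] = (0.10, 0.65),
                      n_boot: int = 300) -> dict:
    """Decay constants and positional error from a statistical field.

    Samples per-nucleus Inuc and mean cluster intensity Ic along the
    gradient with the calibrated decay constants and CVs, bins by x/L,
    fits ln(mean) vs x/L, and propagates the per-bin CV through
    sigma_x/L = CV * lambda.
    """
    sim, _ = paper_preset()
    field = synthetic.sample_gradient_field(sim, n_nuclei, x_range, seed)
    edges = np.arange(x_range[0], x_range[1] + 1e-9, 0.05)
    table = gradient.bin_and_bootstrap(field, ["Inuc", "Ic"], bin_edges=edges,
                                       n_boot=n_boot, seed=seed + 1)
    out = {"n_nuclei": n_nuclei}
    for q in ("Inuc", "Ic"):
        fit = gradient.fit_gradient(table, q)
        _, sx_mean, sx_sd = gradient.positional_error(table[f"{q}_cv"], fit.lam)
        out[q] = {"lambda": fit.lam, "lambda_err": fit.lam_err,
                  "cv_mean": float(np.nanmean(table[f"{q}_cv"])),
                  "sigma_x_pct_L": 100 * sx_mean,
                  "sigma_x_sd_pct_L": 100 * sx_sd,
                  "r_squared": fit.r_squared}
    return out


def size_recovery_protocol(seed: int, *, n_nuclei: int = 200,
                           clusters_per_nucleus: int = 10,
                           percentile: float = 92.0,
                           x_over_L: float = 0.15) -> dict:
    """Population cluster-size recovery through detection and fitting.

    Renders nuclei with planted clusters at the calibrated size preset
    (kept sparse so fitting windows rarely overlap), runs the 3D
    detector and per-cluster 2D Gaussian fits, and compares the mean
    recovered size d = sqrt(sigma1^2 + sigma2^2) with the planted mean.
    The selection percentile is set from the expected spot coverage of
    these nuclei rather than the 1% suited to sparser real data.
    """
    sim, acq = paper_preset()
    seeds = _child_seeds(seed, n_nuclei)
    fit_d, planted = [], []
    n_detected = 0
    for s in seeds:
        stack, truth = synthetic.generate_nucleus_stack(
            sim, acq, x_over_L, s, n_clusters=clusters_per_nucleus)
        recs = cl.quantify_nucleus(stack["tf"], truth.extras["nucleus_mask"],
                                   acq, percentile=percentile,
                                   inuc=float(truth.nuclei["Inuc"].iloc[0]))
        n_detected += len(recs)
        fit_d.extend(r.d_um * 1000 for r in recs if r.accepted)
        planted.extend(truth.clusters["d_nm"])
    fit_d = np.asarray(fit_d)
    planted = np.asarray(planted)
    return {"n_planted": int(planted.size), "n_detected": int(n_detected),
            "n_accepted": int(fit_d.size),
            "planted_mean_nm": float(planted.mean()),
            "planted_sd_nm": float(planted.std(ddof=1)),
            "recovered_mean_nm": float(fit_d.mean()),
            "recovered_sd_nm": float(fit_d.std(ddof=1)),
            "recovered_se_nm": float(fit_d.std(ddof=1) / math.sqrt(fit_d.size))}


def psf_correlation_protocol(seed: int, *, n_nuclei: int = 30,
                             erode_px: int = 10, max_lag: int = 25) -> dict:
    """Pixel-correlation length of homogeneous PSF-blurred nuclei.

    Nuclei rendered without clusters carry only PSF-correlated molecular
    speckle plus detection noise. The lagged autocorrelation is computed
    on the equatorial plane inside the nuclear mask eroded past the rim
    ramp, curves are averaged across nuclei, and one exponential fit
    (from lag 1, excluding the white-noise nugget at lag 0) yields the
    correlation length.
    """
    sim, acq = paper_preset()
    seeds = _child_seeds(seed, n_nuclei)
    curves = []
    for s in seeds:
        stack, truth = synthetic.generate_nucleus_stack(sim, acq, 0.2, s,
                                                        n_clusters=0)
        img = stack["tf"]
        mask = truth.extras["nucleus_mask"]
        z = img.shape[0] // 2
        m = binary_erosion(mask[z], iterations=erode_px)
        if m.sum() < 400:
            continue
        curves.append(corr.pixel_autocorrelation(
            img[z], m, max_lag=max_lag, voxel_nm=acq.voxel_xy_nm).value)
    mean_c = np.mean(curves, axis=0)
    lags = np.arange(max_lag + 1)
    curve = corr.CorrelationCurve(lag_px=lags, lag_nm=lags * acq.voxel_xy_nm,
                                  value=mean_c, value_x=mean_c, value_y=mean_c,
                                  n_samples=np.full(max_lag + 1, len(curves)))
    fit = corr.fit_correlation_length(curve, lag_min_px=1, lag_max_px=max_lag)
    return {"n_nuclei": len(curves), "lambda_corr_um": fit.lambda_corr / 1000,
            "sigma_lambda_um": fit.sigma_lambda / 1000,
            "psf_sigma_nm": acq.psf_sigma_lateral_nm}


def xi_pair_protocol(seed: int, *, n_maps: int = 30, rho_background: float = 2.0,
                     n_clumps: int = 3, r_max_um: float = 1.8) -> dict:
    """Confinement radius from pair correlation of projected maxima maps.

    Each map emulates the 60-frame time projection of maxima in one
    nuclear cross-section: a Poisson scatter plus Gaussian confinement
    clumps at the calibrated pair-correlation width and relative peak
    density. The FFT estimator with window edge correction is averaged
    across maps and fitted with the Gaussian-clump model.
    """
    sim, acq = paper_preset()
    px = acq.voxel_xy_nm / 1000
    window = corr.disk_window(sim.nucleus_diameter_um / 2, px)
    seeds = _child_seeds(seed, n_maps)
    pcs = []
    for s in seeds:
        pts, _ = synthetic.generate_point_pattern(
            rho_background, sim.rho_prime, sim.xi_pair_um, n_clumps,
            window, px, seed=s)
        pcs.append(corr.pair_correlation_map(pts, window, px,
                                             r_max_um=r_max_um + 0.3))
    avg = corr.average_pair_correlations(pcs)
    fit = corr.fit_pair_correlation(avg, r_max_um=r_max_um)
    return {"n_maps": n_maps, "xi_pair_nm": fit.sigma_um * 1000,
            "rho_prime": fit.rho_prime,
            "planted_sigma_nm": sim.xi_pair_um * 1000,
            "planted_rho_prime": sim.rho_prime}


def persistence_protocol(seed: int, *, n_areas: int = 200,
                         n_frames: int = 60) -> dict:
    """Telegraph dwell-time recovery from presence traces.

    Simulates per-area two-state blinking at the calibrated dwell means
    and recovers Ton/Toff and the detection probability from censored
    run lengths, exactly as the video analysis does downstream of maxima
    projection.
    """
    from .maxima import persistence_stats

    sim, acq = paper_preset()
    rng = np.random.default_rng(seed)
    traces = np.array([
        synthetic.simulate_telegraph_trace(rng, sim.ton_s, sim.toff_s,
                                           n_frames, acq.frame_time_s)
        for _ in range(n_areas)])
    stats = persistence_stats(traces, acq.frame_time_s)
    return {"ton_s": stats.ton_s, "toff_s": stats.toff_s,
            "ton_corrected_s": stats.ton_corrected_s,
            "toff_corrected_s": stats.toff_corrected_s,
            "detection_probability": stats.detection_probability,
            "p_from_dwell": stats.p_from_dwell,
            "planted_ton_s": sim.ton_s, "planted_toff_s": sim.toff_s}
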