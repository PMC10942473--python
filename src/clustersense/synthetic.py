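"""Seeded synthetic-embryo generators with ground truth.

Every generator emulates a statistical feature of live-embryo
transcription-factor imaging so that each downstream analysis stage has a
known-truth oracle:

* single nuclei with an exponential anterior-posterior intensity gradient
  and planted anisotropic 3D Gaussian clusters whose count and amplitude
  scale with nuclear intensity while their size does not;
* whole-field statistical samples of the gradient (no rendering) for the
  precision analyses;
* multi-nucleus stacks ("filled" and "hollow" contrast) for segmentation;
* 2D time-lapse videos with telegraph-blinking clusters;
* two-channel stacks with a nascent-transcription hotspot and a tunable
  cluster-gene coupling fraction;
* clumped point patterns and sub-resolution bead fields for the
  correlation estimators.

Randomness: each generator call consumes one ``numpy`` Generator seeded
from the ``seed`` argument; multi-object generators split the seed with
``SeedSequence(seed).spawn(n)`` so object i is reproducible independently.

Cluster sizes are parameterized as *imaged* (PSF-convolved) widths: the
rendered pre-blur Gaussian width is the quadrature difference of the
target width and the PSF sigma, so fitting the blurred image recovers the
configured size distribution. The effective lower size bound is therefore
the PSF-limited width sqrt(2)*psf_sigma when that exceeds the nominal
floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .params import AcquisitionParams, EmbryoSimParams


@dataclass
class ImageStack:
    """Multi-channel voxel grid with physical metadata.

    ``channels`` maps channel name to an array: (z, y, x) for 3D stacks,
    (t, y, x) for time-lapse, (y, x) for single planes. Intensities are
    non-negative by construction.
    """

    channels: dict[str, np.ndarray]
    acq: AcquisitionParams

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class GroundTruth:
    """Planted truth accompanying a synthetic stack or field."""

    seed: int
    nuclei: pd.DataFrame | None = None
    clusters: pd.DataFrame | None = None
    hotspots: pd.DataFrame | None = None
    traces: np.ndarray | None = None          # (n_clusters, n_frames) bool
    confinement_centers: np.ndarray | None = None
    points: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sampling helpers


def truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                     lower: float, size: int) -> np.ndarray:
    """Rejection-sampled normal draws truncated below at ``lower``."""
    if lower >= mean + 6 * sd:
        raise ValueError("truncation bound too far above the mean")
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[draw > lower]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def truncated_lognormal(rng: np.random.Generator, mean: float, sd: float,
                        lower: float, size: int) -> np.ndarray:
    """Lognormal with the given (arithmetic) mean/sd, redrawn above ``lower``.

    The right-skewed shape matches observed size histograms whose left
    tail vanishes at the diffraction limit; with the defaults only a few
    percent of the mass sits below the floor, so the realized moments
    track the nominal ones closely.
    """
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, math.sqrt(s2), size=2 * (size - filled) + 8)
        draw = draw[draw > lower]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def sample_cluster_population(sim: EmbryoSimParams, acq: AcquisitionParams,
                              rng: np.random.Generator, n: int,
                              ibg: float) -> pd.DataFrame:
    """Draw imaged cluster shape/amplitude parameters for ``n`` clusters.

    Sizes (d = sqrt(sigma1^2 + sigma2^2), nm) follow a right-skewed
    lognormal with the configured mean/sd, floored at the larger of the
    nominal cutoff and the PSF-limited width; draws are independent of
    the amplitude ratio. sigma1 >= sigma2 with a random eccentricity
    whose lower bound keeps the minor axis at or above the PSF sigma
    (an imaged width cannot be narrower than the PSF), and rotation
    theta in (0, pi/4).
    """
    psf = acq.psf_sigma_lateral_nm
    floor = max(sim.d_floor_nm, math.sqrt(2.0) * psf * 1.02)
    d = truncated_lognormal(rng, sim.d_mean_nm, sim.d_sd_nm, floor, n)
    # minor axis sigma2 = d*e/sqrt(1+e^2) must stay >= psf sigma
    with np.errstate(invalid="ignore"):
        e_min = psf / np.sqrt(np.clip(d ** 2 - psf ** 2, 1e-6, None))
    e_lo = np.clip(np.maximum(0.6, e_min * 1.01), None, 0.995)
    ecc = rng.uniform(e_lo, 1.0)
    sigma1 = d / np.sqrt(1.0 + ecc ** 2)
    sigma2 = ecc * sigma1
    theta = rng.uniform(1e-3, np.pi / 4 - 1e-3, size=n)
    ratio = truncated_normal(rng, sim.amp_ratio_mean, sim.amp_ratio_sd, 0.05, n)
    return pd.DataFrame({
        "d_nm": d, "sigma1_nm": sigma1, "sigma2_nm": sigma2,
        "theta": theta, "amp_ratio": ratio, "Ia": ratio * ibg,
        "Ibg": np.full(n, float(ibg)),
    })


def _rotated_gaussian_2d(yy, xx, y0, x0, s1, s2, theta):
    """Unit-amplitude anisotropic Gaussian on a pixel grid (sigmas in px)."""
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - x0) * ct + (yy - y0) * st
    yr = -(xx - x0) * st + (yy - y0) * ct
    return np.exp(-0.5 * ((xr / s1) ** 2 + (yr / s2) ** 2))


def _add_cluster(field3d: np.ndarray, zc: float, yc: float, xc: float,
                 amp: float, s1_px: float, s2_px: float, sz_px: float,
                 theta: float) -> None:
    """Add one anisotropic 3D Gaussian in a local window (in place).

    The axial profile is integrated over each voxel slab (erf difference)
    so that total intensity is conserved even when the axial sigma is a
    fraction of the slice thickness; peak semantics are preserved for
    well-resolved widths.
    """
    from scipy.special import erf

    nz, ny, nx = field3d.shape
    hxy = int(np.ceil(4 * max(s1_px, s2_px)))
    hz = int(np.ceil(4 * sz_px)) + 1
    z0, z1 = max(0, int(zc) - hz), min(nz, int(zc) + hz + 1)
    y0, y1 = max(0, int(yc) - hxy), min(ny, int(yc) + hxy + 1)
    x0, x1 = max(0, int(xc) - hxy), min(nx, int(xc) + hxy + 1)
    if z1 <= z0 or y1 <= y0 or x1 <= x0:
        return
    zz = np.arange(z0, z1, dtype=float)[:, None, None]
    yy = np.arange(y0, y1, dtype=float)[None, :, None]
    xx = np.arange(x0, x1, dtype=float)[None, None, :]
    lat = _rotated_gaussian_2d(yy, xx, yc, xc, s1_px, s2_px, theta)
    s = math.sqrt(2.0) * sz_px
    slab = 0.5 * (erf((zz + 0.5 - zc) / s) - erf((zz - 0.5 - zc) / s))
    ax = slab * math.sqrt(2 * math.pi) * sz_px
    field3d[z0:z1, y0:y1, x0:x1] += amp * ax * lat


def apply_detection_noise(img: np.ndarray, acq: AcquisitionParams,
                          rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise on photon counts plus Gaussian read noise."""
    photons = np.clip(img, 0, None) / acq.photon_scale
    noisy = rng.poisson(photons).astype(float) * acq.photon_scale
    noisy += rng.normal(0.0, acq.noise_read_sd, size=img.shape)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# single-nucleus stack


def generate_nucleus_stack(sim: EmbryoSimParams, acq: AcquisitionParams,
                           x_over_L: float, seed: int, *,
                           n_clusters: int | None = None,
                           inuc: float | None = None,
                           noise: bool = True, mol_noise: bool = True,
                           cytoplasm_fraction: float = 0.25,
                           pad_px: int = 10, pad_z: int = 4
                           ) -> tuple[ImageStack, GroundTruth]:
    """One spherical nucleus with planted 3D Gaussian clusters.

    The nuclear background is Inuc = I0*exp(-x/lambda) (unless overridden),
    the cluster count is Poisson with mean linear in Inuc, cluster
    amplitudes are Ia = ratio*Ibg with ratio truncated-normal, and sizes
    are drawn independently of Inuc. The emitter field (optionally with
    multiplicative white "molecular" speckle) is blurred by the Gaussian
    PSF and then corrupted by shot and read noise.
    """
    if not 0 <= x_over_L <= 1:
        raise ValueError("x_over_L must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    r_px = (sim.nucleus_diameter_um * 1000 / 2) / acq.voxel_xy_nm
    r_z = (sim.nucleus_diameter_um * 1000 / 2) / acq.voxel_z_nm
    nxy = int(np.ceil(2 * r_px)) + 2 * pad_px
    nz = int(np.ceil(2 * r_z)) + 2 * pad_z
    cz, cy, cx = (nz - 1) / 2, (nxy - 1) / 2, (nxy - 1) / 2

    if inuc is None:
        inuc = sim.I0_anterior * math.exp(-x_over_L / sim.lambda_gradient)

    zz = ((np.arange(nz) - cz) / r_z) ** 2
    yy = ((np.arange(nxy) - cy) / r_px) ** 2
    xx = ((np.arange(nxy) - cx) / r_px) ** 2
    nucleus_mask = zz[:, None, None] + yy[None, :, None] + xx[None, None, :] <= 1.0

    emitters = np.where(nucleus_mask, float(inuc), cytoplasm_fraction * inuc)

    if n_clusters is None:
        n_clusters = int(rng.poisson(sim.mean_cluster_count(inuc)))
    pop = sample_cluster_population(sim, acq, rng, n_clusters, ibg=inuc)

    # uniform positions inside the nucleus, kept away from the surface so
    # the full cluster profile stays inside its nucleus
    margin = pop["d_nm"].to_numpy() / 2 / (sim.nucleus_diameter_um * 1000 / 2)
    u = rng.random(n_clusters) ** (1 / 3) * np.clip(1 - margin - 0.05, 0.05, None)
    costh = rng.uniform(-1, 1, n_clusters)
    phi = rng.uniform(0, 2 * np.pi, n_clusters)
    sinth = np.sqrt(1 - costh ** 2)
    zc = cz + u * costh * r_z
    yc = cy + u * sinth * np.sin(phi) * r_px
    xc = cx + u * sinth * np.cos(phi) * r_px

    psf_lat, psf_ax = acq.psf_sigma_lateral_nm, acq.psf_sigma_axial_nm
    axial_ratio = psf_ax / psf_lat
    truth_rows = []
    for i in range(n_clusters):
        s1, s2 = pop.at[i, "sigma1_nm"], pop.at[i, "sigma2_nm"]
        s1i = math.sqrt(max(s1 ** 2 - psf_lat ** 2, 1.0))
        s2i = math.sqrt(max(s2 ** 2 - psf_lat ** 2, 1.0))
        # axial extent scales the intrinsic lateral width by the PSF
        # anisotropy; the imaged axial width adds the axial PSF in
        # quadrature and therefore never falls below it
        szi = 0.5 * (s1i + s2i) * axial_ratio
        sz = math.sqrt(szi ** 2 + psf_ax ** 2)
        amp_i = pop.at[i, "Ia"] * (s1 * s2 * sz) / (s1i * s2i * szi)
        _add_cluster(emitters, zc[i], yc[i], xc[i], amp_i,
                     s1i / acq.voxel_xy_nm, s2i / acq.voxel_xy_nm,
                     szi / acq.voxel_z_nm, pop.at[i, "theta"])
        truth_rows.append({
            "z_px": zc[i], "y_px": yc[i], "x_px": xc[i],
            "Ia": pop.at[i, "Ia"], "Ibg": float(inuc),
            "sigma1_nm": s1, "sigma2_nm": s2, "sigma_z_nm": sz,
            "theta": pop.at[i, "theta"], "d_nm": pop.at[i, "d_nm"],
            "amp_ratio": pop.at[i, "amp_ratio"],
        })

    if mol_noise and sim.mol_noise_cv > 0:
        emitters *= 1.0 + sim.mol_noise_cv * rng.standard_normal(emitters.shape)
        emitters = np.clip(emitters, 0.0, None)

    img = gaussian_filter(emitters, sigma=(acq.psf_sigma_axial_px,
                                           acq.psf_sigma_lateral_px,
                                           acq.psf_sigma_lateral_px))
    if noise:
        img = apply_detection_noise(img, acq, rng)

    nuc = pd.DataFrame([{"label": 1, "z_px": cz, "y_px": cy, "x_px": cx,
                         "radius_px": r_px, "radius_z_px": r_z,
                         "Inuc": float(inuc), "x_over_L": float(x_over_L)}])
    clusters = pd.DataFrame(truth_rows) if truth_rows else pd.DataFrame(
        columns=["z_px", "y_px", "x_px", "Ia", "Ibg", "sigma1_nm", "sigma2_nm",
                 "sigma_z_nm", "theta", "d_nm", "amp_ratio"])
    truth = GroundTruth(seed=seed, nuclei=nuc, clusters=clusters,
                        extras={"nucleus_mask": nucleus_mask})
    return ImageStack({"tf": img}, acq), truth


# ---------------------------------------------------------------------------
# statistical embryo field


def sample_gradient_field(sim: EmbryoSimParams, n_nuclei: int,
                          x_range: tuple[float, float], seed: int, *,
                          cv_inuc: float | None = None,
                          cv_ic: float | None = None) -> pd.DataFrame:
    """Per-nucleus gradient statistics without image rendering.

    Returns one row per nucleus with its position, nuclear intensity
    Inuc = I0*exp(-x/lambda) times multiplicative log-normal noise of the
    configured CV, the per-nucleus mean integrated cluster intensity Ic
    (its own decay constant and CV), and a Poisson cluster count whose
    mean is linear in Inuc.
    """
    if n_nuclei < 2:
        raise ValueError("need at least 2 nuclei")
    lo, hi = x_range
    if not (0 <= lo < hi <= 1):
        raise ValueError("x_range must be a nonempty subinterval of [0, 1]")
    rng = np.random.default_rng(seed)
    cvi = sim.cv_inuc if cv_inuc is None else cv_inuc
    cvc = sim.cv_ic if cv_ic is None else cv_ic

    x = rng.uniform(lo, hi, size=n_nuclei)
    inuc_det = sim.I0_anterior * np.exp(-x / sim.lambda_gradient)
    inuc = inuc_det * _lognormal_factor(rng, cvi, n_nuclei)
    ic0 = sim.I0_anterior * 0.25  # arbitrary intensity scale for mean Ic
    ic_det = ic0 * np.exp(-x / sim.lambda_ic)
    ic = ic_det * _lognormal_factor(rng, cvc, n_nuclei)
    counts = rng.poisson(np.clip(sim.mean_cluster_count(inuc), 0, None))
    return pd.DataFrame({"x_over_L": x, "Inuc": inuc, "Ic": ic,
                         "n_clusters": counts})


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested CV."""
    if cv <= 0:
        return np.ones(n)
    s2 = math.log(1 + cv ** 2)
    return rng.lognormal(mean=-s2 / 2, sigma=math.sqrt(s2), size=n)


def generate_embryo_field(sim: EmbryoSimParams, acq: AcquisitionParams,
                          n_nuclei: int, x_range: tuple[float, float],
                          seed: int, *, render: bool = False,
                          cv_inuc: float | None = None,
                          **nucleus_kwargs
                          ) -> tuple[list[ImageStack], GroundTruth]:
    """Nuclei along the gradient; optionally rendered as one stack each.

    With ``render=False`` (the default for statistical work) the stack
    list is empty and only the ground-truth table is produced. Rendered
    nuclei use per-nucleus child seeds of ``seed``.
    """
    table = sample_gradient_field(sim, n_nuclei, x_range, seed,
                                  cv_inuc=cv_inuc)
    stacks: list[ImageStack] = []
    cluster_tables = []
    if render:
        children = np.random.SeedSequence(seed).spawn(n_nuclei)
        for i in range(n_nuclei):
            child_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
            stack, truth = generate_nucleus_stack(
                sim, acq, float(table.at[i, "x_over_L"]), child_seed,
                inuc=float(table.at[i, "Inuc"]), **nucleus_kwargs)
            stacks.append(stack)
            t = truth.clusters.copy()
            t["nucleus"] = i
            cluster_tables.append(t)
    clusters = pd.concat(cluster_tables, ignore_index=True) if cluster_tables else None
    return stacks, GroundTruth(seed=seed, nuclei=table, clusters=clusters)


# ---------------------------------------------------------------------------
# multi-nucleus stack for segmentation


def generate_multinucleus_stack(sim: EmbryoSimParams, acq: AcquisitionParams,
                                n_nuclei: int, seed: int, *,
                                mode: Literal["filled", "hollow"] = "filled",
                                inuc: float = 200.0, jitter_frac: float = 0.15,
                                noise: bool = True
                                ) -> tuple[ImageStack, GroundTruth]:
    """Field of spherical nuclei on a jittered hexagonal grid.

    ``filled`` renders bright nuclei on a dim background (TF channel);
    ``hollow`` renders dark nuclei surrounded by bright interstitial
    signal (coat-protein channel). Identical geometry for both modes under
    the same seed, which twin-rendering tests rely on.
    """
    if n_nuclei < 1:
        raise ValueError("need at least one nucleus")
    rng = np.random.default_rng(seed)
    r_px = (sim.nucleus_diameter_um * 1000 / 2) / acq.voxel_xy_nm
    r_z = (sim.nucleus_diameter_um * 1000 / 2) / acq.voxel_z_nm
    pitch = 2.6 * r_px
    ncols = int(np.ceil(np.sqrt(n_nuclei)))
    nrows = int(np.ceil(n_nuclei / ncols))
    ny = int((nrows + 0.5) * pitch + 2 * r_px)
    nx = int((ncols + 1.0) * pitch + 2 * r_px)
    nz = int(2 * r_z) + 8
    cz = (nz - 1) / 2

    centers = []
    k = 0
    for i in range(nrows):
        for j in range(ncols):
            if k >= n_nuclei:
                break
            y = (i + 0.75) * pitch + r_px * 0.5
            x = (j + 0.75) * pitch + (pitch / 2 if i % 2 else 0)
            y += rng.uniform(-1, 1) * jitter_frac * r_px
            x += rng.uniform(-1, 1) * jitter_frac * r_px
            centers.append((cz, y, x))
            k += 1
    centers = np.array(centers)

    zz = (np.arange(nz)[:, None, None] - cz) / r_z
    yy = np.arange(ny)[None, :, None]
    xx = np.arange(nx)[None, None, :]
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    for lab, (_, yc, xc) in enumerate(centers, start=1):
        d2 = zz ** 2 + ((yy - yc) / r_px) ** 2 + ((xx - xc) / r_px) ** 2
        labels[d2 <= 1.0] = lab
    inside = labels > 0

    if mode == "filled":
        emitters = np.where(inside, inuc, 0.25 * inuc)
    else:
        emitters = np.where(inside, 0.25 * inuc, inuc)
    emitters = emitters * (1.0 + 0.08 * rng.standard_normal(emitters.shape))
    emitters = np.clip(emitters, 0, None)
    img = gaussian_filter(emitters, sigma=(acq.psf_sigma_axial_px,
                                           acq.psf_sigma_lateral_px,
                                           acq.psf_sigma_lateral_px))
    if noise:
        img = apply_detection_noise(img, acq, rng)

    nuc = pd.DataFrame({"label": np.arange(1, len(centers) + 1),
                        "z_px": centers[:, 0], "y_px": centers[:, 1],
                        "x_px": centers[:, 2],
                        "radius_px": r_px, "radius_z_px": r_z,
                        "Inuc": inuc})
    truth = GroundTruth(seed=seed, nuclei=nuc, extras={"labels": labels})
    return ImageStack({mode: img}, acq), truth


# ---------------------------------------------------------------------------
# time-lapse with telegraph blinking


def simulate_telegraph_trace(rng: np.random.Generator, ton_s: float,
                             toff_s: float, n_frames: int,
                             frame_time_s: float) -> np.ndarray:
    """Two-state telegraph presence trace sampled at frame times.

    Dwell times are exponential with means ``ton_s`` / ``toff_s``; the
    initial state is drawn from the stationary occupancy ton/(ton+toff).
    ``ton_s = inf`` yields an always-on trace.
    """
    if math.isinf(ton_s):
        return np.ones(n_frames, dtype=bool)
    total_t = n_frames * frame_time_s
    p_on = ton_s / (ton_s + toff_s)
    state = rng.random() < p_on
    t = 0.0
    times = [0.0]
    states = [state]
    while t < total_t:
        dwell = rng.exponential(ton_s if state else toff_s)
        t += dwell
        state = not state
        times.append(t)
        states.append(state)
    sample_t = np.arange(n_frames) * frame_time_s
    idx = np.searchsorted(times, sample_t, side="right") - 1
    return np.array(states, dtype=bool)[idx]


def generate_timelapse(sim: EmbryoSimParams, acq: AcquisitionParams,
                       n_frames: int, seed: int, *,
                       n_clusters: int = 8, inuc: float = 200.0,
                       noise: bool = True
                       ) -> tuple[ImageStack, GroundTruth]:
    """2D nucleus cross-section video with blinking clusters.

    Clusters sit at fixed confinement centers and blink via independent
    telegraph processes with exponential dwell times (means ton, toff),
    sampled at the acquisition frame time.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    r_px = (sim.nucleus_diameter_um * 1000 / 2) / acq.voxel_xy_nm
    n = int(np.ceil(2 * r_px)) + 16
    c = (n - 1) / 2
    yy, xx = np.mgrid[0:n, 0:n]
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= r_px ** 2

    u = np.sqrt(rng.random(n_clusters)) * 0.8
    ang = rng.uniform(0, 2 * np.pi, n_clusters)
    centers = np.column_stack([c + u * np.sin(ang) * r_px,
                               c + u * np.cos(ang) * r_px])  # (y, x)
    pop = sample_cluster_population(sim, acq, rng, n_clusters, ibg=inuc)
    traces = np.array([
        simulate_telegraph_trace(rng, sim.ton_s, sim.toff_s, n_frames,
                                 acq.frame_time_s)
        for _ in range(n_clusters)])

    frames = np.empty((n_frames, n, n))
    base = np.where(mask, inuc, 0.25 * inuc)
    s1 = pop["sigma1_nm"].to_numpy() / acq.voxel_xy_nm
    s2 = pop["sigma2_nm"].to_numpy() / acq.voxel_xy_nm
    for t in range(n_frames):
        emitters = base * (1 + sim.mol_noise_cv * rng.standard_normal(base.shape))
        emitters = np.clip(emitters, 0, None)
        for i in range(n_clusters):
            if traces[i, t]:
                emitters += pop.at[i, "Ia"] * _rotated_gaussian_2d(
                    yy, xx, centers[i, 0], centers[i, 1],
                    s1[i], s2[i], pop.at[i, "theta"])
        img = gaussian_filter(emitters, acq.psf_sigma_lateral_px)
        frames[t] = apply_detection_noise(img, acq, rng) if noise else img

    truth = GroundTruth(seed=seed, traces=traces,
                        confinement_centers=centers,
                        clusters=pop,
                        extras={"nucleus_mask": mask,
                                "occupancy": traces.mean()})
    return ImageStack({"tf": frames}, acq), truth


# ---------------------------------------------------------------------------
# two-channel (clusters + transcription hotspot)


GeneMode = Literal["target-strong", "target-weak", "nontarget"]

_MODE_PRESETS = {
    # coupling fraction, hotspot intensity scale relative to weak
    "target-strong": {"coupling": None, "intensity_scale": 3.2},
    "target-weak": {"coupling": 0.30, "intensity_scale": 1.0},
    "nontarget": {"coupling": None, "intensity_scale": 1.0},
}


def generate_two_channel(sim: EmbryoSimParams, acq: AcquisitionParams,
                         gene_mode: GeneMode, seed: int, *,
                         x_over_L: float = 0.25,
                         coupling_fraction: float | None = None,
                         noise: bool = True, n_clusters: int | None = None
                         ) -> tuple[ImageStack, GroundTruth]:
    """One nucleus with a TF-cluster channel and an mRNA-hotspot channel.

    The hotspot is a bright 3D Gaussian at a random intranuclear site. With
    probability ``coupling_fraction`` the nearest cluster is planted within
    the accumulation radius r0 of the hotspot, otherwise all clusters are
    kept beyond r0; ``nontarget`` mode places clusters independently of the
    hotspot.
    """
    if gene_mode not in _MODE_PRESETS:
        raise ValueError(f"unknown gene_mode {gene_mode!r}")
    preset = _MODE_PRESETS[gene_mode]
    if coupling_fraction is None:
        coupling_fraction = (sim.coupling_fraction if preset["coupling"] is None
                             else preset["coupling"])

    rng = np.random.default_rng(seed)
    stack, truth = generate_nucleus_stack(sim, acq, x_over_L, seed + 1,
                                          noise=noise, n_clusters=n_clusters)
    nuc = truth.nuclei.iloc[0]
    cz, cy, cx = nuc["z_px"], nuc["y_px"], nuc["x_px"]
    r_px, r_z = nuc["radius_px"], nuc["radius_z_px"]
    vz, vxy = acq.voxel_z_nm / 1000, acq.voxel_xy_nm / 1000  # um per voxel

    # hotspot position well inside the nucleus
    u = rng.random() ** (1 / 3) * 0.6
    costh = rng.uniform(-1, 1)
    phi = rng.uniform(0, 2 * np.pi)
    sinth = math.sqrt(1 - costh ** 2)
    hz = cz + u * costh * r_z
    hy = cy + u * sinth * math.sin(phi) * r_px
    hx = cx + u * sinth * math.cos(phi) * r_px

    clusters = truth.clusters
    r0_um = sim.accumulation_radius_r0_um
    coupled = False
    if gene_mode != "nontarget" and len(clusters):
        dz = (clusters["z_px"] - hz) * vz
        dy = (clusters["y_px"] - hy) * vxy
        dx = (clusters["x_px"] - hx) * vxy
        dist = np.sqrt(dz ** 2 + dy ** 2 + dx ** 2)
        coupled = bool(rng.random() < coupling_fraction)
        if coupled:
            # move the nearest cluster to within r0 of the hotspot
            i = int(np.argmin(dist.to_numpy()))
            rr = r0_um * (0.25 + 0.65 * rng.random())
            ct = rng.uniform(-1, 1)
            ph = rng.uniform(0, 2 * np.pi)
            st = math.sqrt(1 - ct ** 2)
            clusters.loc[clusters.index[i], "z_px"] = hz + rr * ct / vz
            clusters.loc[clusters.index[i], "y_px"] = hy + rr * st * math.sin(ph) / vxy
            clusters.loc[clusters.index[i], "x_px"] = hx + rr * st * math.cos(ph) / vxy
        else:
            # push any cluster inside ~r0 out beyond it, radially
            for i in np.nonzero(dist.to_numpy() < 1.15 * r0_um)[0]:
                rr = r0_um * (1.25 + 1.0 * rng.random())
                ct = rng.uniform(-1, 1)
                ph = rng.uniform(0, 2 * np.pi)
                st = math.sqrt(1 - ct ** 2)
                clusters.loc[clusters.index[i], "z_px"] = hz + rr * ct / vz
                clusters.loc[clusters.index[i], "y_px"] = hy + rr * st * math.sin(ph) / vxy
                clusters.loc[clusters.index[i], "x_px"] = hx + rr * st * math.cos(ph) / vxy
        # re-render the TF channel with the (possibly moved) clusters
        stack = _render_from_truth(truth, sim, acq,
                                   np.random.default_rng(seed + 2),
                                   noise=noise)

    # mRNA channel: dim nucleoplasm, one bright hotspot
    mr_base = 40.0
    hot_amp = 8.0 * mr_base * preset["intensity_scale"]
    mask = truth.extras["nucleus_mask"]
    emitters = np.where(mask, mr_base, 0.6 * mr_base)
    emitters = emitters * (1 + 0.10 * rng.standard_normal(emitters.shape))
    emitters = np.clip(emitters, 0, None)
    _add_cluster(emitters, hz, hy, hx, hot_amp,
                 180.0 / acq.voxel_xy_nm, 180.0 / acq.voxel_xy_nm,
                 280.0 / acq.voxel_z_nm, 0.0)
    mrna = gaussian_filter(emitters, sigma=(acq.psf_sigma_axial_px,
                                            acq.psf_sigma_lateral_px,
                                            acq.psf_sigma_lateral_px))
    if noise:
        mrna = apply_detection_noise(mrna, acq, rng)

    hot = pd.DataFrame([{"z_px": hz, "y_px": hy, "x_px": hx,
                         "amplitude": hot_amp, "coupled": coupled,
                         "r0_um": r0_um, "gene_mode": gene_mode}])
    truth.hotspots = hot
    truth.extras["coupling_fraction"] = coupling_fraction
    return ImageStack({"tf": stack["tf"], "mrna": mrna}, acq), truth


def _render_from_truth(truth: GroundTruth, sim: EmbryoSimParams,
                       acq: AcquisitionParams, rng: np.random.Generator,
                       *, noise: bool = True) -> ImageStack:
    """Re-render a TF channel from a (possibly edited) cluster truth table."""
    mask = truth.extras["nucleus_mask"]
    nuc = truth.nuclei.iloc[0]
    inuc = float(nuc["Inuc"])
    emitters = np.where(mask, inuc, 0.25 * inuc)
    psf_lat, psf_ax = acq.psf_sigma_lateral_nm, acq.psf_sigma_axial_nm
    for _, c in truth.clusters.iterrows():
        s1, s2, sz = c["sigma1_nm"], c["sigma2_nm"], c["sigma_z_nm"]
        s1i = math.sqrt(max(s1 ** 2 - psf_lat ** 2, 1.0))
        s2i = math.sqrt(max(s2 ** 2 - psf_lat ** 2, 1.0))
        szi = math.sqrt(max(sz ** 2 - psf_ax ** 2, 1e-2))
        amp = c["Ia"] * (s1 * s2 * sz) / (s1i * s2i * szi)
        _add_cluster(emitters, c["z_px"], c["y_px"], c["x_px"], amp,
                     s1i / acq.voxel_xy_nm, s2i / acq.voxel_xy_nm,
                     szi / acq.voxel_z_nm, c["theta"])
    if sim.mol_noise_cv > 0:
        emitters = emitters * (1 + sim.mol_noise_cv *
                               rng.standard_normal(emitters.shape))
        emitters = np.clip(emitters, 0, None)
    img = gaussian_filter(emitters, sigma=(acq.psf_sigma_axial_px,
                                           acq.psf_sigma_lateral_px,
                                           acq.psf_sigma_lateral_px))
    if noise:
        img = apply_detection_noise(img, acq, rng)
    return ImageStack({"tf": img}, acq)


def sample_coupling_distances(sim: EmbryoSimParams, n_nuclei: int, seed: int,
                              *, coupling_fraction: float | None = None
                              ) -> pd.DataFrame:
    """Truth-level nearest-cluster distances for many nuclei (no images).

    Coupled hotspots draw a distance within r0, uncoupled ones beyond it,
    mirroring the placement rule of :func:`generate_two_channel`.
    """
    rng = np.random.default_rng(seed)
    f = sim.coupling_fraction if coupling_fraction is None else coupling_fraction
    r0 = sim.accumulation_radius_r0_um
    coupled = rng.random(n_nuclei) < f
    d = np.where(coupled,
                 r0 * (0.25 + 0.65 * rng.random(n_nuclei)),
                 r0 * (1.25 + 1.0 * rng.random(n_nuclei)))
    return pd.DataFrame({"distance_um": d, "coupled": coupled})


# ---------------------------------------------------------------------------
# point patterns and beads


def generate_point_pattern(rho_poisson: float, rho_prime: float,
                           sigma_clump_um: float, n_clumps: int,
                           window: np.ndarray, pixel_size_um: float,
                           seed: int) -> tuple[np.ndarray, GroundTruth]:
    """Poisson background plus Gaussian clumps with a set peak density.

    ``sigma_clump_um`` is the *pair-correlation* Gaussian width: points in
    a clump are scattered with per-axis sd sigma/2, so the planted pattern
    has g(r) = rho_prime * exp(-(r/sigma)^2) + 1 in expectation. The
    points-per-clump mean is solved from (rho_prime, background density,
    clump density); the product of clump density, rho_prime and clump area
    must stay below the feasibility bound.
    """
    if rho_poisson < 0 or rho_prime < 0:
        raise ValueError("densities must be non-negative")
    if sigma_clump_um <= 0:
        raise ValueError("sigma_clump must be positive")
    w = np.asarray(window, dtype=bool)
    area = w.sum() * pixel_size_um ** 2
    if area <= 0:
        raise ValueError("window is empty")
    rng = np.random.default_rng(seed)

    pts = [_uniform_in_window(rng, w, pixel_size_um,
                              rng.poisson(rho_poisson * area))]
    clump_centers = np.empty((0, 2))
    if rho_prime > 0 and n_clumps > 0:
        lam_c = n_clumps / area
        alpha = lam_c / (rho_prime * np.pi * sigma_clump_um ** 2)
        if math.sqrt(alpha) <= lam_c:
            raise ValueError("infeasible clump configuration: reduce clump "
                             "density, rho_prime or sigma")
        n_bar = rho_poisson / (math.sqrt(alpha) - lam_c)
        clump_centers = _uniform_in_window(rng, w, pixel_size_um, n_clumps,
                                           margin_um=2 * sigma_clump_um)
        for cc in clump_centers:
            k = rng.poisson(n_bar)
            offs = rng.normal(0.0, sigma_clump_um / 2, size=(k, 2))
            pts.append(cc + offs)
    points = np.vstack(pts) if pts else np.empty((0, 2))
    points = _clip_to_window(points, w, pixel_size_um)
    truth = GroundTruth(seed=seed, points=points,
                        extras={"clump_centers": clump_centers,
                                "rho_prime": rho_prime,
                                "sigma_clump_um": sigma_clump_um})
    return points, truth


def _uniform_in_window(rng, w, pixel_size_um, n, margin_um=0.0):
    """Uniform points inside a binary window (rejection sampling)."""
    ny, nx = w.shape
    out = np.empty((n, 2))
    filled = 0
    m_px = margin_um / pixel_size_um
    from scipy.ndimage import binary_erosion
    w_eff = w
    if m_px >= 1:
        w_eff = binary_erosion(w, iterations=int(m_px))
        if not w_eff.any():
            w_eff = w
    while filled < n:
        cand = rng.uniform(0, [nx, ny], size=(2 * (n - filled) + 8, 2))
        ix = np.floor(cand[:, 0]).astype(int)
        iy = np.floor(cand[:, 1]).astype(int)
        good = w_eff[iy, ix]
        take = min(good.sum(), n - filled)
        out[filled:filled + take] = cand[good][:take] * pixel_size_um
        filled += take
    return out


def _clip_to_window(points, w, pixel_size_um):
    if points.size == 0:
        return points
    idx = np.floor(points / pixel_size_um).astype(int)
    ny, nx = w.shape
    ok = (idx[:, 0] >= 0) & (idx[:, 0] < nx) & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
    idx = idx[ok]
    points = points[ok]
    return points[w[idx[:, 1], idx[:, 0]]]


def generate_bead_field(acq: AcquisitionParams, n_beads: int, seed: int, *,
                        fov_px: int = 300, amplitude: float = 600.0,
                        background: float = 20.0, noise: bool = True
                        ) -> tuple[ImageStack, GroundTruth]:
    """Sub-resolution point emitters on one plane, blurred by the PSF.

    Beads closer than 3x the PSF FWHM to an already placed bead are
    redrawn, so each spot is isolated for calibration.
    """
    if n_beads < 1:
        raise ValueError("need at least one bead")
    rng = np.random.default_rng(seed)
    min_sep = 3 * 2.355 * acq.psf_sigma_lateral_px
    margin = 4 * acq.psf_sigma_lateral_px
    pos = []
    attempts = 0
    while len(pos) < n_beads:
        cand = rng.uniform(margin, fov_px - margin, size=2)
        if all(np.hypot(*(cand - p)) >= min_sep for p in pos):
            pos.append(cand)
        attempts += 1
        if attempts > 1000 * n_beads:
            raise RuntimeError("could not place beads with the required separation")
    pos = np.array(pos)  # (y, x)

    img = np.full((fov_px, fov_px), float(background))
    yy, xx = np.mgrid[0:fov_px, 0:fov_px]
    s = acq.psf_sigma_lateral_px
    for y0, x0 in pos:
        img += amplitude * np.exp(-(((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s ** 2)))
    if noise:
        img = apply_detection_noise(img, acq, rng)
    truth = GroundTruth(seed=seed, points=pos[:, ::-1],
                        extras={"psf_sigma_px": s})
    return ImageStack({"beads": img}, acq), truth
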