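"""Transcription-hotspot detection and cluster-gene coupling analysis.

Nascent-mRNA hotspots (stem-loop/coat-protein label) are detected per
nucleus with a difference-of-Gaussians enhancement and a mean + 4 sd
nuclear-intensity threshold. Around each hotspot the transcription-factor
channel is ring-averaged into a radial profile; a double-Gaussian fit of
the aggregated profile gives the accumulation radius r0 (FWHM of the
first component). Nearest-cluster distances from hotspot centroids give
the coupling fraction as the empirical CDF at r0, with an alternative
boundary r0' from the crossing of a two-component fit of the distance
histogram.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.measure import label as cc_label, regionprops

from .params import AcquisitionParams

MIN_HOTSPOT_VOXELS = 18


@dataclass
class HotspotRecord:
    nucleus_label: int
    centroid_px: tuple[float, float, float]     # (z, y, x)
    centroid_um: tuple[float, float, float]     # (x, y, z)
    integrated_intensity: float
    voxels: int


@dataclass
class RadialProfile:
    """Ring-averaged TF intensity around hotspot centroids (0.1 um rings)."""

    r_um: np.ndarray          # ring centers
    intensity: np.ndarray
    n_pixels: np.ndarray

    @property
    def ring_width_um(self) -> float:
        return float(self.r_um[1] - self.r_um[0]) if self.r_um.size > 1 else 0.1


@dataclass
class AccumulationFit:
    k0: float
    x0: float
    a0: float
    k1: float
    x1: float
    a1: float
    r0_um: float
    r0_err_um: float
    single_component: bool = False
    unreliable: bool = False


@dataclass
class CouplingResult:
    distances_um: np.ndarray
    r0_um: float
    coupling_fraction: float
    median_um: float
    median_err_um: float


# ---------------------------------------------------------------------------
# hotspot detection


def detect_hotspots(mrna_stack: np.ndarray, nucleus_labels: np.ndarray,
                    acq: AcquisitionParams, *, dog_sigma_px: tuple[float, float] = (1.0, 2.0),
                    k_sigma: float = 4.0, min_voxels: int = MIN_HOTSPOT_VOXELS
                    ) -> list[HotspotRecord]:
    """Detect one-per-nucleus transcription hotspots in the mRNA channel.

    Difference-of-Gaussians enhancement of the raw stack is multiplied
    back onto the raw image (mutual-evidence weighting) and rescaled;
    voxels below mu(Inuc) + ``k_sigma`` * sd(Inuc) of their nucleus are
    discarded, candidate masks smaller than ``min_voxels`` are rejected,
    and intensity-weighted centroids are computed on the raw image.
    """
    img = np.asarray(mrna_stack, dtype=float)
    labels = np.asarray(nucleus_labels)
    if img.shape != labels.shape:
        raise ValueError("stack and label volume shapes differ")
    s1, s2 = dog_sigma_px
    dog = (ndimage.gaussian_filter(img, (s1 / acq.z_anisotropy, s1, s1))
           - ndimage.gaussian_filter(img, (s2 / acq.z_anisotropy, s2, s2)))
    enh = np.clip(dog, 0, None) * img
    if enh.max() > 0:
        enh = enh / enh.max()

    out: list[HotspotRecord] = []
    vz, vxy = acq.voxel_z_nm / 1000, acq.voxel_xy_nm / 1000
    for lab in np.unique(labels):
        if lab == 0:
            continue
        inside = labels == lab
        vals = img[inside]
        thr = vals.mean() + k_sigma * vals.std()
        cand = inside & (img >= thr) & (enh > 0)
        if not cand.any():
            continue
        cc = cc_label(cand)
        for rp in regionprops(cc, intensity_image=img):
            if rp.area < min_voxels:
                continue
            z, y, x = rp.centroid_weighted
            out.append(HotspotRecord(
                nucleus_label=int(lab), centroid_px=(z, y, x),
                centroid_um=(x * vxy, y * vxy, z * vz),
                integrated_intensity=float(rp.intensity_image.sum()),
                voxels=int(rp.area)))
    return out


# ---------------------------------------------------------------------------
# radial profiles


def radial_profile(tf_stack: np.ndarray, hotspot: HotspotRecord,
                   acq: AcquisitionParams, *, r_max_um: float = 1.5,
                   ring_um: float = 0.1,
                   nucleus_mask: np.ndarray | None = None
                   ) -> RadialProfile:
    """Ring-averaged TF intensity on the hotspot's z-plane.

    Averages raw TF intensities in annuli [r, r + ring) around the
    hotspot centroid, restricted to in-nucleus pixels of that plane when
    a mask is supplied. Empty rings yield NaN entries.
    """
    img = np.asarray(tf_stack, dtype=float)
    z = int(round(hotspot.centroid_px[0]))
    z = min(max(z, 0), img.shape[0] - 1)
    plane = img[z]
    vxy = acq.voxel_xy_nm / 1000
    yy, xx = np.mgrid[0:plane.shape[0], 0:plane.shape[1]]
    r = np.hypot(yy - hotspot.centroid_px[1], xx - hotspot.centroid_px[2]) * vxy
    sel = r < r_max_um
    if nucleus_mask is not None:
        sel &= np.asarray(nucleus_mask[z], dtype=bool)
    nbins = int(np.ceil(r_max_um / ring_um))
    idx = np.floor(r[sel] / ring_um).astype(int)
    vals = plane[sel]
    num = np.bincount(idx, weights=vals, minlength=nbins)[:nbins]
    cnt = np.bincount(idx, minlength=nbins)[:nbins]
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = num / cnt
    prof[cnt == 0] = np.nan
    centers = (np.arange(nbins) + 0.5) * ring_um
    return RadialProfile(r_um=centers, intensity=prof, n_pixels=cnt)


def aggregate_profiles(profiles: list[RadialProfile]) -> RadialProfile:
    """Pixel-weighted mean of radial profiles across hotspots/nuclei."""
    nbins = max(p.r_um.size for p in profiles)
    num = np.zeros(nbins)
    cnt = np.zeros(nbins)
    for p in profiles:
        k = p.r_um.size
        m = np.isfinite(p.intensity)
        num[:k][m] += (p.intensity * p.n_pixels)[m]
        cnt[:k][m] += p.n_pixels[m]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = num / cnt
    mean[cnt == 0] = np.nan
    ring = profiles[0].ring_width_um
    return RadialProfile(r_um=(np.arange(nbins) + 0.5) * ring,
                         intensity=mean, n_pixels=cnt)


def fit_accumulation(profile: RadialProfile, *, fwhm_multiplier: float = 1.0
                     ) -> AccumulationFit:
    """Double-Gaussian fit of a radial profile; r0 = FWHM of component 1.

    f(x) = k0 exp(-((x-x0)/a0)^2) + k1 exp(-((x-x1)/a1)^2); the
    accumulation radius is 2 a0 sqrt(ln 2) (the FWHM of the first,
    central component) times ``fwhm_multiplier`` (an alternative
    convention doubles it). Falls back to a single component when the
    two-component fit fails, and flags profiles with no central
    enrichment as unreliable.
    """
    m = np.isfinite(profile.intensity)
    x, y = profile.r_um[m], profile.intensity[m]
    if x.size < 8:
        raise ValueError("need >= 8 radial bins to fit the accumulation model")

    base = float(np.median(y[-3:]))
    amp0 = float(y[0] - base)
    span = float(x[-1] - x[0])

    def two(xx, k0, x0, a0, k1, x1, a1):
        return (k0 * np.exp(-((xx - x0) / a0) ** 2)
                + k1 * np.exp(-((xx - x1) / a1) ** 2))

    p0 = (max(amp0, 1e-3), 0.0, span / 5, max(base, 1e-3), x[-1], span)
    lb = (0, -span / 4, 1e-3, 0, 0, 1e-3)
    ub = (np.inf, span / 2, span, np.inf, 3 * span, 5 * span)
    single = False
    try:
        popt, pcov = optimize.curve_fit(two, x, y, p0=p0, bounds=(lb, ub),
                                        maxfev=20000)
        a0_err = math.sqrt(pcov[2, 2]) if np.isfinite(pcov[2, 2]) else np.nan
    except RuntimeError:
        def one(xx, k0, a0):
            return k0 * np.exp(-(xx / a0) ** 2)
        popt1, pcov1 = optimize.curve_fit(one, x, y - base,
                                          p0=(max(amp0, 1e-3), span / 5),
                                          maxfev=20000)
        popt = (popt1[0], 0.0, popt1[1], base, x[-1], span)
        a0_err = math.sqrt(pcov1[1, 1]) if np.isfinite(pcov1[1, 1]) else np.nan
        single = True
    k0, x0, a0, k1, x1, a1 = popt
    factor = 2 * math.sqrt(math.log(2)) * fwhm_multiplier
    # no central enrichment above the tail noise, or a "component" as wide
    # as the whole profile, means r0 is not meaningful
    tail_sd = float(np.std(y[-max(3, y.size // 3):]))
    unreliable = bool(amp0 < 3 * tail_sd or a0 > 0.9 * span)
    return AccumulationFit(k0=float(k0), x0=float(x0), a0=float(a0),
                           k1=float(k1), x1=float(x1), a1=float(a1),
                           r0_um=float(factor * a0),
                           r0_err_um=float(factor * a0_err),
                           single_component=single,
                           unreliable=bool(unreliable))


# ---------------------------------------------------------------------------
# coupling


def nearest_cluster_distances(hotspots: list[HotspotRecord],
                              clusters_um: pd.DataFrame) -> np.ndarray:
    """3D anisotropy-corrected distance from each hotspot to its nearest
    accepted cluster centroid (um). Hotspots in nuclei without clusters
    are skipped."""
    dists = []
    for h in hotspots:
        sub = clusters_um
        if "nucleus" in clusters_um.columns:
            sub = clusters_um[clusters_um["nucleus"] == h.nucleus_label]
        if "accepted" in sub.columns:
            sub = sub[sub["accepted"]]
        if not len(sub):
            continue
        hx, hy, hz = h.centroid_um
        d = np.sqrt((sub["x_um"] - hx) ** 2 + (sub["y_um"] - hy) ** 2
                    + (sub["z_um"] - hz) ** 2)
        dists.append(float(d.min()))
    return np.asarray(dists)


def coupling_fraction(distances_um: np.ndarray, r0_um: float, *,
                      n_boot: int = 500, seed: int = 0) -> CouplingResult:
    """Empirical-CDF coupling fraction at the accumulation radius.

    The coupling fraction is the fraction of hotspot-nearest-cluster
    distances below r0 (a step-function CDF evaluation); the median
    distance carries a bootstrap error.
    """
    d = np.asarray(distances_um, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 10:
        raise ValueError("need >= 10 hotspot-cluster distances")
    if r0_um < 0:
        raise ValueError("r0 must be non-negative")
    frac = float(np.mean(d < r0_um))
    rng = np.random.default_rng(seed)
    med = float(np.median(d))
    meds = np.median(rng.choice(d, size=(n_boot, d.size), replace=True), axis=1)
    return CouplingResult(distances_um=d, r0_um=float(r0_um),
                          coupling_fraction=frac, median_um=med,
                          median_err_um=float(np.std(meds, ddof=1)))


def coupling_boundary_alt(distances_um: np.ndarray, *, bins: int = 20
                          ) -> float:
    """Alternative coupling boundary r0' from the distance histogram.

    The histogram of nearest-cluster distances is fitted with a
    two-Gaussian mixture (coupled and uncoupled populations); r0' is the
    abscissa where the two components cross between their means. Raises
    ``ValueError`` when no crossing exists between the fitted means
    (unimodal distances) so callers can fall back to the r0 method.
    """
    d = np.asarray(distances_um, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 30:
        raise ValueError("need >= 30 distances for the histogram fit")
    hist, edges = np.histogram(d, bins=bins, density=True)
    x = 0.5 * (edges[:-1] + edges[1:])

    binw = float(edges[1] - edges[0])
    q = np.quantile(d, [0.25, 0.75])
    p0 = (hist.max(), q[0], max(0.15, 1.5 * binw),
          hist.max() / 2, q[1], max(0.2, 1.5 * binw))
    # component widths cannot be narrower than a histogram bin
    lb = (0, 0, binw, 0, 0, binw)
    ub = (np.inf, d.max(), d.max(), np.inf, d.max() * 2, d.max())

    def two(xx, k0, m0, s0, k1, m1, s1):
        return (k0 * np.exp(-((xx - m0) / s0) ** 2)
                + k1 * np.exp(-((xx - m1) / s1) ** 2))

    try:
        popt, _ = optimize.curve_fit(two, x, hist, p0=p0, bounds=(lb, ub),
                                     maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(f"histogram fit failed: {exc}") from exc
    k0, m0, s0, k1, m1, s1 = popt
    lo, hi = sorted((m0, m1))
    if hi - lo < 1e-6:
        raise ValueError("fitted components coincide (unimodal distances)")
    # both populations must carry real weight, else one component is a
    # noise spike and the histogram is effectively unimodal
    w0, w1 = k0 * s0, k1 * s1
    if min(w0, w1) < 0.05 * (w0 + w1):
        raise ValueError("negligible second component (unimodal distances)")
    # require genuine bimodality: the fitted two-component curve must dip
    # between the means, else the histogram is effectively unimodal
    grid = np.linspace(lo, hi, 256)
    mix = two(grid, *popt)
    peaks = min(two(np.array([lo]), *popt)[0], two(np.array([hi]), *popt)[0])
    if mix.min() > 0.85 * peaks:
        raise ValueError("no dip between components (unimodal distances)")

    def diff(xx):
        return (k0 * math.exp(-((xx - m0) / s0) ** 2)
                - k1 * math.exp(-((xx - m1) / s1) ** 2))

    vals = np.array([diff(g) for g in grid])
    sign = np.sign(vals)
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if flips.size == 0:
        raise ValueError("no component crossing between the means "
                         "(unimodal distances)")
    i = flips[0]
    return float(optimize.brentq(diff, grid[i], grid[i + 1]))
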