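"""3D cluster detection and per-cluster 2D Gaussian fitting.

Candidate spots are located in 3D by top-hat background flattening,
per-nucleus top-percentile voxel selection and a watershed split, then
filtered by a voxel-support rule (>= 3x3 px laterally, >= 2 z-slices,
18 voxels total -- an effective spot diameter of (6/pi*18)^(1/3) = 3.25 px).
Each accepted candidate is fit in the 2D plane through its centroid with a
rotated anisotropic Gaussian plus constant local background,

    f(x, y) = Ia * exp(-(a dx^2 + 2 b dx dy + c dy^2)) + Ibg,

whose quadratic-form coefficients (a, b, c) encode widths sigma1, sigma2
and rotation theta in (0, pi/4). Derived per-cluster properties are the
size d = r_eff = sqrt(sigma1^2 + sigma2^2), the amplification ratio
Ia/Ibg, and the integrated intensity Ic = 2*pi*Ia*sigma1*sigma2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .params import AcquisitionParams

MIN_VOXELS = 18
MIN_XY_EXTENT = 3
MIN_Z_EXTENT = 2


def threshold_effective_diameter_px(n_voxels: int = MIN_VOXELS) -> float:
    """Effective diameter (px) of the voxel-support threshold volume."""
    return (6.0 / math.pi * n_voxels) ** (1.0 / 3.0)


@dataclass
class ClusterRecord:
    """One fitted cluster with its raw-fit and derived quantities."""

    nucleus_label: int
    centroid_px: tuple[float, float, float]      # (z, y, x) detection centroid
    Ia: float = np.nan
    Ibg: float = np.nan
    x0c_px: float = np.nan
    y0c_px: float = np.nan
    sigma1_px: float = np.nan
    sigma2_px: float = np.nan
    theta: float = np.nan
    residual_norm: float = np.nan
    accepted: bool = False
    voxels: int = 0
    # derived (filled by cluster_properties)
    sigma1_um: float = np.nan
    sigma2_um: float = np.nan
    d_um: float = np.nan
    amp_ratio: float = np.nan
    Ic: float = np.nan

    @property
    def abc(self) -> tuple[float, float, float]:
        """Quadratic-form coefficients of the fitted Gaussian."""
        s1, s2, th = self.sigma1_px, self.sigma2_px, self.theta
        a = math.cos(th) ** 2 / (2 * s1 ** 2) + math.sin(th) ** 2 / (2 * s2 ** 2)
        b = math.sin(2 * th) / (4 * s2 ** 2) - math.sin(2 * th) / (4 * s1 ** 2)
        c = math.sin(th) ** 2 / (2 * s1 ** 2) + math.cos(th) ** 2 / (2 * s2 ** 2)
        return a, b, c


# ---------------------------------------------------------------------------
# detection


def detect_clusters_3d(stack: np.ndarray, nucleus_mask: np.ndarray, *,
                       tophat_halfwidth_px: int = 12,
                       percentile: float = 99.0,
                       nucleus_label: int = 1
                       ) -> list[ClusterRecord]:
    """Locate candidate cluster centroids inside one nucleus mask.

    Top-hat filtering (separable cuboid element applied per plane)
    flattens the nuclear background; the top ``100 - percentile`` percent
    of in-nucleus voxels of the transformed image are selected, joined
    spots are split by a watershed, masks are mapped back to the raw
    image, and intensity-weighted 3D centroids are computed on raw
    voxels. Candidates failing the lateral 3x3 / axial 2-slice / 18-voxel
    support rule are rejected.
    """
    img = np.asarray(stack, dtype=float)
    mask = np.asarray(nucleus_mask, dtype=bool)
    if img.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) stack")
    if not mask.any():
        raise ValueError("nucleus mask is empty")

    # light lateral denoising before the top-hat so shot-noise spikes do
    # not crowd out true spot cores in the percentile selection; no axial
    # smoothing, so single-slice speckles still fail the z-extent rule
    smooth = ndimage.gaussian_filter(img, (0.0, 1.5, 1.5))
    w = 2 * tophat_halfwidth_px + 1
    tophat = ndimage.white_tophat(smooth, size=(1, w, w))

    vals = tophat[mask]
    thr = np.percentile(vals, percentile)
    cand = mask & (tophat >= thr)
    if not cand.any():
        return []

    # split joined spots: watershed on the smoothed top-hat landscape
    # seeded from its local maxima inside the candidate set
    land = ndimage.gaussian_filter(tophat, (1, 2, 2))
    mx = ndimage.maximum_filter(land, size=(3, 9, 9))
    peaks = cand & (land >= mx)
    markers, n = ndimage.label(peaks)
    if n == 0:
        labels, _ = ndimage.label(cand)
    else:
        labels = watershed(-land, markers=markers, mask=cand)

    out: list[ClusterRecord] = []
    for rp in regionprops(labels, intensity_image=img):
        zmin, ymin, xmin, zmax, ymax, xmax = rp.bbox
        if (rp.area < MIN_VOXELS or (ymax - ymin) < MIN_XY_EXTENT
                or (xmax - xmin) < MIN_XY_EXTENT
                or (zmax - zmin) < MIN_Z_EXTENT):
            continue
        z, y, x = rp.centroid_weighted
        out.append(ClusterRecord(nucleus_label=nucleus_label,
                                 centroid_px=(z, y, x), voxels=int(rp.area)))
    return out


# ---------------------------------------------------------------------------
# fitting


def _gauss2d(coords, Ia, Ibg, x0, y0, s1, s2, th):
    xx, yy = coords
    ct, st = np.cos(th), np.sin(th)
    a = ct ** 2 / (2 * s1 ** 2) + st ** 2 / (2 * s2 ** 2)
    b = np.sin(2 * th) / (4 * s2 ** 2) - np.sin(2 * th) / (4 * s1 ** 2)
    c = st ** 2 / (2 * s1 ** 2) + ct ** 2 / (2 * s2 ** 2)
    dx, dy = xx - x0, yy - y0
    out = Ia * np.exp(-(a * dx ** 2 + 2 * b * dx * dy + c * dy ** 2)) + Ibg
    return out.ravel()


def fit_cluster_2d(raw_plane: np.ndarray, centroid_yx: tuple[float, float], *,
                   w: int = 12, inuc: float | None = None,
                   nucleus_label: int = 1,
                   centroid_z: float = 0.0,
                   sigma_bound_factor: float = 1.0) -> ClusterRecord:
    """Fit a rotated 2D Gaussian + background in a (2w+1)^2 window.

    Initialization: Ia = center pixel minus background guess, Ibg = the
    nuclear mean intensity (or the window median), sigma1 = sigma2 = w/2,
    theta = 0, center = window center. Bounds: sigma in (0, w *
    ``sigma_bound_factor``], center within +/- w, theta in (0, pi/4).
    Fits that do not converge, hug a bound, or return non-positive
    amplitude/background are rejected (``accepted=False``).
    """
    img = np.asarray(raw_plane, dtype=float)
    yc, xc = int(round(centroid_yx[0])), int(round(centroid_yx[1]))
    ny, nx = img.shape
    if yc - w < 0 or xc - w < 0 or yc + w + 1 > ny or xc + w + 1 > nx:
        return ClusterRecord(nucleus_label=nucleus_label,
                             centroid_px=(centroid_z, *centroid_yx),
                             accepted=False)
    win = img[yc - w: yc + w + 1, xc - w: xc + w + 1]
    yy, xx = np.mgrid[-w: w + 1, -w: w + 1].astype(float)

    ibg0 = float(inuc) if inuc is not None else float(np.median(win))
    ia0 = max(float(win[w, w]) - ibg0, 1e-3)
    smax = w * sigma_bound_factor
    p0 = (ia0, ibg0, 0.0, 0.0, w / 2, w / 2, 1e-3)
    lb = (0.0, 0.0, -w, -w, 0.3, 0.3, 0.0)
    ub = (np.inf, np.inf, w, w, smax, smax, np.pi / 4)
    rec = ClusterRecord(nucleus_label=nucleus_label,
                        centroid_px=(centroid_z, float(centroid_yx[0]),
                                     float(centroid_yx[1])))
    try:
        popt, _ = optimize.curve_fit(_gauss2d, (xx, yy), win.ravel(),
                                     p0=p0, bounds=(lb, ub), maxfev=4000,
                                     xtol=1e-8)
    except (RuntimeError, ValueError):
        return rec
    Ia, Ibg, x0, y0, s1, s2, th = popt
    resid = win.ravel() - _gauss2d((xx, yy), *popt)
    rec.residual_norm = float(np.sqrt(np.mean(resid ** 2)))
    # reject bound-hugging or degenerate solutions
    eps = 1e-3
    if (Ia <= eps or Ibg <= eps or s1 >= smax * (1 - 1e-3)
            or s2 >= smax * (1 - 1e-3) or s1 <= 0.3 + eps or s2 <= 0.3 + eps
            or abs(x0) >= w - eps or abs(y0) >= w - eps):
        rec.Ia, rec.Ibg = float(Ia), float(Ibg)
        return rec
    # canonical orientation: sigma1 >= sigma2, theta strictly inside (0, pi/4)
    if s2 > s1:
        s1, s2 = s2, s1
        th = np.pi / 4 - th if th <= np.pi / 4 else th
    th = min(max(th, 1e-6), np.pi / 4 - 1e-6)
    rec.Ia, rec.Ibg = float(Ia), float(Ibg)
    rec.x0c_px, rec.y0c_px = float(x0), float(y0)
    rec.sigma1_px, rec.sigma2_px, rec.theta = float(s1), float(s2), float(th)
    rec.accepted = True
    return rec


def cluster_properties(rec: ClusterRecord, acq: AcquisitionParams, *,
                       size_multiplier: float = 1.0) -> ClusterRecord:
    """Fill derived fields: d = sqrt(s1^2+s2^2), Ia/Ibg, Ic = 2*pi*Ia*s1*s2.

    Sizes are converted to microns with the lateral voxel pitch; Ic is in
    um^2 * intensity. ``size_multiplier`` rescales the reported d for
    alternative size conventions (default 1: d is the effective radius
    measure r_eff).
    """
    if not rec.accepted:
        raise ValueError("cluster_properties requires an accepted fit")
    vxy_um = acq.voxel_xy_nm / 1000
    rec.sigma1_um = rec.sigma1_px * vxy_um
    rec.sigma2_um = rec.sigma2_px * vxy_um
    rec.d_um = size_multiplier * math.hypot(rec.sigma1_um, rec.sigma2_um)
    rec.amp_ratio = rec.Ia / rec.Ibg
    rec.Ic = 2 * math.pi * rec.Ia * rec.sigma1_um * rec.sigma2_um
    return rec


# ---------------------------------------------------------------------------
# per-nucleus pipeline and aggregation


def quantify_nucleus(stack: np.ndarray, nucleus_mask: np.ndarray,
                     acq: AcquisitionParams, *, nucleus_label: int = 1,
                     inuc: float | None = None, w: int = 12,
                     tophat_halfwidth_px: int = 12,
                     percentile: float = 99.0,
                     require_window_in_mask: bool = True
                     ) -> list[ClusterRecord]:
    """Detect, fit and derive properties for all clusters of one nucleus.

    With ``require_window_in_mask`` (default) the full fitting window
    must lie inside the nucleus mask on the fit plane, excluding
    candidates whose local background would be contaminated by the
    nuclear rim.
    """
    if inuc is None:
        inuc = float(np.mean(stack[nucleus_mask]))
    cands = detect_clusters_3d(stack, nucleus_mask,
                               tophat_halfwidth_px=tophat_halfwidth_px,
                               percentile=percentile,
                               nucleus_label=nucleus_label)
    out = []
    for cand in cands:
        z, y, x = cand.centroid_px
        zi = int(round(z))
        if require_window_in_mask:
            yi, xi = int(round(y)), int(round(x))
            ny, nx = nucleus_mask.shape[1:]
            if (yi - w < 0 or xi - w < 0 or yi + w + 1 > ny
                    or xi + w + 1 > nx
                    or not nucleus_mask[zi, yi - w: yi + w + 1,
                                        xi - w: xi + w + 1].all()):
                out.append(cand)  # kept as a rejected candidate
                continue
        rec = fit_cluster_2d(stack[zi], (y, x), w=w, inuc=inuc,
                             nucleus_label=nucleus_label, centroid_z=z)
        rec.voxels = cand.voxels
        if rec.accepted:
            cluster_properties(rec, acq)
        out.append(rec)
    return out


def records_to_frame(records: list[ClusterRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        z, y, x = r.centroid_px
        rows.append({"nucleus": r.nucleus_label, "z_px": z, "y_px": y,
                     "x_px": x, "Ia": r.Ia, "Ibg": r.Ibg,
                     "sigma1_px": r.sigma1_px, "sigma2_px": r.sigma2_px,
                     "sigma1_um": r.sigma1_um, "sigma2_um": r.sigma2_um,
                     "theta": r.theta, "d_um": r.d_um,
                     "amp_ratio": r.amp_ratio, "Ic": r.Ic,
                     "voxels": r.voxels, "accepted": r.accepted,
                     "residual_norm": r.residual_norm})
    return pd.DataFrame(rows)


def nuclear_cluster_summary(records: list[ClusterRecord] | pd.DataFrame,
                            inuc: float, x_over_L: float,
                            nucleus_label: int = 1) -> dict:
    """Per-nucleus count and means of d, Ia, Ibg, Ic over accepted fits."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df):
        df = df[df["accepted"]]
    n = len(df)
    summary = {"nucleus": nucleus_label, "n_clusters": n, "Inuc": inuc,
               "x_over_L": x_over_L}
    for col, name in [("d_um", "mean_d_um"), ("Ia", "mean_Ia"),
                      ("Ibg", "mean_Ibg"), ("Ic", "mean_Ic")]:
        summary[name] = float(df[col].mean()) if n else np.nan
    return summary
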