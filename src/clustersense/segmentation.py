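"""Nucleus segmentation ("filled" and "hollow" contrast) and AP positioning.

Two morphological pipelines label nuclei in 3D stacks: one for channels
where nuclei are brighter than the surrounding cytoplasm (a nuclear-
enriched TF), one for channels where nuclei are darker than the
interstitial space (a cytoplasm-enriched coat protein). A matching step
pairs the two labelings by centroid distance, and an embryo-axis geometry
maps stage-coordinate centroids to fractional anterior-posterior position
x/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import reconstruction
from skimage.segmentation import watershed

from .params import AcquisitionParams
from .synthetic import ImageStack


@dataclass
class NucleusRecord:
    """One labeled nucleus: mask label, centroid, size and mean intensity."""

    label: int
    centroid_px: tuple[float, float, float]     # (z, y, x)
    centroid_um: tuple[float, float, float]     # (x, y, z) physical
    equivalent_diameter_um: float
    inuc: float
    voxels: int
    touches_border: bool
    x_over_L: float | None = None


@dataclass(frozen=True)
class EmbryoGeometry:
    """Anterior/posterior tip coordinates of the embryo in stage microns."""

    anterior_um: tuple[float, float]
    posterior_um: tuple[float, float]

    @property
    def length_um(self) -> float:
        (x0, y0), (xl, yl) = self.anterior_um, self.posterior_um
        L = math.hypot(xl - x0, yl - y0)
        if L <= 0:
            raise ValueError("embryo length must be positive")
        return L


def _contrast_stretch(img: np.ndarray, lo_pct=0.5, hi_pct=99.5) -> np.ndarray:
    lo, hi = np.percentile(img, [lo_pct, hi_pct])
    if hi <= lo:
        return np.zeros_like(img, dtype=float)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def _cuboid(nxy: int, nz: int = 1) -> np.ndarray:
    return np.ones((nz, nxy, nxy), dtype=bool)


def _split_watershed(mask: np.ndarray, z_aniso: float,
                     min_distance_px: float) -> np.ndarray:
    """Label a binary mask, splitting touching nuclei with a watershed
    seeded from smoothed distance-transform maxima."""
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(mask, sampling=(z_aniso, 1.0, 1.0))
    smooth = ndimage.gaussian_filter(dist, sigma=(1, 2, 2))
    mx = ndimage.maximum_filter(smooth, size=(3,
                                              int(min_distance_px) | 1,
                                              int(min_distance_px) | 1))
    peaks = (smooth == mx) & (smooth > 0.3 * smooth.max())
    markers, n = ndimage.label(peaks)
    if n == 0:
        return cc_label(mask).astype(np.int32)
    # merge marker fragments of the same peak plateau
    return watershed(-smooth, markers=markers, mask=mask).astype(np.int32)


def _records_from_labels(labels: np.ndarray, raw: np.ndarray,
                         acq: AcquisitionParams, *, min_voxels: int = 50
                         ) -> list[NucleusRecord]:
    vz, vxy = acq.voxel_z_nm / 1000, acq.voxel_xy_nm / 1000
    nz, ny, nx = labels.shape
    out = []
    for rp in regionprops(labels, intensity_image=raw):
        if rp.area < min_voxels:
            continue
        z, y, x = rp.centroid
        zmin, ymin, xmin, zmax, ymax, xmax = rp.bbox
        border = (zmin == 0 or ymin == 0 or xmin == 0 or
                  zmax == nz or ymax == ny or xmax == nx)
        vol_um3 = rp.area * vz * vxy * vxy
        eq_d = (6 * vol_um3 / math.pi) ** (1 / 3)
        out.append(NucleusRecord(
            label=int(rp.label), centroid_px=(z, y, x),
            centroid_um=(x * vxy, y * vxy, z * vz),
            equivalent_diameter_um=eq_d,
            inuc=float(rp.intensity_mean), voxels=int(rp.area),
            touches_border=border))
    return out


def segment_filled_nuclei(stack: ImageStack | np.ndarray,
                          acq: AcquisitionParams | None = None, *,
                          channel: str | None = None,
                          nucleus_diameter_um: float = 5.0,
                          min_voxels: int = 50
                          ) -> tuple[list[NucleusRecord], np.ndarray]:
    """Label bright ("filled") nuclei in a single-channel 3D stack.

    The pipeline: percentile contrast stretch, 3D median filter, 3D
    Gaussian filter, grayscale erosion with a cuboid element,
    morphological reconstruction (opening-by-reconstruction), dilation,
    complement, Gaussian blur, grayscale closing, erosion, Otsu
    binarization of the (dark-nucleus) complement, then a watershed split
    of touching nuclei. Returns the records and the label volume.
    """
    img, acq = _unpack(stack, acq, channel)
    if np.ptp(img) <= 0:
        return [], np.zeros(img.shape, dtype=np.int32)
    vxy_um = acq.voxel_xy_nm / 1000
    se_xy = max(3, int(round(nucleus_diameter_um / 10 / vxy_um)))

    work = _contrast_stretch(img)
    work = ndimage.median_filter(work, size=(1, 3, 3))
    work = ndimage.gaussian_filter(work, sigma=(1, 2, 2))
    se = _cuboid(se_xy, 1)
    eroded = ndimage.grey_erosion(work, footprint=se)
    recon = reconstruction(eroded, work, method="dilation")
    dil = ndimage.grey_dilation(recon, footprint=se)
    comp = dil.max() - dil
    comp = ndimage.gaussian_filter(comp, sigma=(1, 2, 2))
    comp = ndimage.grey_closing(comp, footprint=se)
    comp = ndimage.grey_erosion(comp, footprint=se)
    thr = threshold_otsu(comp)
    mask = comp < thr           # nuclei are the dark class of the complement
    mask = ndimage.binary_opening(mask, structure=_cuboid(3, 1))
    mask = ndimage.binary_fill_holes(mask)

    r_px = nucleus_diameter_um / 2 / vxy_um
    labels = _split_watershed(mask, acq.z_anisotropy, max(3.0, r_px))
    return _records_from_labels(labels, img, acq, min_voxels=min_voxels), labels


def segment_hollow_nuclei(stack: ImageStack | np.ndarray,
                          acq: AcquisitionParams | None = None, *,
                          channel: str | None = None,
                          nucleus_diameter_um: float = 5.0,
                          h_frac: float = 0.15, min_voxels: int = 50
                          ) -> tuple[list[NucleusRecord], np.ndarray]:
    """Label dark ("hollow") nuclei on a bright interstitial background.

    Pipeline: contrast stretch, median, Gaussian, extended regional maxima
    of the bright interstitial signal, binarize, invert (nuclei become the
    foreground), smoothing kernel convolution plus threshold, watershed,
    cuboid opening and hole filling.
    """
    img, acq = _unpack(stack, acq, channel)
    if np.ptp(img) <= 0:
        return [], np.zeros(img.shape, dtype=np.int32)
    vxy_um = acq.voxel_xy_nm / 1000
    se_xy = max(3, int(round(nucleus_diameter_um / 10 / vxy_um)))

    work = _contrast_stretch(img)
    work = ndimage.median_filter(work, size=(1, 3, 3))
    work = ndimage.gaussian_filter(work, sigma=(1, 2, 2))
    # extended regional maxima of the bright background (h-maxima mask)
    h = h_frac * float(np.ptp(work))
    seed = np.clip(work - h, 0, None)
    rec = reconstruction(seed, work, method="dilation")
    em = work - rec > 1e-9
    bright = em | (work > threshold_otsu(work))
    nuclei_fg = ~bright
    kernel = np.ones((3, se_xy, se_xy), dtype=float)
    kernel /= kernel.sum()
    smooth = ndimage.convolve(nuclei_fg.astype(float), kernel, mode="nearest")
    mask = smooth > 0.5
    mask = ndimage.binary_opening(mask, structure=_cuboid(se_xy, 1))
    mask = ndimage.binary_fill_holes(mask)
    # drop the image-border background component if it slipped through
    mask &= ndimage.binary_erosion(np.ones_like(mask), border_value=0)

    r_px = nucleus_diameter_um / 2 / vxy_um
    labels = _split_watershed(mask, acq.z_anisotropy, max(3.0, r_px))
    return _records_from_labels(labels, img, acq, min_voxels=min_voxels), labels


def _unpack(stack, acq, channel):
    if isinstance(stack, ImageStack):
        name = channel or next(iter(stack.channels))
        return np.asarray(stack.channels[name], dtype=float), stack.acq
    if acq is None:
        raise ValueError("acq is required when passing a bare array")
    return np.asarray(stack, dtype=float), acq


def match_nuclei(filled: list[NucleusRecord], hollow: list[NucleusRecord],
                 nuclear_length_um: float) -> list[tuple[NucleusRecord, NucleusRecord]]:
    """Greedy nearest-centroid pairing of two nucleus labelings.

    Pairs are accepted only if the centroid distance is below half the
    nuclear length; unmatched records are excluded.
    """
    if not filled or not hollow:
        raise ValueError("both nucleus lists must be non-empty")
    fa = np.array([r.centroid_um for r in filled])
    ha = np.array([r.centroid_um for r in hollow])
    d = np.linalg.norm(fa[:, None, :] - ha[None, :, :], axis=2)
    pairs = []
    used_f: set[int] = set()
    used_h: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    limit = nuclear_length_um / 2
    for i, j in order:
        if d[i, j] >= limit:
            break
        if i in used_f or j in used_h:
            continue
        pairs.append((filled[i], hollow[j]))
        used_f.add(int(i))
        used_h.add(int(j))
    return pairs


def nucleus_position(centroid_um: tuple[float, float],
                     geom: EmbryoGeometry) -> float:
    """Fractional AP position x'/L of a stage-coordinate centroid.

    The centroid is projected onto the anterior-posterior axis through
    x' = r*cos(theta), with r the distance from the anterior tip and
    theta the angle between the centroid ray and the AP axis; nuclei on
    either side of the axis map to the same x'.
    """
    (x0, y0) = geom.anterior_um
    (xl, yl) = geom.posterior_um
    xi, yi = centroid_um
    r = math.hypot(xi - x0, yi - y0)
    if r == 0:
        return 0.0
    theta = math.atan2(yi - y0, xi - x0) - math.atan2(yl - y0, xl - x0)
    return r * math.cos(theta) / geom.length_um


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        x, y, z = r.centroid_um
        rows.append({"label": r.label, "x_um": x, "y_um": y, "z_um": z,
                     "diameter_um": r.equivalent_diameter_um, "Inuc": r.inuc,
                     "voxels": r.voxels, "touches_border": r.touches_border,
                     "x_over_L": r.x_over_L})
    return pd.DataFrame(rows)
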