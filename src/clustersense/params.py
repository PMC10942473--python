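"""Parameter containers for acquisition and embryo simulation.

All physical quantities carry explicit units in their field names or
docstrings: lengths in nanometres (voxel/PSF scales) or micrometres
(embryo-scale geometry), times in seconds, intensities in arbitrary
detector units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class AcquisitionParams:
    """Microscope acquisition geometry and noise model.

    Parameters
    ----------
    voxel_xy_nm, voxel_z_nm : float
        Voxel edge lengths. Defaults match a fast-Airyscan confocal
        configuration (43 x 43 x 200 nm^3).
    frame_time_s : float
        Frame interval of 2D time-lapse acquisitions.
    psf_sigma_lateral_nm, psf_sigma_axial_nm : float
        Gaussian PSF standard deviations. The lateral default is chosen so
        that the pixel-correlation length of PSF-blurred homogeneous signal
        is 0.20 um (see :func:`clustersense.correlation.psf_sigma_for_corr_length`).
    noise_read_sd : float
        Additive Gaussian read-noise standard deviation (intensity units).
    photon_scale : float
        Intensity units per detected photon; shot noise is Poisson on
        ``intensity / photon_scale``.
    """

    voxel_xy_nm: float = 43.0
    voxel_z_nm: float = 200.0
    frame_time_s: float = 0.497
    psf_sigma_lateral_nm: float = 140.0
    psf_sigma_axial_nm: float = 300.0
    noise_read_sd: float = 2.0
    photon_scale: float = 2.0

    def __post_init__(self) -> None:
        if not (self.voxel_xy_nm > 0 and self.voxel_z_nm > 0):
            raise ValueError("voxel sizes must be positive")
        if self.voxel_z_nm < self.voxel_xy_nm:
            raise ValueError("voxel_z must be >= voxel_xy")
        if self.frame_time_s <= 0:
            raise ValueError("frame_time must be positive")
        if not (self.psf_sigma_lateral_nm > 0 and self.psf_sigma_axial_nm > 0):
            raise ValueError("PSF sigmas must be positive")

    @property
    def psf_sigma_lateral_px(self) -> float:
        return self.psf_sigma_lateral_nm / self.voxel_xy_nm

    @property
    def psf_sigma_axial_px(self) -> float:
        return self.psf_sigma_axial_nm / self.voxel_z_nm

    @property
    def z_anisotropy(self) -> float:
        """Ratio of axial to lateral voxel size."""
        return self.voxel_z_nm / self.voxel_xy_nm


@dataclass(frozen=True)
class EmbryoSimParams:
    """Statistical structure of the simulated embryo.

    The defaults are the study conditions this package emulates: an
    exponential anterior-posterior nuclear-intensity gradient, cluster
    counts and amplitudes scaling linearly with nuclear intensity while
    cluster size does not, and telegraph-blinking cluster dynamics.

    Notes on individual fields
    --------------------------
    lambda_gradient : exponential decay constant of the nuclear intensity
        gradient, in units of embryo length L (0.23).
    lambda_ic, cv_ic : decay constant (0.26 L) and nucleus-to-nucleus
        coefficient of variation (0.22) of the per-nucleus mean integrated
        cluster intensity, used by the statistical gradient sampler.
    cv_inuc : multiplicative nucleus-to-nucleus noise on Inuc (0.14).
    cluster_count_* : mean cluster count per nucleus is
        ``intercept + slope * Inuc``; defaults give ~55 clusters at the
        anterior dropping about two-fold over the anterior 60% of L.
    d_mean_nm, d_sd_nm : imaged (PSF-convolved) cluster size d =
        sqrt(sigma1^2 + sigma2^2), truncated normal (400 +/- 140 nm).
    d_floor_nm : lower truncation of the size draw (150 nm nominal; the
        effective floor is the PSF-limited size if that is larger).
    amp_ratio_mean, amp_ratio_sd : cluster amplitude over local background
        Ia/Ibg, truncated normal (2.2 +/- 0.8, > 0).
    ton_s, toff_s : telegraph dwell-time means (2.4 s on, 1.6 s off).
    coupling_fraction : probability that a hotspot's nearest cluster is
        placed within the accumulation radius r0.
    accumulation_radius_r0_um : accumulation radius r0 (0.44 um).
    xi_pair_um, rho_prime : confinement-area width of the maxima
        pair-correlation (0.37 um) and its relative peak density (8).
    """

    embryo_length_um: float = 500.0
    lambda_gradient: float = 0.23
    lambda_ic: float = 0.26
    cv_inuc: float = 0.14
    cv_ic: float = 0.22
    I0_anterior: float = 400.0
    nucleus_diameter_um: float = 5.0
    cluster_count_intercept: float = 24.0
    cluster_count_slope_per_intensity: float = 0.12
    amp_ratio_mean: float = 2.2
    amp_ratio_sd: float = 0.8
    d_mean_nm: float = 400.0
    d_sd_nm: float = 140.0
    d_floor_nm: float = 150.0
    ton_s: float = 2.4
    toff_s: float = 1.6
    coupling_fraction: float = 0.57
    accumulation_radius_r0_um: float = 0.44
    xi_pair_um: float = 0.37
    rho_prime: float = 8.0
    mol_noise_cv: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.lambda_gradient < 1):
            raise ValueError("lambda_gradient must be in (0, 1) units of L")
        if not (0 <= self.coupling_fraction <= 1):
            raise ValueError("coupling_fraction must be a probability")
        if self.ton_s <= 0 or self.toff_s <= 0:
            raise ValueError("telegraph dwell times must be positive")
        if self.d_mean_nm <= self.d_floor_nm:
            raise ValueError("cluster size floor must lie below d_mean (degenerate truncation)")

    def mean_cluster_count(self, inuc: float) -> float:
        return self.cluster_count_intercept + self.cluster_count_slope_per_intensity * inuc


def paper_preset() -> tuple[EmbryoSimParams, AcquisitionParams]:
    """Acquisition + simulation parameters matching the emulated study.

    The lateral PSF sigma is derived at call time so that the preset's
    pixel-correlation length, measured inside an eroded nuclear mask of
    the preset diameter at the reference anterior position, equals the
    0.20 um diffraction-limited reference. The calibration models the
    full measurement expectation: finite-row taper, mean-subtraction
    deficit, and the white detection-noise baseline tilt (see
    :func:`clustersense.correlation.expected_masked_curve`).
    """
    import math

    import numpy as np

    from .correlation import disk_row_lengths, psf_sigma_for_corr_length

    sim = EmbryoSimParams()
    acq = AcquisitionParams()
    erode_px = 10                      # matches the measurement protocol
    r_px = sim.nucleus_diameter_um * 1000 / 2 / acq.voxel_xy_nm
    rows = disk_row_lengths(r_px - erode_px)

    # detection-noise-to-texture variance ratio at the reference position
    x_ref = 0.2
    inuc = sim.I0_anterior * math.exp(-x_ref / sim.lambda_gradient)
    z = np.linspace(-8, 8, 4001)
    phi = np.exp(-z ** 2 / 2) / math.sqrt(2 * math.pi)
    y = np.clip(1 + sim.mol_noise_cv * z, 0, None)   # clipped speckle factor
    m1 = np.trapezoid(y * phi, z)
    var_clip = np.trapezoid((y - m1) ** 2 * phi, z)
    sz_px = acq.psf_sigma_axial_px

    def noise_ratio(sigma_nm: float) -> float:
        sxy_px = sigma_nm / acq.voxel_xy_nm
        blur_factor = (1 / (2 * math.sqrt(math.pi) * sxy_px)) ** 2 \
            * (1 / (2 * math.sqrt(math.pi) * sz_px))
        speckle_var = inuc ** 2 * var_clip * blur_factor
        noise_var = acq.photon_scale * inuc * m1 + acq.noise_read_sd ** 2
        return noise_var / speckle_var

    sigma = psf_sigma_for_corr_length(200.0, voxel_nm=acq.voxel_xy_nm,
                                      row_lengths=rows,
                                      noise_ratio_fn=noise_ratio)
    return sim, replace(acq, psf_sigma_lateral_nm=sigma)
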