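# Methods

`clustersense` quantifies sub-micron transcription-factor (TF) clusters in
fluorescence images of early-embryo nuclei and asks whether their
properties preserve the positional information of a morphogen gradient.
Because no raw microscopy data ships with the package, every analysis
stage is exercised against a synthetic-embryo generator whose parameters
are the study conditions being emulated; the generator's ground truth is
the oracle for all quantitative claims.

## The synthetic embryo

A nucleus is a sphere (default diameter 5 µm) rendered on the acquisition
grid (43 × 43 × 200 nm³ voxels). Its emitter field is a uniform nuclear
level `Inuc = I0 · exp(−x/λ)` (λ = 0.23 L along the anterior–posterior
axis, x in units of embryo length L), multiplied by per-voxel "molecular"
speckle — white noise with CV 1.0, clipped at zero. The large CV reflects
sub-molecule-per-voxel occupancy at realistic nuclear concentrations
(~600 molecules/µm³ → ~0.2 molecules per voxel), which is what makes the
texture of freely diffusing fluorophores PSF-limited rather than
noise-limited. The field is blurred by a Gaussian PSF and then corrupted
by Poisson shot noise on photon counts (2 intensity units/photon) plus
Gaussian read noise (sd 2).

Clusters are anisotropic 3D Gaussians planted uniformly inside the
nucleus. The size parameter is the *imaged* lateral width
`d = sqrt(σ1² + σ2²)`: draws come from a lognormal with mean 400 nm and
sd 140 nm, redrawn above the PSF-limited floor `sqrt(2)·σ_psf`
(≈ 240 nm). A lognormal rather than the nominal truncated normal is used
because the observed size histogram is right-skewed with a left tail that
vanishes at the diffraction limit; truncating a normal with the printed
moments at the PSF floor either shifts the mean by ~7% or, if
moment-matched, degenerates into a floor-peaked shape. With the
lognormal the realized planted mean sits ~4% above the nominal 400 nm —
the price of the diffraction floor — and the fitted population mean
tracks it. The rendered (pre-blur) widths are obtained by quadrature
subtraction of the PSF sigma per axis, so fits on the blurred image
recover the planted imaged widths; the eccentricity draw is floored so
the minor axis never falls below the PSF sigma. Cluster amplitudes are
`Ia = ratio · Ibg` with ratio ~ Normal(2.2, 0.8) truncated above zero,
drawn independently of size (the size–amplitude independence the
analysis must preserve). Cluster count per nucleus is Poisson with mean
linear in `Inuc` (≈ 55 at the anterior, two-fold drop across the
anterior 60% of L).

Telegraph blinking uses exponential dwell times with means Ton = 2.4 s
and Toff = 1.6 s, sampled at the 497 ms frame time; the stationary
occupancy Ton/(Ton+Toff) = 0.6 fixes the initial state distribution.

Two-channel stacks add a nascent-mRNA hotspot (bright 3D Gaussian) per
nucleus. With probability equal to the coupling fraction the nearest TF
cluster is placed uniformly within 0.25–0.90 of the accumulation radius
r0 = 0.44 µm; otherwise all clusters are pushed beyond ~1.25 r0.
`nontarget` mode leaves clusters independent of the hotspot.

Projected-maxima point patterns are a Poisson background plus Gaussian
confinement clumps. The clump parameter is the *pair-correlation* width
σ (points scatter with per-axis sd σ/2, so planted g(r) =
ρ′·exp(−(r/σ)²) + 1 with σ = 0.37 µm, ρ′ = 8); the mean points per clump
is solved from (ρ′, background density, clump density) via the Thomas-
process relation, which requires λ_clump·ρ′·πσ² < 1.

What the generator does *not* emulate: chromatin motion blur, Airyscan
reconstruction artifacts, nuclear-envelope invaginations, mitotic
stages, spatially varying background within a nucleus, or any coupling
between cluster dynamics and position. Tests passing on this generator
show the estimators are correct for the stated statistical structure,
not that real images satisfy that structure.

## PSF calibration

The preset PSF sigma is not set directly; it is solved so that the
*measured* pixel-correlation length of homogeneous (cluster-free) nuclei
equals the 0.20 µm diffraction-limited reference. The row-wise
autocorrelation estimator (per-row mean subtraction, biased 1/T
normalization, exponential fit `a + b·exp(−c·x)` from lag 1 with
λ = x0 + ln2/c) is biased on finite masked rows: the lag taper (T−k)/T,
the mean-subtraction deficit of the correlated texture, and a tilted
baseline from white detection noise (−σe²(T−k)/T² at positive lags) all
shorten the apparent length. `expected_masked_curve` computes the exact
expectation of the estimator for PSF-blurred white noise over the chord
lengths of the (eroded) nuclear disk including the noise term, and
`psf_sigma_for_corr_length` inverts it with a root finder. The
calibrated sigma is ≈ 167 nm; measuring the protocol (30–60 nuclei,
equatorial plane, mask eroded 10 px past the rim ramp, curves averaged
before one fit) returns 0.20 ± 0.01 µm. The erosion exists because the
blurred nucleus–cytoplasm boundary inside an exact geometric mask
carries an intensity cliff whose correlation signature otherwise swamps
the texture.

## Maxima detection and persistence

The 2D detector applies Otsu thresholding to nuclear pixels, then
iterates local thresholding: moving mean + sd over 25 × 25 windows
*including previously zeroed pixels* (computing the statistics over
surviving pixels only makes the iteration collapse to the single
brightest peak), zeroing sub-threshold pixels and rescaling to [0, 1].
Iteration stops when the SSIM of the binarized iterate against the first
binarized image changes by < 10⁻³ for 3 consecutive steps, when the
binary image stops changing, or at 20 iterations. The method detects all
local peaks including speckle maxima by design; discrimination happens
downstream (3D voxel-support rule, or spatial persistence of projected
maxima). Centroids are intensity-weighted per connected component.

Presence traces (a maximum within a radius of a confinement center) give
effective dwell times as mean run length × frame time, with first/last
runs censored. At 497 ms sampling these run 15–25% above the underlying
exponential means because sub-frame absences merge runs; the
geometric-run MLE correction τ = −Δt/ln(1 − 1/k̄) removes most of the
sampling bias and recovers the simulator means within ~5%. Both values
are reported; the detection probability is the raw occupancy fraction
(≈ 0.58–0.60 at the presets), alongside Ton/(Ton+Toff).

## Cluster detection and fitting

Candidates come from a white top-hat (separable (1, 25, 25) cuboid
element — an opening element *smaller* than the spot suppresses the spot
itself, so the half-width exceeds the typical cluster sigma) applied to
a lightly denoised stack (Gaussian sigma ≈ 1.5 px laterally; without it
shot-noise spikes crowd the percentile selection). The top percentile of
in-nucleus top-hat voxels is selected per nucleus, joined spots are
split by watershed seeded from smoothed top-hat maxima, and masks map
back to the raw stack for intensity-weighted 3D centroids. Candidates
need ≥ 3 × 3 px lateral and ≥ 2-slice axial support (18 voxels; an
effective spot diameter of (6/π·18)^(1/3) = 3.25 px). The percentile is
a coverage knob: the classic top-1% suits data whose spots occupy ≲ 1%
of the nuclear volume; at this package's size convention planted spots
cover far more, so the size-recovery protocol runs sparser nuclei at the
92nd percentile. Because planted size and amplitude are independent,
amplitude-limited selection does not bias size statistics.

Each accepted candidate is fit on the raw 2D plane through its centroid
with a rotated Gaussian `Ia·exp(−(a dx² + 2b dx dy + c dy²)) + Ibg`
(widths σ1 ≥ σ2, rotation θ ∈ (0, π/4)), initialized at Ia = center
pixel − background, Ibg = nuclear mean, σ = w/2, window half-width
w = 12 px. Width bounds are (0.3, w] pixels: a w/2 bound would cap
`sqrt(σ1²+σ2²)` at 365 nm and truncate the printed 400 ± 140 nm
population. Fits must keep their full window inside both the image and
the nucleus mask on the fit plane (rim-contaminated backgrounds inflate
widths by 5–15%); bound-hugging or non-convergent solutions are
discarded. Derived per-cluster quantities: size d = sqrt(σ1² + σ2²),
amplification Ia/Ibg, integrated intensity Ic = 2π·Ia·σ1·σ2 (the
2D-Gaussian volume above background, in µm²·intensity).

## Gradient precision

Per-nucleus quantities are binned in 0.05-wide x/L bins over [0.10,
0.70]; within each bin, nuclei are bootstrap-resampled (default 1000
draws, seeded). The table reports the bootstrap mean, the bootstrap
error of the mean (`se`), and the nucleus-to-nucleus spread (`sd`, the
mean resample standard deviation) whose ratio to the mean is the CV used
for precision analysis. Decay constants come from OLS of ln(bin mean) on
x/L: λ = −1/slope, σλ = σ_slope/slope². For an exponential gradient the
positional error reduces to σx/L = CV·λ, which equals the general
propagation form δc·|dc/dx|⁻¹ identically; the pooled value at the
calibrated presets (CV_Ic = 0.22, λ_Ic = 0.26) is ≈ 5.5–5.9 %L.
Estimation-error propagation for reading nuclear properties off cluster
properties follows the closed forms σc = σi/s and σp = λ·σi/ī with their
stated uncertainty combinations, cross-checked against Monte-Carlo
propagation in the tests.

The molecule budget converts a flat-expression nuclear count N0_flat =
8000 into the anterior wild-type count N0 = N0_flat·L/λ = 40 000
(λ = 0.2 L; the exact integral form N0_flat·(L/λ)/(1−e^(−L/λ)) ≈ 40 271
is returned as a diagnostic), then chains: nuclear density N0/((π/6)d³)
≈ 611 ≈ 600 molecules/µm³ for a 5 µm nucleus; in-cluster concentration
2.2 × that ≈ 1320–1345 molecules/µm³; cluster volume (π/6)(0.4 µm)³ ≈
0.034 ≈ 0.03 µm³; molecules per cluster ≈ 45 unrounded (the chain of
printed rounded values gives ≈ 40); clustered fraction ≈ 6% of the
nuclear pool with ~55 clusters. All values are kept at full precision;
rounding is the caller's display choice.

## Colocalization

Hotspots are detected per nucleus by difference-of-Gaussians enhancement
multiplied pointwise onto the raw stack (a literal convolution of the
DoG output with the raw image is not meaningful; the product keeps
voxels that are bright in both), thresholded at μ + 4σ of the nuclear
mRNA intensity, with an 18-voxel minimum mask size. TF intensity is
ring-averaged in 0.1 µm annuli on the hotspot's z-plane within the
nucleus, aggregated pixel-weighted across nuclei, and fitted with a
double Gaussian; the accumulation radius r0 is the FWHM of the central
component, 2·a0·sqrt(ln 2) (a config multiplier exposes the
alternative twice-FWHM convention). The coupling fraction is the
empirical CDF of hotspot-to-nearest-accepted-cluster 3D distances
(anisotropy-corrected µm) evaluated at r0; the alternative boundary r0′
is the crossing point of a two-component fit of the distance histogram,
falling back to the r0 method when the histogram is unimodal.

## Sensing times

A cluster of diameter d holding concentration c_clust can estimate the
nuclear concentration to fractional accuracy δN/N in
T_clust = 6/(D·d·c_clust)·(δN/N)⁻²; a single binding site of length
a = 3.4 nm reading the bulk concentration c_nuc needs
T_site = 1/(D·a·c_nuc)·(δN/N)⁻². The prefactors are fixed by requiring
the ratio T_site/T_clust = d/(6a)·(c_clust/c_nuc), which is independent
of D and the accuracy target. At the presets (d = 0.4 µm, amplification
2.2) the ratio is ≈ 43 for nucleus-averaged inputs; a position-resolved
profile evaluates it per x/L bin from the binned size and amplification.
D has no default — it is a required user input.

## Problem sizes and determinism

The standard protocols run at desk scale on one core: 400-nucleus
statistical fields, 120–220 rendered sparse nuclei (~1000–2000 planted
clusters) for size recovery, 30–60 homogeneous nuclei for the
correlation length, 30–40 projected-maxima maps, 200–300 telegraph
traces. Every protocol and generator consumes a single integer seed;
multi-object generators split it with `SeedSequence.spawn`, so any
object is reproducible in isolation and identical seeds give
bit-identical outputs.

## Known limitations

* At the full calibrated cluster density (~50 per 5 µm nucleus) fitting
  windows overlap and fitted sizes inflate by ~10–15%; size statistics
  are therefore validated on sparse fields. Real nuclei are larger and
  less crowded in voxel terms, but window overlap is a real effect the
  fit model ignores.
* The top-percentile selection reaches only the brightest clusters at
  full density; detected-count gradients flatten there, so count-vs-Inuc
  analyses should use the statistical field, not dense renders.
* The effective dwell times are frame-rate-dependent; only the corrected
  estimates are comparable across acquisition settings.
* The hollow-nucleus pipeline assumes reasonably uniform interstitial
  brightness; strong cytoplasmic texture would require retuning the
  regional-maxima depth parameter.
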