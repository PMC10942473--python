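# clustersense

Quantitative analysis of transcription-factor (TF) clusters in
live-embryo fluorescence images — and of whether those clusters preserve
the positional information of a morphogen gradient.

In the early *Drosophila* embryo the maternal TF Bicoid forms an
exponential anterior–posterior concentration gradient,
`c(x) = c0·exp(−x/λ)` with `λ ≈ 0.2 L`, that nuclei read to learn their
position `x/L`. Inside each nucleus the TF is not uniform: it
concentrates in transient sub-micron clusters. `clustersense`
implements the full quantitative chain for asking what those clusters
know about the gradient:

* **Synthetic embryos with ground truth** — seeded generators for 3D
  nucleus stacks with planted anisotropic Gaussian clusters, gradient
  fields, telegraph-blinking time-lapse videos, two-channel
  cluster + transcription-hotspot stacks, clumped point patterns and
  bead fields. Every downstream stage is validated against planted
  truth; no raw microscopy data is required.
* **Correlation statistics** — masked row-wise pixel autocorrelation
  with an exponential correlation-length fit (`λcorr = x0 + ln2/c`), and
  an FFT pair-correlation estimator for point patterns with window edge
  correction and a Gaussian-clump model fit
  `g(r) = ρ′·exp(−(r/σ)²) + 1`.
* **Detection** — iterative local-threshold maxima detection (Otsu,
  25×25 moving mean+sd, SSIM stopping), 3D cluster detection (top-hat,
  per-nucleus percentile, watershed, 18-voxel support rule), and
  per-cluster 2D Gaussian fits giving size `d = √(σ1²+σ2²)`,
  amplification `Ia/Ibg` and integrated intensity `Ic = 2π·Ia·σ1·σ2`.
* **Segmentation** — morphological pipelines for bright ("filled") and
  dark ("hollow") nuclei, matching between channels, and mapping of
  stage coordinates to fractional AP position `x′ = r·cos θ`.
* **Gradient precision** — x/L binning with bootstrap, log-linear decay
  fits (`λ = −1/slope`), and the positional error
  `σx/L = CV·λ`, plus the absolute molecule budget
  `N0 = N0_flat·L/λ` and its chain to molecules per cluster.
* **Colocalization** — transcription-hotspot detection (DoG + μ+4σ),
  radial TF profiles, the accumulation radius `r0` (FWHM of a
  double-Gaussian fit) and cluster–gene coupling fractions.
* **Sensing limits** — Berg–Purcell-style times for a cluster
  (`T_clust = 6/(D·d·c_clust)·(δN/N)⁻²`) versus a single binding site
  (`T_site = 1/(D·a·c_nuc)·(δN/N)⁻²`) and their D-independent ratio
  `d/(6a)·c_clust/c_nuc`.

## Worked example

```bash
python examples/06_coupling_and_sensing.py
```

prints (exactly this, seed-fixed):

```
coupling fraction at r0=0.44 um: 0.55 (planted 0.55); median distance 0.36 +/- 0.04 um

anterior molecule count N0 = 40000
nuclear density ~611 /um^3, in-cluster ~1345 /um^3, cluster volume 0.034 um^3
molecules per cluster ~45, clustered fraction 6.2%

T_cluster = 1.12 s, T_site = 48.1 s (D = 1 um^2/s, 10% accuracy)
sensing-time ratio T_site/T_cluster = 43.1 (independent of D and accuracy)
```

Reading: converting a flat-expression calibration count of 8000
molecules through the gradient-conservation relation gives 40 000
molecules in an anterior nucleus, a nuclear density of ~600 /µm³ and,
with the measured ~2.2× in-cluster amplification, ~1300 /µm³ inside a
0.4 µm cluster — a few tens of molecules per cluster, ~6% of the
nuclear pool in clusters. A cluster that size nevertheless reads the
nuclear concentration ~40× faster than a single enhancer binding site,
which is the case for clusters as the gradient's sensors. The other
examples print the gradient decay constants (λ_Ic ≈ 0.26 L), the
positional error (≈ 5.6 %L — about three cell diameters), the
diffraction-limited correlation length (0.20–0.21 µm), the confinement
radius (≈ 0.39 µm) and the blinking dwell times (2.4 s on / 1.6 s off
after sampling correction; detection probability ≈ 0.6).

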