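# Methods

This note records the models implemented by `hsoi`, the parameter choices
that matter, what the synthetic data does and does not emulate, and the
numerical conventions — in enough detail to reproduce or audit any number
the package computes.

## Colorimetry conventions

* Wavelength grid: 380–780 nm at 1 nm (401 samples). All integrals are
  1 nm rectangle sums on this grid.
* Tristimulus normalization: k = 100 / Σ S(λ)ȳ(λ), so a perfect reflector
  has Y = 100 under any illuminant and Y is a reflectance-like quantity.
  (Including R(λ) in k would force Y ≡ 100 for every spectrum and destroy
  the meaning of the integral.)
* sRGB: the 4-decimal 3×3 matrix and the standard transfer function with
  encoded-domain threshold 0.04045 — the unique value at which the linear
  and power branches meet continuously. Out-of-gamut values are clipped to
  [0, 1], never wrapped, and the clipping is reported via a flag.
* Chromatic adaptation: CMCCAT2000 with its sharpened 3×3 cone matrix, a
  luminance-ratio term, and degree of adaptation D ∈ [0, 1] (default 1,
  complete adaptation). The reverse transform (whites swapped) is the exact
  inverse; with equal whites or D = 0 it is the identity.
* The packaged observer table is a multi-lobe piecewise-Gaussian analytic
  fit of the CIE 1931 2° color-matching functions, and the default
  illuminant is a Planckian 6504 K spectrum standing in for D65; both are
  marked `synthetic` in their filenames. Every consumer (forward camera
  simulation, calibration, phantom rendering) uses the same tables, so all
  closed-loop results are independent of how closely the fits track the
  measured CIE data. For quantitative work on real cameras, substitute
  measured tables — the CSV schema is `wavelength_nm, value(s)`.

## Checker calibration

The calibration chain is linear-algebraic throughout: an uncentered
6-vector spectral basis (eigenvectors of D·Dᵀ, so spectra reconstruct as
Eᵀα with no mean term), coefficients via pseudoinverse, a 3×20 polynomial
color correction fitted to checker targets, and a 6×3 transformation from
adapted tristimulus values to basis coefficients. All pseudoinverses are
SVD-based with a relative singular-value cutoff of 1e-10; fits agree with
normal-equation solutions to 1e-8 on full-rank inputs.

Chromatic adaptation is applied **symmetrically**: measurement illuminant
→ D65 when building sRGB targets during calibration, and D65 → measurement
illuminant both when forming β during calibration and per pixel at
inference. This makes the noiseless forward model exactly invertible as
far as rank permits.

**The rank-3 bottleneck.** Reconstruction is spectrum = Eᵀ·M·XYZ with XYZ
∈ ℝ³, so the image of the reconstruction operator is 3-dimensional no
matter how many basis vectors are kept. Consequences, all verified by the
test suite:

* scenes whose spectra span ≤ 3 dimensions reconstruct exactly
  (closed-loop RMSE < 1e-9 for rank-3 checker sets fitted with 3 basis
  vectors);
* genuinely rank-6 checker sets leave a metamerism residual
  (RMSE ≈ 4e-2 with the default generator) that no amount of calibration
  can remove — two spectra with the same XYZ are indistinguishable to the
  camera;
* under capture noise the residual is the quadrature sum of this
  systematic floor and the noise response, so at rank 6 small noise levels
  barely move the total, while at rank 3 the error grows from zero
  strictly monotonically with σ.

An alternative β (the 20-vector of polynomial features instead of XYZ,
making M 6×20) is available via `beta_mode="poly"`; it roughly halves the
rank-6 residual but cannot eliminate it, for the same reason.

Serialization stores every matrix entry as a decimal string (`repr` of the
float), so a model survives a JSON round trip bit-exactly.

## Vessel segmentation

Five stages: preprocessing, Gabor enhancement, gamma contrast stretch,
Otsu binarization, FOV masking. Defaults, all exposed in
`SegmentationConfig`:

* Preprocessing: inverted green channel (vessels bright), 3×3 median
  filter. Compact regions — dark lesions (top-decile inverted intensity,
  area < 500 px) and the bright optic disc (bottom decile, area < 3000 px)
  — are filled with the median of a 5 px surrounding ring. Compactness is
  ellipse eccentricity < 0.9 **and** solidity > 0.85; the solidity
  condition protects curved vessel fragments, which can be ellipse-compact
  but are sparse in their convex hull. Intensity percentiles are computed
  over the scene (green > 0.02), not the black surround. A lesion touching
  a vessel merges into an elongated component and is deliberately left
  alone.
* Gabor bank: 12 orientations (15° apart), wavelength 8 px, σ 3 px across
  the ridge, aspect ratio 0.5 (envelope elongated 2× along the ridge).
  Kernels are real and zero-mean, so flat regions give zero response and
  the response is offset-invariant. The per-pixel maximum over
  orientations is the vessel-ness score; it is matched to vessels 3–8 px
  wide, the calibre range of the phantom.
* Contrast stretch: window at the (2, 98) percentiles of the FOV-interior
  response, gamma 0.5. The sub-unity gamma saturates weak vessel-flank
  responses toward the vessel core so that Otsu separates the whole vessel
  class from the tight near-zero background mode; with gamma > 1 the
  threshold lands inside the vessel class and halves recall.
* Otsu: exhaustive 256-level between-class-variance maximization (lowest
  maximizing level on ties), computed over the eroded FOV interior — the
  black surround and the FOV-rim edge response are not part of the scene.
  A guard declares the image vessel-free when the interior 99.5th
  percentile response is below 0.004 (preprocessed-intensity units);
  without it the adaptive threshold amplifies background texture on
  vessel-free images.
* Masking: AND with the FOV disk eroded by 10 px (the disk is auto-fitted
  from image brightness: centroid + equivalent-area radius); connected
  components under 30 px are removed.

On the default phantom the pipeline reaches Dice 0.83–0.93 over seeds
0–7, with recall ≈ 0.96 and precision ≈ 0.8.

## Oximetry

Bare two-chromophore Beer–Lambert in reflection, single effective pass:
A(λᵢ) = d·(c₁ε_HbO₂(λᵢ) + c₂ε_Hb(λᵢ)), solved as a 2×2 system per vessel
pixel. Conventions and parameters:

* Wavelength pair (570, 600) nm: 570 nm sits near an isosbestic crossing
  (total-hemoglobin sensitive), 600 nm has ≈3× deoxy/oxy contrast, giving
  a well-conditioned system. Pairs whose extinction rows are proportional
  (two isosbestic points) raise an explicit singularity error.
* Path length d: per-label vessel thickness when artery/vein labels are
  available (0.0104 / 0.01325 cm), otherwise their mean (0.011825 cm).
* Incident-light reference: each vessel pixel's background is a local mean
  of vessel-free fundus — normalized Gaussian convolution (σ = 15 px) of
  the non-vessel pixels, excluding pixels at the reflectance floor
  (outside the FOV) and bright optic-disc-like pixels (> 2× the median
  background). A local reference matters: SO₂ at high saturation is very
  sensitive to reference bias (a 1% reference error can wipe out the small
  deoxyhemoglobin concentration), and a global mean over a spatially
  varying fundus produces exactly that bias.
* Negative concentrations are clamped to zero and flagged; SO₂ is NaN
  where both concentrations vanish or the absorbance is undefined.

The packaged extinction table is synthetic: Gaussian Soret (415/432 nm)
and Q bands (542/577 vs 556 nm) plus red/NIR tails, shaped to the
qualitative features and magnitudes (10²–5·10⁵ cm⁻¹M⁻¹) of measured
hemoglobin spectra, with isosbestic crossings at 524/546/569/591 nm
(measured hemoglobin: ≈529/545/570/584 nm). Because the phantom's forward
optics and the solver share this table, recovery error measures the
pipeline, not the table; substitute a measured tabulation
(`wavelength_nm, eps_hbo2_cm1M1, eps_hb_cm1M1`) for real data.

## Staging

Mean vessel spectra are scored in a mean-centered 2-component PCA space
(deterministic sign: largest-magnitude loading positive). The shipped
region boxes are the published artery/vein score ranges per stage; interval
membership is strict (`<`), matching their published form. Overlapping
regions are resolved by nearest box center and flagged `ambiguous`; points
outside every box map to the nearest box boundary and are flagged
`out-of-range`. When artery and vein disagree, the artery decision is
primary (arterial spectra separate the stages more cleanly) and the vein
result is reported alongside. The vein PDR SPC range (−0.25, −0.05) is
shipped exactly as published even though it does not overlap the vein
Normal range's sign convention.

Metrics are one-vs-rest on the 4-class confusion matrix. They are computed
in full precision and **truncated** (not rounded) toward zero at two
decimals for table rendering — truncation is the convention that
reproduces all 16 published cohort values exactly (e.g. 43/49 =
87.7551% → 87.75, BDR F1 83.4955% → 83.49).

## Synthetic data: what it emulates, what it does not

* **Checker spectra**: smooth non-negative combinations of `basis_dim`
  Gaussian bumps spanning the grid, scaled into [0.02, 0.95], exact
  spectral rank `basis_dim` by construction. They emulate the smoothness
  and dynamic range of a measured 24-patch checker, not its actual colors.
* **Camera**: the exact forward model of the calibration chain
  (spectrum → XYZ → adaptation → sRGB encoding) plus additive Gaussian
  noise in the encoded domain. No demosaicing, no spectral sensitivity
  mismatch, no quantization beyond optional 8-bit rendering — so
  closed-loop tests isolate the algebra, and real-camera effects (unknown
  sensitivities, flare, compression) are out of scope.
* **Fundus phantom** (default 192×192): circular FOV (margin 4 px),
  reddish background spectrum (sigmoid rising at ≈585 nm) with ±3% smooth
  multiplicative variation, a bright optic disc, and 6 cubic-spline
  vessels of width 3–7 px, alternating artery (SO₂ 0.95) / vein (SO₂
  0.60). Vessel pixels attenuate the local background by
  10^(−d(c₁ε_HbO₂+c₂ε_Hb)) with total hemoglobin 1.2 mM — chosen once so
  the 570 nm absorbance is ≈0.6, mid-range vessel darkness and a
  well-conditioned solve. Vessels keep a 10 px clearance inside the FOV,
  mirroring how the vignetted rim of real photographs is excluded from
  vessel annotation (and matching the segmenter's fixed erosion margin, so
  the ground truth is evaluable). Strokes are hard-edged; no
  anti-aliasing, no pathology morphology (exudates, neovascular fronds),
  no inter-vessel calibre variation within a vessel.

Passing phantom tests therefore demonstrates correctness of the optics,
algebra and image processing under the stated forward model — not
clinical performance on real fundus photographs, which adds spectral
sensitivity mismatch, scattering, pigmentation variation and pathology
appearance that the phantom deliberately omits.

## Problem sizes and determinism

Default test and acceptance problem sizes: 24-patch checkers, 192×192
phantoms, 1000-trial solver oracles, 100-histogram Otsu oracles, 10-seed
noise sweeps — sized so the whole suite runs in well under a minute while
every statistic is stable to the asserted tolerance. Every generator is a
pure function of an explicit integer seed; the CLI logs package version,
config hash and seed, and identical inputs produce byte-identical outputs.
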