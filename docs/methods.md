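# Methods

`echodsi` implements a multiparametric ("disease-specific imaging") analysis
of ultrasound breast lesions: biophysical features are extracted from raw RF,
envelope, and log-compressed data within a segmented lesion, combined into a
scalar malignancy score, and rendered as a per-pixel probability-of-malignancy
color overlay. This note records the models, the parameters that matter, and
the numerical choices made where the design was genuinely open.

## Signal pipeline

**Envelope detection.** The echo envelope is the magnitude of the per-scanline
analytic signal (Hilbert transform). IQ demodulation followed by magnitude
detection is equivalent up to the demodulation carrier; scanner-internal IQ
pipelines are not reproduced.

**Log compression.** `20 log10(A / A_max)` clipped to `[-DR, 0]` dB and mapped
linearly onto `[0, 255]`, with `DR = 60` dB by default. The frame maximum
normalization makes B-mode statistics invariant to global gain. The formula
and dynamic range are the standard B-mode convention; both are configurable.

**Attenuation compensation.** Before H-scan analysis the RF frame is split
into `n_zones = 10` contiguous axial blocks and each block's spectrum is
multiplied by the scalar gain `exp(alpha' * f0 * x_z)`, where `x_z` is the
zone's mean depth (cm), `f0` the center frequency (MHz, default 9.4), and
`alpha'` the attenuation coefficient `alpha` (default 1 dB MHz^-1 cm^-1)
converted to nepers via `ln(10)/20`. The gain deliberately uses the fixed
`f0`, not the spectral frequency axis; a frequency-dependent mode
(`AttenuationConfig(frequency_dependent=True)`) is available. Because real
attenuation is frequency dependent while the default compensation is scalar,
the correction slightly overcompensates the downshifted deep spectrum; the
depth trend of zone-mean envelope amplitude still shrinks by well over half
on simulated frames. Zone boundaries are equal-length blocks with remainder
samples absorbed by the deepest zone; the gain acts on the amplitude
spectrum.

## H-scan color level

A bank of `n = 256` Gaussian bandpass filters with peak frequencies equally
spaced from 5.2 to 12.4 MHz (spacing 7.2/255 ≈ 0.028 MHz) is applied per
scanline in the frequency domain. Each filter is normalized to unit spectral
energy so the per-sample argmax is a matched-filter comparison unbiased by
bandwidth. The comparison uses the magnitude of the filtered analytic signal
(the filtered RF itself oscillates through zero, making a raw per-sample
argmax ill-defined). The winning filter index `C ∈ {1..256}` is the "color
level": low C = low-frequency content (larger effective scatterers), high C =
high-frequency content. Ties break toward the lower index. The filter
spectral standard deviation `sigma_f` defaults to 1.0 MHz (the order of the
pulse bandwidth) and must be reported with results; it is not a published
constant. Lesion-level features are the mean and STD of `C` over the lesion
mask.

A note on exactness: the color map is mathematically invariant to a positive
RF gain. In floating point this holds bit-for-bit for power-of-two gains
(exact IEEE scalings); an arbitrary gain can flip sub-ulp near-ties at
filter-response crossovers by one index.

## Morphology and texture

**Boundary roughness.** `dA/A = (hull area − contour area) / contour area`,
computed from the raw (unsmoothed) contour polygon; convex boundaries give 0.
The measure is invariant to rigid rotation and uniform scaling.

**Margin bands.** The lesion length is the maximum Feret diameter of the
contour. "Margin width = 10% of lesion length" is read as the *total* band
width, so the disk radius is `r = round(0.05 × length)`. Inner band =
mask − erosion(mask, disk r); outer band = dilation(mask, disk r) − mask.
B-mode mean/STD are computed within the lesion (B-scan intensity/STD) and
over the union of the bands (boundary intensity/STD).

**Contour smoothing.** Texture and speckle features use a Chaikin
corner-cut (2 iterations) smoothed contour so that boundary roughness does
not leak into intensity statistics; `dA/A` always uses the raw contour.
Band construction uses the same smoothed mask.

**Display grid.** Texture and margin features are computed on a
near-isotropic grid: the envelope is decimated axially by
`round(lateral_pitch / axial_pitch)` so that pixels are ≈ square. Margin
disks and median/Gaussian kernels in raw RF coordinates would be wildly
anisotropic (axial pitch ≈ 0.02 mm vs lateral 0.3 mm). H-scan and Burr
statistics use the native RF grid, where per-sample spectral information
lives.

## Burr speckle model

Envelope amplitudes within the lesion are fitted with the Burr law

    P(A) = 2 A (b − 1) / (λ² [(A/λ)² + 1]^b),  A ≥ 0,  λ > 0,  b > 1,

whose closed-form CDF `F(A) = 1 − [(A/λ)² + 1]^(1−b)` also provides the
inverse-CDF sampler used as the generative oracle in tests. The fit is
unweighted nonlinear least squares of the density against a histogram whose
bin count is `max(8, round(rate × N))` with sampling rate `rate = 0.10` by
default; the 2–40% sweep (step 2%) reproduces the rate-selection logic and
shows the estimates to be essentially rate-independent while R² drifts down
with rate. Initialization is `λ0 = median`, `b0 = 2`, with a handful of
restarts; `b ≤ 50` guards against divergence toward the Rayleigh limit.

Histogram range: `[0, min(max, 20 × median)]`. For light tails the cap is
inactive (range = data maximum); for heavy tails (b near 1) the largest draw
exceeds the bulk by orders of magnitude and an equal-width histogram to the
maximum starves every informative bin — the median-multiple cap keeps ~97%+
of the mass in range and parameter recovery within a few percent down to
b = 1.5.

## Combined scores

Features are standardized per feature with training-set mean/STD, frozen for
test use. The default selected subset is {H-scan color level, boundary shape
dA/A, B-scan STD, boundary STD, Burr b}; an exhaustive in-sample AUC search
over all 2⁹ − 1 = 511 subsets of the nine candidates is provided
(`select_features`). When that search is scored by the SVM distance it uses a
fixed mid-grid SVM (box 1, gamma = 1/m) per subset rather than the full
cross-validated grid — 511 × 16 × 5 fits would add nothing but runtime to an
in-sample ranking.

* **PC1** — first principal component of the standardized training features,
  sign-oriented so the malignant-class mean exceeds the benign-class mean
  (orientation-stable color maps). Per-feature contributions are the
  normalized absolute PC1 loadings.
* **Projection** — inner product with the unit benign→malignant centroid
  direction in standardized space. (The reference direction has no published
  closed form; the centroid difference is the natural two-class choice.)
* **SVM distance** — signed decision value of a Gaussian-kernel soft-margin
  SVM. `(box, gamma)` are selected by seeded 5-fold cross-validated accuracy
  on the grid {0.1, 1, 10, 100} × {0.01, 0.1, 1, 10}; ties prefer the smaller
  box then the smaller gamma (the smoother hyperplane). The decision value is
  zero exactly on the hyperplane and its sign is the predicted class (−1
  benign, +1 malignant). A *geometric* mode returns the Euclidean distance in
  standardized feature space to the nearest point of the decision surface
  (bracketing + bisection toward opposite-sign support vectors, refined by
  SLSQP with the surface as an equality constraint); it is slower and used
  for visualization-faithful distances only.

The trained model (standardization, PC1 loadings and contributions,
reference direction, SVM support vectors/dual coefficients/bias, clipping
limits) serializes to a single versioned JSON document.

## Probability map and overlay

A score is mapped to a probability of malignancy by clipping between
`(d_lo, d_hi)` — the 5th/95th percentiles of the training scores by default —
and rescaling linearly onto [0, 1]. Within a lesion the H-scan color level is
the only localized feature, so the per-pixel combined parameter substitutes
the pixel's own color level into the lesion-global feature vector and
re-evaluates the combiner (for PC1 and projection this is linear, so the
pixel-mean score equals the score of the mean vector). The map is smoothed by
a mask-aware 2-D median filter (5 px) then Gaussian (sigma 2 px); out-of-mask
pixels never contribute (windows renormalize over in-mask weight), and output
values stay within the input range. Two 256-entry colormaps ship
(green→red and light-blue→red, the latter the overlay default); the overlay
alpha-blends colormap(prob) over the grayscale B-mode inside the lesion and
leaves the exterior untouched, byte-reproducibly.

## Evaluation protocol

AUC is the Mann–Whitney rank statistic with half credit for ties; its 95% CI
uses DeLong's structural-components estimator (implemented here; no installed
package provides it). Operating accuracy/sensitivity/specificity are taken at
the threshold maximizing Youden's J on *training* scores only, frozen for the
test fold. Per-feature class separation is a one-way ANOVA with the notation
ns / * / ** / *** / **** at p cut points 0.05 / 0.01 / 0.001 / 0.0001.
Cohorts are evaluated over five seeded stratified 70/30 train/test splits,
reported as mean ± STD; the lesion-size stratification re-runs the protocol
keeping only lesions with area strictly greater than each threshold in
{0.0, 0.1, …, 1.0} cm², marking (not dropping) strata with fewer than two
cases of either class. A leakage invariant is tested: shuffling test labels
changes no fitted parameter.

## Synthetic cohort generator

The generator exists so every stage is testable without patient data. Each
case is a 1-D per-scanline convolution of a Gaussian-modulated cosine pulse
with a random scatterer train (no diffraction, beamforming, or transducer
model), followed by zone-wise frequency-dependent attenuation
`exp(−alpha' f x)` and additive Gaussian noise. Speed of sound is fixed at
1540 m/s.

Default study conditions (the strong-effect cohort): 40 benign + 40 malignant
cases; benign lesions carry 8.5 MHz spectral content, echogenicity ratio 1.0,
boundary roughness 0.05, Burr b 3.5; malignant lesions 10.5 MHz, 0.5, 0.5,
b = 2.0; background 9.4 MHz content, attenuation 1 dB MHz⁻¹ cm⁻¹. The effect
sizes are deliberately large so that separability is forced and end-to-end
classification checks are sharp. Acquisition geometry is a package
convention, not a clinical fact: 30 mm depth × 19.2 mm width, fs = 36 MHz,
64 scanlines at 0.30 mm pitch, fractional bandwidth 0.6, background scatterer
density 100 mm⁻² (≥ 10 per resolution cell, the fully-developed-speckle
regime).

Lesion boundaries are ellipses (semi-axes 3.5–6 mm) radially perturbed by
circularly-smoothed Gaussian noise with amplitude `roughness × mean radius`
— roughness 0 yields the inscribed convex ellipse and expected dA/A grows
monotonically with the parameter. Lesion scatterer reflectivities are drawn
from the Burr law itself with the class b (random sign), scaled so that mean
lesion echo intensity over background matches the squared echogenicity
ratio. The fitted envelope b then separates the classes monotonically; no
claim is made that the fitted value equals the reflectivity parameter
(summation over the resolution cell lightens tails), and no per-class
calibration loop is attempted.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: diffraction and elevational beam structure, speckle
correlation from real apertures, tissue heterogeneity outside the lesion,
posterior shadowing/enhancement, scanner post-processing, and
operator-dependent contouring. Tests establish that each operator measures
what it claims on signals with the assumed statistical structure, not
clinical performance.

## Problem sizes

Desk-scale sizes keep the full pipeline fast while leaving every contract
sharp: Burr calibration at n = 5×10⁴ samples; hull checks on 200 random
polygons of ≤ 12 vertices; tone frames of 1024 samples for H-scan; one
simulated speckle frame (~50 000 scatterers) for the attenuation check; the
80-case cohort for the end-to-end pattern. The acceptance script
(`scripts/acceptance.py`) recomputes all of these from scratch in about a
minute.

## Known limitations

* The 1-D simulator cannot probe lateral-resolution effects or scan
  conversion; margin geometry is exercised on the near-isotropic display
  grid only.
* The geometric SVM distance is a numerical search; it is validated against
  a dense-grid oracle in 2-D but has no closed-form guarantee in higher
  dimensions (non-convex surfaces can in principle hide a nearer sheet).
* The Burr fit is a least-squares histogram fit, not maximum likelihood;
  its R² depends on the histogram range rule described above.
* BI-RADS-style reader grades appear only as a generic ordinal column for
  rank correlation; no clinical mapping is encoded.
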