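# Methods

This note documents the models, parameter choices, and numerical decisions
behind `rhizospec`, and what the synthetic-data tests do and do not show
about real rhizobox images.

## The classification problem

A VNIR hyperspectral cube of a rhizobox face records a reflectance spectrum
(nominally 150 bands, 470–900 nm) per pixel. Three classes are
distinguished: *soil*, *root*, and the *root-soil interface* — the
rhizosheath zone where exudates bind soil to the root surface. The
interface is spectrally a mixture of the other two and is not expected to
be cleanly resolvable; it is kept because it sharpens the root/soil
boundary. Labels use a fixed dictionary 0 = unlabeled, 1 = soil,
2 = interface, 3 = root, and the same order breaks classification ties.

## Pixel hygiene

- **Reflectance correction.** `R = t · (raw − dark)/(white − dark)` per
  band, with the white-panel target `t = 0.95` (the reflectance of the
  reference panel used at acquisition). Values are *not* clipped: clipping
  would hide overexposure from the downstream mask. Bands with
  `white = dark` everywhere are flagged unusable; if all bands are
  degenerate the correction refuses to run.
- **Overexposure.** Any pixel with a band above reflectance 1 has its whole
  spectrum zeroed and its mask cleared. Zeroing only the offending band
  would corrupt spectral angles and derivatives, so the pixel is removed
  outright; the count is recorded in cube metadata for audit. The operation
  is idempotent.
- **Binning/cropping.** Non-overlapping N×N block means, trailing partial
  blocks dropped (sensor-style); crops are 0-based, origin top-left,
  half-open. Binned masks are conservative (a block is usable only if all
  its source pixels were).

## Pre-classification

- **SAM.** References are ROI mean spectra (masked pixels excluded; ROIs
  below 100 pixels warn rather than fail, since the minimum is a study
  convention, not an algorithmic requirement). A pixel is labeled by the
  reference of minimum angle when that angle is ≤ the threshold (default
  10°, inclusive); zero-norm or masked pixels stay unlabeled. SAM output is
  invariant to positive per-pixel scaling — the point of using angles under
  uneven illumination.
- **K-Means.** Our own Lloyd's loop: Euclidean distance over full spectra
  (all 150 bands, pre-selection), greedy farthest-point seeding from a
  seeded RNG, stop at assignment convergence or 20 iterations, empty
  clusters keep their centroid (preserving the monotone non-increasing
  inertia guarantee). Deterministic per seed. Clusters are then named by
  minimum spectral angle of their centroid to the ROI references; without
  references, a documented heuristic orders the k = 3 clusters by mean
  reflectance (soil darkest, root brightest).

## Band selection

The Savitzky–Golay second derivative of the *root-class* mean spectrum is
the data-reduction signal: it suppresses additive offsets and linear
baseline drift, leaving curvature features. Defaults: window 21 bands,
polynomial order 3 (an order ≥ 2 is required for a second derivative; 3 is
the common derivative-spectroscopy default — the order is a package choice,
as is unit band-index spacing, since windows are quoted in bands).
Edges use scipy's one-sided truncated-window polynomial fits rather than
reflection padding, to avoid inventing data beyond the recorded range.
`compare_windows` reports per-window roughness (sum of squared successive
differences) as a quantitative aid: small windows keep noise artifacts,
windows past ~25 bands over-smooth genuine features.

Per-image derivative curves are averaged band-wise, and the retained
wavelengths are the local peaks and troughs of the averaged curve with
`|value| ≥ 0.05 · max|curve|` (scale-invariant prominence), thinned to a
minimum separation of 3 bands (stronger extremum wins; ties go to the
lower index). The published workflow picked extrema visually; this
deterministic surrogate keeps both knobs in config. On smooth synthetic
root spectra it retains well under a fifth of the bands.

## Label transfer and evaluation

Labeled pixels (masked and unlabeled rows dropped — SAM's above-threshold
pixels are excluded exactly as unlabeled rows) are restricted to the
selected bands, split 80/20 by a seeded uniform permutation
(`|train| = round(0.8 n)`, no stratification — imbalance is possible and
accepted), and fed to a Random Forest (50 trees, fixed seed) or linear SVM
(C = 1.0, a package default since no value is standard for this data).
Whole-image prediction labels every usable pixel (the model never emits
unlabeled); masked pixels stay 0. Wavelength compatibility between model
and cube is enforced to within one band-center spacing.

Evaluation excludes unlabeled-truth pixels from per-class metrics (they
carry no reference information and would skew averages) but keeps them as
an extra truth row of the confusion matrix. Macro F1 is the unweighted
mean of the three semantic per-class F1s, never including an unlabeled
pseudo-class. Each F1 is the harmonic mean of that class's own precision
and recall.

PLS scores use the NIPALS implementation in scikit-learn (PLS2, one-hot
group response, 2 components, centering only, convergence run essentially
to machine precision so results are reproducible and match an independent
eigen-decomposition construction). The test-suite oracle is exactly that
independent construction.

## Biomass

Class percentages are computed over *all* pixels — the unlabeled share
stays in the denominator and is reported explicitly rather than silently
redistributed. Surface area per class is `pct/100 × width × height` (mm²),
so class areas sum exactly to the physical image area and the estimate is
invariant to image resolution at fixed class fractions. Replicate time
series are summarised as mean ± standard error (σ/√n), with single
replicates flagged (SE reported as 0). These are visible-surface
approximations: they ignore biomass hidden in the rhizobox depth and were
never calibrated against destructive measurements.

## Synthetic scenes

The generator emulates the geometry and spectral structure of a rhizobox
face, not its radiometry:

- **Geometry.** Downward-biased random walks from the top edge (persistent
  horizontal direction between down-steps, so strands never revisit a
  pixel), optional branching, dilated to a configurable radius; the
  interface is exactly the morphological halo `dilate(root, r) \ root`.
  Species presets vary strand count/thickness/branching only.
- **Spectra.** Soil: low, gently rising line. Root: brighter, with a
  sigmoidal red-edge rise (center 700 nm, width 30 nm) to a NIR plateau;
  mean root reflectance exceeds soil by > 0.1 by construction. Interface:
  `α·root + (1−α)·soil` with α drawn once per scene from (0.3, 0.7).
- **Noise.** Independent per-pixel-per-band Gaussian, multiplicative
  σ_m = 0.03 and additive σ_a = 0.01 by default; Gaussian (rather than
  Poisson shot) noise keeps the per-band soil SD analytically
  `sqrt(σ_a² + (σ_m·E_b)²)`, which the suite verifies within 10% at
  ≥ 10⁴ pixels. Planted overexposed pixels get one band pushed above 1 and
  are the only unlabeled ground-truth pixels.
- **Sizes.** Default scenes are 120×160×150 (tests also use 80×100); full
  sensor frames (1528×2048) appear only in the binning-geometry check, at
  2 bands, since that contract is band-independent. These sizes are the
  package's choice of desk-scale problem sizes.

What passing means — and does not. The generator's linear-mixture
interface, piecewise-smooth endmembers, and i.i.d. Gaussian noise make the
three classes nearly separable at default noise, so end-to-end macro F1
≈ 1.0 here says the pipeline machinery is correct, *not* that real
rhizobox images (heterogeneous peat soil, moisture gradients, vignetting,
correlated sensor noise) would score as high. The noise-grid test shows
the expected degradation: accuracy is non-increasing in σ and collapses
once SAM's 10° threshold starts rejecting most pixels (~4× default noise).

## Band-recovery oracle

The recovery check plants five Gaussian absorption dips (σ = 3 bands,
30-band spacing, depth 0.08) on a sloped baseline; the analytic second
derivative then has a peak at each center and troughs at the ±√3σ
shoulders (15 extrema). Recovery is asserted within ±2 bands of those
analytic locations across seeds, using an 11-band SG window for this check:
with σ = 3-band features, a 21-band window broadens the signal enough to
shift shoulder extrema beyond the 2-band contract — an instance of the
general rule that the window must stay below the feature-resolving limit.
The default pipeline window remains 21, matched to the broader curvature
features of real root reflectance spectra.

## Determinism

All randomness flows from explicit seeds (scene seed, K-Means seed, split
seed, RF seed; the pipeline derives all of them from one global seed).
The pipeline writes a manifest of SHA-256 content hashes over every
artifact; a rerun with identical config and inputs is bit-identical, which
the suite asserts.

## Known limitations

- ENVI support covers the common float/integer types, BSQ/BIL/BIP reads,
  and BSQ float32 writes; exotic header dialects are out of scope.
- The interface class is a modeling convenience; no claim is made that the
  rhizosheath is spectrally a two-member linear mixture.
- Surface area is not biomass; no calibration is provided.
- The K-Means route inherits K-Means' known weaknesses on non-spherical
  clusters; it is retained as the unsupervised baseline, and label-transfer
  training from SAM labels is the recommended route.
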