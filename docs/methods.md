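# Methods

## Forward model: from packing scaling D to the spectral readout Σ

The chromatin mass-density autocorrelation of a packing domain is modeled
as a pure power law with an exponential cutoff:

    B(r) = φ(1−φ) · (r/r_min)^(D−3)        r_min ≤ r ≤ r_d
    B(r) = B(r_d) · exp(−(r−r_d)/r_d)      r > r_d

The amplitude φ(1−φ) is the density variance of a two-phase medium at
chromatin volume concentration φ; the power law makes the identity
D − 3 = ∂logB/∂logr exact, which is what the slope-inversion contract and
its tests rely on. The Whittle–Matérn family used elsewhere in tissue
optics reduces to the same slope in the fractal regime but blurs the
identity near the cutoffs; the pure power law was chosen so the D↔slope
relation is testable to machine precision.

The domain radius is tied to the domain's genomic content through the
mass-fractal relation r_d = r_min · (N_f / 1 kbp)^(1/D), with 1 kbp taken
as the genomic content of one r_min = 10 nm chain unit. At the default
N_f = 200 kbp this gives r_d ≈ 77 nm at D = 2.6, consistent with the
~80 nm average physical radius of packing domains. Both the cube generator
and the calibration builder derive r_d this way (`ChromatinParams.at_d`),
so simulation and inversion live on the same curve — an earlier version
that fixed r_d in the generator while re-deriving it in the calibration
produced a ~0.05 systematic recovery bias.

Σ is computed as

    Σ = α · ρ_scale · sqrt( mean over [s_lo, s_hi] of B(r) )

with the sensitivity window [23, 334] nm as a hard band-pass. The full
coherence-volume smoothing S(r) depends on Fresnel coefficients and the
NA geometry; the band-pass surrogate preserves the two properties the
pipeline needs — Σ strictly increasing in D at fixed φ, N_f (verified
numerically across D ∈ [2.02, 2.98] and enforced at calibration time with
a hard failure on non-monotonicity), and Σ first-order in the
refractive-index fluctuation amplitude α·ρ_scale. Whether the real window
is hard or soft changes the calibration knots, not the architecture.

Defaults: n_media = 1.337 (aqueous), α = 0.18 (specific refractive
increment of biological macromolecules), ρ_scale = 1.6 in the same density
units, chosen so Σ spans ≈ 0.040–0.075 over D ∈ [2.02, 2.98] — the upper
part of the range PWS instruments report, and an SNR of ≥ 2 against the
0.02 spectral noise floor used in the validation experiments. At
substantially lower signal (Σ ≈ noise), the Σ-estimation error is
dominated by the signal×noise cross term (SD ≈ 2νΣ/√n_λ per pixel) and
boundary clipping makes nucleus means unrecoverable near D = 2.9 for any
estimator; the default amplitude keeps the pipeline in the regime the
quality targets assume.

## Spectral-cube synthesis

Each in-mask pixel carries an interference fringe on the normalized
spectrum: a cosine in wavenumber with amplitude √2·Σ(D_pixel), optical
path difference 2·n_media·(depth of field) with ±5% per-pixel jitter, and
a uniform random phase, plus additive i.i.d. Gaussian spectral noise of SD
`noise_sd` per (pixel, wavelength). A fringe, rather than i.i.d. Gaussian
signal draws, is the physically faithful model of spectral interference
and makes the per-pixel sample SD converge deterministically to Σ as the
wavelength axis covers more fringe periods (worst case ±1.9% at the
default 101-sample, 500–700 nm axis); with i.i.d. draws the per-pixel SD
would carry an irreducible ~7% sampling error. Out-of-mask pixels carry
the reference spectrum exactly. Fidelity limits: no 3-D refractive-index
field propagation (no FDTD), no stain/debris/mucus artifacts, no 3-D
nucleus geometry — so tests passing here certify the statistical pipeline,
not instrument physics.

## Σ extraction and inversion

`compute_sigma` uses the sample (n−1) standard deviation after per-pixel
mean removal; the interference baseline is uninformative, and mean removal
makes Σ invariant to wavelength-independent offsets. An optional
`noise_floor` subtracts a known spectral-noise SD in quadrature
(Σ = √max(s² − ν², 0)) — the standard PWS noise-floor calibration; with
the matched floor the noisy round trip is unbiased.

The calibration evaluates the forward model on a D grid (default
{2.02, 2.05 … 2.95, 2.98} — knots beyond the 2.1–2.9 physiological range
reduce boundary clipping of noisy pixels) and inverts by monotone
piecewise-linear interpolation. Σ outside the knot range clips to the
boundary D and is flagged rather than extrapolated, since extrapolation
would leave the physical (2, 3) interval; nucleus averages exclude flagged
pixels and record the clipped fraction.

Measured round-trip accuracy (64-pixel nuclei, 101 wavelengths): noise-free
max |error| ≈ 0.009 across D ∈ {2.2 … 2.9}; with spectral noise SD 0.02
and matched floor, max |error| ≈ 0.027.

## Cohort generator

Defaults are the study conditions the analysis assumes: group sizes
135/13/15/74/9/10 (Control / diminutive adenoma / nondiminutive adenoma /
advanced adenoma / HNPCC / CRC), 40 nuclei per patient, ages ~N(57, 8) for
controls and ~N(62, 8) for cases truncated to [40, 90], sex near-balanced
(49%/48% female), slightly more smokers among cases and more drinkers
among controls, and advanced-adenoma lesion sizes in the 23/35/16 mix
(<1 cm / 1–1.5 cm / >1.5 cm). Group-mean D rises Control < DA < NDA < AA
< HNPCC < CRC with a between-patient SD of 0.075 and a control–AA gap of
0.06, i.e. a standardized case separation of 0.8 — the magnitude of effect
the method is designed to resolve. The paper-scale group-mean increments
(0.02–0.03 for the small groups) sit within one standard error at
n = 9–15, so the sampled ordering of HNPCC vs CRC is stochastic at study
scale; it is deterministic by n ≈ 2000 per group, and the generator's
ordering guarantee is on the configured means.

The −0.008 per-year age effect on D is applied around each group's own
mean age. Group-centering preserves the configured group means exactly in
expectation (cohort-centering would shift case groups by −0.008 × ~5 yr);
the within-group slope that ANCOVA estimates is unaffected. A consequence
worth noting: with cases older than controls, equal group means plus a
real age effect imply a genuinely positive age-adjusted case coefficient,
so the "null" for case-effect testing must equalize age distributions too.

Intranuclear heterogeneity is not reported in the source literature;
per-nucleus D scatters around the patient mean with SD 0.04 (configurable),
a value that leaves patient means estimable from ~8 nuclei in the demo
configurations while keeping nucleus images visibly textured.

All generators run off `numpy.random.default_rng(seed)` streams derived
from one master seed by fixed offsets and are bit-reproducible.

## Risk model

Annual advanced-adenoma→CRC hazards are stratified by sex and by age
below/above 80 and converted to cumulative probabilities via
1 − exp(−annual·t) over a 5-year horizon (parameterized). The shipped
stratum values (2.1–5.0% per year), the per-group cumulative
future-advanced-adenoma probabilities, and the metachronous-CRC risk are
**PLACEHOLDER** configuration — the cited surveillance literature does not
print them — and every output carries a fingerprint of the resolved risk
configuration. The printed equation's grouping AAr·Σ(cumulative terms) is
followed as written. Colonoscopy-history categories (no / low-risk /
high-risk history) come from a configurable rule table mapping finding
codes to categories, with the highest-risk finding winning.

The demo regression of group-mean D on modeled risk is reported both over
all six groups and over the adenoma-progression pathway (CRC excluded):
the CRC group's modeled risk is dominated by the separate metachronous
term, which lives on a different scale from the future-adenoma pathway
shared by the other groups.

## Classifier

Preprocessing crops the nucleus bounding box, pads to square, resizes
(bilinear; background filled with the in-nucleus mean before resizing so
interpolation does not bleed background into the boundary), then min-max
normalizes to [0, 1] using the in-nucleus extrema of the resized image — a
constant nucleus maps to 0.5. Default side 224 px (the standard pretrained
-backbone input); the validation experiments use 24–32 px, which loses no
information at the simulated nucleus sizes.

The default feature extractor is a deterministic texture bank: intensity
moments, gradient energy, gray-level co-occurrence contrast / homogeneity /
correlation / energy / entropy at five symmetric offsets averaged over the
four principal angles, and ring-averaged spatial-frequency power in eight
radial bands — each term exactly invariant under 90° rotation. A
pretrained CNN backbone is an optional plug-in requiring torch/torchvision
with local weights; nothing in the default path downloads anything.
Because per-nucleus min-max normalization removes the absolute D level —
which is itself the primary biomarker — `nucleus_feature_matrix` appends
the raw-scale nucleus D mean and SD to the texture features.

The autoencoder is a single hidden layer of width `latent_dim` with
identity activation (a linear bottleneck, equivalent in capacity to PCA),
trained to reconstruct standardized features under mean-squared error with
L-BFGS for a fixed epoch budget; it is deterministic given the seed and
reports its final reconstruction error. Depth/width and the training loss
are not constrained by the source problem description; the linear choice
is declared, not inferred.

Cross-validation is repeated stratified k-fold (default 4×5) at the
patient level — all nuclei of a patient share a fold, since nucleus-level
splitting would leak patient identity. Within each training fold the
scaler, autoencoder, forest (grid-searched by inner stratified CV:
trees {100, 500}, depth {∞, 10}, features-per-split {√p, p/3} by default)
and the ROC cutpoint are fit on training data only. Patient scores use
score aggregation by default: the forest is trained on nucleus-level
latents carrying the patient's label, and a held-out patient's score is
the mean of its nucleus scores. The alternative (mean latent per patient,
one forest row per patient) is available as `aggregate="latent"` but is
fragile: after standardization every feature has unit variance, so whether
the linear bottleneck retains the biomarker direction is a property of the
correlation structure realization, and patient-level training (~10² rows)
is noisy; nucleus-level training (~10³–10⁴ rows) recovers weakly
represented directions and yields continuous patient scores. Measured on
the analytic-AUC property below, latent aggregation missed by up to 0.14
on some cohort realizations while score aggregation stays within 0.04.
The optimal cutpoint scans midpoints between adjacent sorted unique scores
plus one threshold below the minimum and one above the maximum
(rule: score ≥ t ⇒ case), maximizing total correct classifications with
ties broken toward the lower threshold (higher sensitivity).

The classifier validation experiment generates control-vs-case cohorts of
100 patients per group, 8 nuclei each, standardized patient-mean
separation 0.8, simulates every nucleus through the optical forward model,
and compares the cross-validated mean AUC with the analytic normal-model
reference Φ(d/√2) evaluated at the sample separation; three independent
cohort replicates are averaged, since a single cohort realization carries
~0.03–0.04 AUC noise that reflects the draw, not the pipeline. Typical
result: pipeline ≈ 0.66–0.70 vs analytic ≈ 0.68–0.73, gap ≲ 0.04 — the
residual deficit is cross-validation's finite-training pessimism.

## Statistics

Two-sample comparisons use Welch's t (no equal-variance assumption) with
Cohen's d on the pooled SD; both choices are declared in the output
metadata since the source reports bare p-values and "effect size".
Multi-group tables carry unadjusted and Holm-adjusted p-values. The
confounder model is OLS of patient-mean D on case status, age, sex,
smoking and drinking, with a hard failure on rank-deficient designs.
Patient QC reports the strict >30-cells rule and the CI-precision rule
(t-based 95% CI half-width < 5% of a configured control–case reference
difference) separately, plus their conjunction.

## Numerical and interface choices

Pixel coordinates are 0-based row-major; the wavelength axis includes both
endpoints (101 samples at 500–700/2 nm). HDF5 is the canonical cube format
(datasets `/intensities`, `/wavelengths`, `/reference`, attribute
`pixel_pitch`); TIFF is an interchange convenience (one page per
wavelength + JSON sidecar). Configurations are validated with unknown keys
rejected, round-trip serialize-stable, and fingerprinted by a SHA-256 of
the resolved block; every pipeline manifest records the fingerprint and
seed, and a rerun with both unchanged reproduces all outputs.

## Problem sizes

The validation experiments use 64-pixel nuclei for D recovery, 5,000
patients for ANCOVA recovery, 2,000 patients per group for the trend
check, 100 patients per group × 8 nuclei × 3 replicates for the classifier
property, and 4 label randomizations × 100 patients for the permutation
null — sizes at which each check's sampling error is comfortably inside
its tolerance while the whole suite runs in a couple of minutes on one
CPU.

## Known limitations

- The Σ forward model is analytic, not electromagnetic: absolute Σ values
  are internally consistent, not instrument-calibrated, and the Σ→D lookup
  is simulator-derived rather than anchored to ChromTEM ground truth.
- φ and N_f are configuration inputs, not estimated from data.
- The risk-model numbers are placeholders; only the model's arithmetic and
  monotonicity are validated.
- Synthetic nuclei are disks with spatially unstructured intranuclear D;
  classifier results certify the learning machinery, not morphological
  feature discovery on real chromatin images.
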