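# chromascan

Chromatin packing-scaling analysis of chromatin-sensitive partial wave
spectroscopic (csPWS) microscopy data, built for studying colorectal field
carcinogenesis from rectal brushings — with a synthetic data generator so
the entire analysis runs end to end with no external data.

## The science

Supranucleosomal chromatin folds into packing domains (~100–200 nm radius,
~100–1,000 kbp) whose internal conformation follows a mass-fractal scaling
law N_f ∝ r^D. The packing scaling exponent **D ∈ (2, 3)** fixes the
log-log slope of the chromatin mass-density autocorrelation B(r):

    D − 3 = ∂ log B(r) / ∂ log r

csPWS measures D indirectly: spectrally resolved backscattered images
I(x, y, λ) (500–700 nm, 2 nm steps) are normalized by a blank-slide
reference, and the per-pixel standard deviation of the interference
spectrum, **Σ**, quantifies refractive-index fluctuations
(n(r) = n_media + αρ(r)) within each coherence volume. Σ integrates the
spectral density of B(r) over the instrument's 23–334 nm length-scale
sensitivity window, so a monotone calibration curve Σ(D) — built here from
the package's own analytic forward model, parameterized by chromatin volume
concentration φ and domain genomic size N_f — inverts Σ maps into per-pixel
D maps.

Downstream, the package aggregates nucleus-level D to patients (with the
>30-cells and confidence-interval quality rules), compares diagnostic
groups (Welch's t, Cohen's d, ANCOVA over age/sex/smoking/drinking),
relates group-level D to a 5-year cumulative colorectal-cancer risk model

    risk = [ AAr · Σᵢ (1 − e^(−annualᵢ·t)) + N_c · CRCm ] / (N_a + N_c)

and evaluates an AI-enhanced classifier: nucleus D-map images →
texture-bank features (an optional pretrained CNN backbone can be plugged
in) → autoencoder reduction → random forest, scored by repeated stratified
4-fold cross-validation at the patient level with per-fold optimal-cutpoint
sensitivity/specificity.

## Layout

- `src/chromascan/` — the library: `synthetic` (forward model, cubes,
  cohorts), `core` (Σ extraction, calibration, inversion), `nuclei`
  (segmentation, aggregation, QC), `risk` (hazard model, regression),
  `classify` (features, autoencoder, forest, CV), `stats` (group tests,
  ANCOVA), `io`/`config`/`pipeline`/`cli` (formats, validation, chaining).
- `analysis/01…05_*.py` — numbered drivers reproducing each analysis and
  writing tables under `results/`.
- `tests/` — the pytest suite.
- `docs/methods.md` — model assumptions, parameter choices, limitations.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_d_recovery.py
```

The first call generates the study-scale cohort (256 patients:
135/13/15/74/9/10 across Control/DA/NDA/AA/HNPCC/CRC) and prints, among
other things, the true group-mean packing scaling:

    Control   2.535
    DA        2.564
    NDA       2.578
    AA        2.604
    HNPCC     2.656
    CRC       2.634

— group means rise along the progression order by construction (the small
HNPCC/CRC groups, n = 9 and 10, can swap in a single draw, as they do
here). The second call pushes eight nuclei with known D ∈ {2.2 … 2.9}
through the full optical round trip (spectral cube → Σ → calibration →
inversion) under spectral noise SD 0.02 and prints:

    true_d  estimated_d  abs_error
    2.2000       2.2025     0.0025
    ...
    2.9000       2.8850     0.0150

    max |error| = 0.0150 (64 pixels/nucleus, spectral noise SD 0.02)

i.e. nucleus-mean D is recovered to ~0.01–0.02 across the physiological
range. `03` runs the group statistics (control-vs-AA effect size 0.74 on
this cohort), `04` the risk model (D vs modeled 5-year risk, r² = 0.97
over the adenoma-progression groups), and `05` the cross-validated
classifier (mean AUC 0.655 against an analytic reference of 0.693 for the
configured separation).

A `chromascan` CLI wraps the same stages (`simulate`, `dmap`, `aggregate`,
`risk`, `classify`, `report`, `run`); `chromascan run --out DIR --seed 0`
executes the whole pipeline on a small demo configuration and writes a
manifest with the resolved-config fingerprint.

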