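# Methods

## Problem

Primary aldosteronism (PA) remodels the arterial wall (fibrosis,
stiffening) beyond what essential hypertension (EH) does, and these
micro-structural changes plausibly alter the speckle texture of the
carotid far wall on B-mode ultrasound. The package implements the full
analysis chain for asking whether wall texture carries diagnostic
information: extract a fixed 152-feature texture signature from a thin
intima-media region of interest (ROI), screen each feature for group
differences, and evaluate multivariate classifiers patient-by-patient
with leave-one-out (LOO) cross-validation. Because clinical scan
archives of this kind are private, the package ships a synthetic cohort
generator that reproduces the *structure* of such a study — it is
first-class, tested code, and every downstream stage runs end-to-end on
it.

## Preprocessing

Images are 8-bit grayscale (PNG; single-frame grayscale DICOM is read
and window-rescaled to 0–255). Preprocessing is per image:

1. **Intensity normalization** — percentile-clipped linear rescale, the
   1st/99th percentiles mapping to 0/1 (clipped). Percentiles rather
   than min–max so that a handful of saturated caliper pixels cannot
   compress the dynamic range. Whether the original study normalized
   globally or per image is not recoverable; per-image is the documented
   choice here.
2. **Caliper-dot removal** — connected components of near-saturated
   pixels (≥ 0.98 of the normalized range) with area ≤ 30 px are masked
   and filled by iterated 4-neighbour averaging (discrete harmonic
   infill, convergence 1e-6). The area cap leaves large saturated
   structures such as the adventitia band untouched. The operation is
   idempotent.
3. **ROI rasterization** — the ROI polygon (0-based `(row, col)`
   vertices at pixel centers, implicitly closed) is rasterized to the
   pixel set Ω: a pixel belongs to Ω when its center is covered by the
   closed polygon (boundary inclusive). An axis-aligned rectangle with
   corners (0,0)–(4,9) therefore contains exactly 5×10 pixels.
4. **Crop** — image and mask are cropped to the ROI bounding box plus a
   56 px margin (the total support of three undecimated Haar levels,
   2·(2³−1)·2 ≈ 56 per axis, rounded up), clamped at borders, so wavelet
   boundary effects cannot reach Ω.

## The 152 texture features

All statistics use only pixels of Ω (|Ω| = pixel count).

**First order (2).** μ = mean intensity over Ω; σ = population standard
deviation (divisor |Ω|).

**Haralick / GLCM (140).** Intensities over Ω are quantized into
N_g = 16 uniform bins spanning Ω's own [min, max] (the ROI maximum maps
to level N_g−1; a constant ROI maps to level 0). Binning over the ROI's
own range makes the whole block invariant to intensity shifts; a fixed
[0,1] range is available by flag. For displacement d ∈ {1..5} pixels
along direction θ ∈ {0°, 45°, 90°, 135°} (unit offsets: up, up-right,
right, down-right; the offset is d unit steps along θ), the gray-level
co-occurrence matrix P_{d,θ}(a,b) counts ordered pairs of quantized
levels at that offset with **both** pixels in Ω, normalized by the raw
pair count Z to sum to 1. The default is the directed (ordered) count;
a symmetric mode (adding the transpose) is a flag. Seven scalar
measures per matrix, a ∈ {1..7}:

1. inverse difference moment  Σ_{a≠b} P(a,b)/|a−b|²
2. correlation  Σ (a−μ_a)(b−μ_b) P(a,b) / (σ_a σ_b)  — defined as 0
   (flagged) when either marginal variance vanishes
3. contrast  Σ |a−b|² P(a,b)
4. maximum  max P(a,b)
5. energy  Σ P(a,b)²
6. dissimilarity  Σ |a−b| P(a,b)
7. entropy  −Σ P ln P (natural log, 0·ln 0 = 0; the sign makes it
   nonnegative — a monotone relabeling, irrelevant to tree classifiers)

5 × 4 × 7 = 140 features H_{d,θ,a}. Thin ROIs (strips 6–8 px thick) can
admit zero pairs at large vertical displacements; such degenerate
(d,θ) configurations are imputed from the largest smaller d available
for the same θ, with a runtime warning, so the inventory stays fixed.

**Haar wavelet frame (10).** Undecimated (à-trous) separable Haar
decomposition over 3 levels: at level i (0-based) the low-pass taps are
(½, ½) and the high-pass taps (−½, ½) at offsets {0, 2^i}; sub-bands
keep the input's shape. Orientations: j=1 high-pass along rows, j=2
along columns, j=3 both. These taps are power complementary
(|H(ω)|² + |G(ω)|² = 1), so with periodic boundary the per-level energy
telescopes exactly — the conservation test checks this to 1e-10.
Default boundary is mirror (half-sample symmetric); energies are
phase- and sign-invariant to the filter convention. Features:
W_{i,j} = ‖d_j^(i)‖²/|Ω| (norm over Ω only) for i,j ∈ {1..3}, plus
W_0 = ‖f^(3)‖²/|Ω|.

Canonical ordering everywhere: μ, σ, H by (d, θ, a), W_0, W by (i, j) —
152 values, all finite, deterministic.

## Group screening

For each feature, three two-sided tests compare PA vs EH and PA+EH vs
controls: Welch's unequal-variance t, the two-sample Kolmogorov–Smirnov
test, and the Mann–Whitney U test (exact null for samples ≤ 20 without
ties, tie-corrected normal approximation otherwise; KS uses scipy's
auto rule). A feature is *significant* only when all three p-values are
below α = 0.05. Raw p-values are reported, as is a supplementary
Benjamini–Hochberg column that never gates significance. The default
unit of analysis is the image (one feature value per image); per-patient
means are a flag. When both groups are constant the Welch statistic is
undefined and p = 1 is returned, flagged.

## Classification

Two binary tasks: PA vs EH, and hypertensives (PA+EH) vs controls.
Feature subsets: `clinical` (age, sex, office systolic/diastolic BP,
glucose, cholesterol, HDL, LDL, smoking, triglycerides), `clinical_imt`
(plus CCA-IMT, CB-IMT, combined IMT), `texture` (the 152), and `aldo`
(plasma aldosterone, plasma renin activity, ARR) — the aldosterone panel
is undefined for the control task because those assays are not run on
normotensives.

Evaluation is leave-one-*patient*-out: for each patient, a gradient
boosted tree classifier (XGBoost) is trained on all images of all other
patients and predicts a probability for each of the held-out patient's
images; the per-image probabilities are aggregated by arithmetic mean
(positive iff > 0.5, exact ties to the negative class; a hard
majority-vote mode is a flag). Training samples are weighted
1/(images of their patient) so every patient carries unit weight.
Accuracy and the ROC (thresholds over aggregated patient probabilities,
trapezoidal AUC) are computed over patients. Clinical-only subsets have
one row per patient, so aggregation is a no-op.

Model settings (recorded in a config hash embedded in every result):
100 trees, depth 3, learning rate 0.3, `min_child_weight = 0` and
`tree_method = "exact"`. The last two are deliberate: unit-per-patient
sample weights shrink hessian sums far below 1, so the library default
`min_child_weight = 1` would veto nearly every split; and the histogram
split finder pins thresholds to training extremes, which systematically
misclassifies held-out patients whose values fall inside the margin gap,
whereas exact greedy splits at midpoints. At this data scale the exact
method is also fast.

## Synthetic cohort generator

The generator emulates the study design: 33 PA / 52 EH / 33 control
patients (configurable), 4 longitudinal far-wall images per patient
(2 angles × 2 sides), 10 px/mm, ROI strips ≥ 10 mm long and 6–10 px
thick, and 2–3 bright caliper dots per image.

Each image is a smooth layered depth profile — anechoic lumen, the
intima-media strip at the group's mean level, a brighter adventitia
band, deep tissue — multiplied by a correlated multiplicative speckle
field: a log-normal process exp(s·z − s²/2) where z is unit-variance
Gaussian noise smoothed at the group's correlation length and
s = √ln(1+c²) sets SD/mean = c (the speckle contrast). The model is the
simplest stationary process with controllable first- and second-order
statistics; it does not simulate ultrasound physics (no point-spread
function, no depth-dependent attenuation, no Rayleigh amplitude
statistics), so passing tests demonstrate pipeline correctness and
statistical calibration, not clinical performance.

Planted group processes (chosen once, for testability — the real
effect sizes are unknown):

| group | mean level | speckle contrast | correlation length (px) |
|---|---|---|---|
| PA | 146 | 0.36 | 1.12 |
| EH | 145 | 0.35 | 1.20 |
| C  | 120 | 0.25 | 2.00 |

plus per-patient random effects drawn once per patient (mean level
± 3 additive SD; log-normal SD 0.08 on contrast and correlation
length). The random effects matter: without between-patient
variability, per-image feature estimates are so precise that even the
tiny PA/EH delta is fully separable and universally significant, which
is not the structure such studies show. With them, hypertensives vs
controls remain separated by many patient-SDs (strong contrast) while
PA vs EH is weak — few or no single features screen significant, and
only the multivariate classifier does better than chance at realistic
cohort sizes.

Clinical covariates are drawn independently per patient from per-group
marginals (normal with published-style group means/SDs; smoking and sex
as Bernoulli; aldosterone, renin and ARR log-normal parameterized by
median and quartiles, and missing for controls). No correlation
structure between covariates is modeled — only marginals are specified —
and the combined IMT is drawn independently rather than derived, a
documented simplification.

Determinism: every patient consumes an independent child stream of the
cohort seed (`numpy` `SeedSequence.spawn`), so a fixed config yields a
bit-identical cohort (images, polygons, clinical table).

## Validation choices and problem sizes

The validation suite (and `scripts/acceptance.py`) uses scaled cohorts
chosen as the package's own desk-scale defaults:

- **GLCM**: 200 random masks up to 20×20, all 20 (d,θ) configurations,
  against exhaustive pair enumeration (and against scikit-image on
  rectangular ROIs where conventions coincide).
- **Null calibration**: a null cohort (identical texture process in all
  groups, no patient random effects, 1+30 vs 30 patients, 2 images each)
  with 200 patient-label permutation replicates. With identical group
  parameters, random label assignment is distributionally equivalent to
  regenerating group membership, and disabling the patient effects makes
  images iid so image-level tests are correctly calibrated. The slightly
  unequal arm sizes (62 vs 60 images) avoid a lattice artifact of the
  equal-n two-sample KS statistic, whose p-value support is otherwise so
  coarse that no finite-n test is uniform.
- **Signal recovery**: a balanced planted cohort (8 PA + 8 EH vs 16
  controls, 4 images each) — balanced so that chance accuracy is 0.5 for
  the permutation null (20 patient-label permutations).

## Known limitations

- The speckle model is phenomenological; none of the acceptance numbers
  say anything about real carotid ultrasound.
- Clinical covariates lack correlation structure and group-conditional
  dependencies.
- Degenerate-GLCM imputation duplicates information across d for very
  thin ROIs; the affected features are flagged by warnings.
- ROI geometry is a straight strip; real intima-media boundaries
  undulate and the study's multi-angle geometry is not modeled.
- The exact KS p-value is discrete at small n; calibration checks use
  the design above rather than pretending finite-n uniformity where it
  cannot hold.
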