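# Methods

## Problem and pipeline

The package targets binary, pixel-wise tissue classification in
hyperspectral datacubes (H × W × 100 reflectance bands, 500–1000 nm, 5 nm
step) with pathologist-style masks containing four labels: non-malignant,
cancerous, a margin ring around lesions, and unlabeled. Margin and
unlabeled pixels are excluded from both training and metrics everywhere;
cancerous is the positive class throughout. The stages are: spectral
pre-processing → patch extraction → 3D-CNN training under leave-k-out
patient cross-validation → full-image probability maps → threshold
calibration → median-filter post-processing with a grid search for the
optimal (window, threshold).

## Synthetic phantoms

Real records of this kind are not freely distributable, so every stage is
exercised on seeded phantoms. What the generator emulates:

* **Class spectra.** A smooth shared baseline (sum of broad Gaussian bumps
  over wavelength) plus a cancer-specific increment of amplitude
  0.05·`class_contrast`, split between bumps at 600 nm (σ = 35 nm) and
  950 nm (σ = 45 nm). These are exactly the spectral windows where trained
  models of both families concentrate their key wavelengths, so
  importance extraction has ground truth to find.
  `contrast_window_weights` can silence either window.
* **Patient variation.** One multiplicative gain (sd 0.08) and one
  additive offset (sd 0.02) per patient; both per-spectrum scalers are
  invariant to exactly these nuisances, which is why they are the two
  scalers offered.
* **Sensor noise.** i.i.d. Gaussian per pixel and band (sd 0.02),
  clipped at zero reflectance.
* **Geometry.** 1–3 smooth lesion blobs (low-order radial Fourier
  perturbation of a disc) per patient; a margin ring of width 2 px labels
  the lesion boundary; a class-blind random 40% of the remaining pixels
  is left unlabeled (`annotated_fraction` = 0.6 — real annotation
  coverage is unknown, so this is a free parameter).
* **Imbalance.** Total lesion area is solved from
  area = (A − margin)/(imbalance + 1) with a small fixed-point correction
  for the margin ring, so the labeled-pixel ratio converges to the target
  10 : 1 as cohorts grow; at the default 96 × 128 frame a 20-patient
  cohort lands within a few percent.
* **Default frame.** 96 × 128 px, scaled down from the native 480 × 640
  so a complete cross-validation run stays desk-sized; the native frame
  is a config value away.

Independently of the cubes, `simulate_probability_map` emulates a trained
classifier's output: p = logistic(sharpness · (s + ε)) with the signed
latent class s ∈ {−1, +1} and ε ~ N(0, 0.35²), then exactly
round(`flip_rate` · n) random pixels are replaced by 1 − p. That last step
reproduces the salt-and-pepper speckle of raw prediction maps and gives
post-processing something real to remove without any training in the
loop.

What the phantoms do **not** model: light transport, specular reflections,
blood, tissue texture, spatially correlated noise, or annotation errors.
Passing tests therefore demonstrate the correctness and behavior of the
algorithms, not clinical performance.

## Pre-processing conventions

* The first 8 spectral channels are excluded first (they are dominated by
  sensor noise and would corrupt per-spectrum statistics), then scaling is
  applied to the remaining 92 channels.
* Both scalers act per pixel spectrum, not per wavelength across the
  dataset; that is what cancels patient-level gain/offset. The z-score
  uses the population (divide-by-N) standard deviation — a documented
  constant, and the tests use the same convention.
* Patches are 5 × 5 × 92 with the center pixel's label; borders are
  reflect-padded, and neighbor labels are ignored (only the center
  counts).
* The "every third sample" reduction is a seeded shuffle followed by
  taking every third position, i.e. an unbiased ceil(N/3) subsample.

## Architectures and training

The two classifiers map a 5 × 5 × 92 patch to one sigmoid probability.

* **inception3d**: parallel 3D convolutions with kernels 1³/3³/5³ under
  "same" padding, ReLU, channel concatenation, dropout 0.1, flatten,
  one dense sigmoid unit.
* **rs3d**: conv3d 3³ (valid) → conv3d 3³ with stride (1,1,2) —
  downsampling convolutions take the place of pooling — then two 1D
  spectral convolutions (kernel 3, stride 2), dropout, and exactly one
  dense output unit. Spectral sizes run 92 → 90 → 44 → 21 → 10.

The published description pins the layer structure and the total
parameter budgets (393,633 / 27,156) but not per-layer widths. Widths
were therefore calibrated: all exact integer solutions for the structure
above were enumerated and the one with the smallest spread between layer
widths was frozen — inception branches (62, 39, 66) filters for k = 1, 3,
5; RS widths (33, 24, 27, 31). `build_model` verifies the totals at build
time and refuses a miscalibrated plan, reporting the achieved count.
`width_scale` < 1 shrinks every width proportionally (min 1) for CPU-scale
runs; the budget check applies only to the full profile.

Training uses weighted binary cross-entropy on logits (softplus form),
Adam (β₁ = 0.9, β₂ = 0.99, lr 10⁻⁴, ε = 10⁻⁷), batch 100, 40 epochs by
default, no early stopping. Per-sample weights are the class weights
N/N_X, or N/N_{X,Y} per (class, patient) when sample weights are enabled.
The layer stack is plain numpy with hand-written backprop (verified
against central differences to ~10⁻⁹; ReLU-kink crossings excepted), so
training is bit-reproducible given the seed. Glorot-uniform
initialization, inverted dropout.

A practical note reproduced by the phantoms: with per-spectrum
standardization most input values are negative (typically in (−3, 1)), and
trained models can end up with very low optimal thresholds; unit-length
normalization keeps inputs positive and thresholds in a regular range.
This is why the threshold is always calibrated, never assumed to be 0.5.

## Threshold calibration

For each threshold t on a grid (step 10⁻⁴; reported thresholds carry four
decimals), a pixel is predicted cancerous iff p > t — strict everywhere,
which makes t = 0 ⇒ sensitivity 1 and t = 1 ⇒ specificity 1 exact.
Sensitivity and specificity are computed per patient, averaged over
patients with defined values, and the optimal raw threshold is the grid
point minimizing |sens − spec| (the crossing of the two curves), ties
toward the smaller t. Model-level thresholds come from patient-mean
curves; per-patient metrics with empty denominators are flagged undefined
(NaN) and skipped in averages rather than imputed. MCC's zero-denominator
case is defined as 0 (the usual convention). Averages are reported ± the
sample (n−1) standard deviation.

## Post-processing and the parameter search

AP median-filters the probability map then thresholds; AWT thresholds
then median-filters the binary map. Because the indicator `p > t` is
monotone and the odd-window median is an order statistic, the operations
commute: the median of indicators is the indicator of the median. The
package keeps both entry points (AP retains the filtered probability map
for visualization) and property-tests the identity bit-exactly.

The search is the exhaustive grid scan over window sizes (default odd
3…75) and thresholds (default step 10⁻³): a cell's value is
Δsens + Δspec over the calibrated no-filter baseline, counted only when
both deltas are positive — so the selected configuration never trades one
rate below baseline. The argmax breaks ties toward the smaller window,
then the smaller threshold (smaller filters are cheaper and less
destructive). If no cell qualifies, the baseline configuration (m = 1,
baseline threshold) is returned with improvement 0.

Implementation: the search evaluates the AWT route. For each threshold
block the binary indicator stack is turned into summed-area tables, and
each window's median becomes a majority vote (window count · 2 > m²) read
off four table corners. This is exact — identical to median-filter-then-
threshold by the commutativity above, which the oracle tests confirm
against an independently coded scipy double loop — and it makes the
default 37 × 1001 grid run in seconds where repeated large-window float
median filters would take minutes. Borders use reflect padding everywhere
(symmetric at the edge pixel), matching `scipy.ndimage.median_filter`'s
"reflect" mode; metrics are always computed on annotated pixels only,
though maps are filtered whole.

## Cross-validation and reporting

Patients are shuffled once under the master seed and split into
contiguous blocks of k (1 or 4); each block is held out in turn, the
remaining patients' samples are pooled, shuffled and split 90/10 into
train/validation (unstratified — the original protocol does not say, and
this is flagged as a choice), optionally reduced to every third sample,
and the model trains on the rest before predicting full maps for the
held-out patients. Held-out pixels can never influence training by
construction, and the suite audits this. All sub-seeds (cohort, fold
shuffles, init, training, subsampling) derive from the master seed via
named SeedSequence spawn keys, so a study is reproducible end to end.

Reports follow the standard table set: baseline (threshold + metrics
± sd), post-processing (m_opt, t_opt, metrics ± sd with two-tailed
paired-t stars; a zero-variance difference vector is flagged degenerate
rather than given a fabricated p), and improvements (Δsens, Δspec, sum,
in percent points). Key-wavelength importance is channel occlusion: each
spectral channel in turn is replaced (at all 25 spatial positions) by its
sample-set mean and the mean absolute change in predicted probability is
recorded. The original feature-extraction procedure for this quantity is
not public, so occlusion is a documented substitute with the same output
contract; it recovers the phantom's contrast windows but is not expected
to reproduce any particular published wavelength set.

## Numerical and scale choices

* Desk-scale problem sizes in the tests: phantoms 24 × 32 to 96 × 128,
  cohorts of 2–8 patients (one determinism test uses 56), training runs of
  5–10 epochs on a few hundred samples at width_scale 0.08–0.15. The
  full-profile parameter counts and all exactness properties are
  independent of these sizes.
* Training tests assert behavior (convergence on separable phantoms,
  chance-level AUC at zero contrast, determinism), not clinical numbers.
* The probability-map simulator's defaults (sharpness 2.5, latent noise
  0.35, flip rate 0.1) produce baseline sens ≈ spec ≈ 0.9 with visible
  speckle — maps qualitatively like raw CNN output.
* Degenerate inputs fail loudly: constant spectra under standardization,
  even filter windows, single-class training sets, masks without labeled
  pixels, containers with missing datasets.

## Known limitations

* The numpy training loop is CPU-bound and meant for desk-scale studies;
  full-profile training on native-resolution cohorts is out of scope.
* Phantoms are spectrally and spatially idealized (see above); results on
  them bound algorithm correctness, not clinical accuracy.
* Min-max scaling, standardization-then-min-max, outlier exclusion,
  edge-preserving or MRF post-processing, and gradient-based saliency are
  deliberately not implemented.
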