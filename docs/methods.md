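# Methods

## Problem and pipeline

Herbicides are grouped by mode of action (MOA) and, more finely, by
site of action (SOA) — the specific biochemical target in the plant.
The pipeline in this package asks whether the SOA of a treatment can
be read off a plant's reflectance spectrum within days of application.
It processes line-scan hyperspectral cubes of potted grass seedlings
end to end:

1. **Calibration.** Raw digital numbers are converted to reflectance
   against dark-current and white-reference frames,
   `R = (DN_raw − DN_dark) / (DN_white − DN_dark)`.  The white frame is
   a per-spatial-line array, so the division also removes the
   light-source non-uniformity across the scan line.  Out-of-range
   values are kept, not clipped, to avoid biasing the later scatter
   correction.
2. **Segmentation.** Vegetation shows a steep reflectance rise between
   680 and 732 nm (the red edge).  Convolving each pixel's spectrum over
   that window with a centered integer ramp `lin = −m..m` and dividing
   by `lin·lin` yields the least-squares slope per band step; pixels
   with slope strictly above a threshold (default 7) are plant.
3. **Extraction.** The mean spectrum over plant pixels is smoothed with
   a Savitzky–Golay filter (order 1, window 5 — a 5-point moving average
   in the interior, a one-sided polynomial fit at the edges) and cropped
   to the high-SNR 460–975 nm range.
4. **Exploration.** Per-sample NDVI `(R_800 − R_670)/(R_800 + R_670)`
   with Welch two-sample t-tests over all treatment pairs; Random-Forest
   impurity importance (100 trees, seed 42) ranks wavelengths per
   one-vs-rest or per-pair comparison.
5. **Classification.** The K-class problem is split one-vs-one into
   K(K−1)/2 binary problems.  Each binary model is a preprocessing
   chain — `log10(1/R)` → multiplicative scatter correction (MSC)
   against the training-mean reference → mean centering — followed by
   either PLS-DA (1–3 latent variables) or an SVM (linear or RBF,
   C ∈ [1e−3, 100], γ ∈ [1e−6, 1e−1], log-spaced grids).  Model
   selection minimizes RMSEcv, the leave-one-out RMSE between the
   predicted class-1 probability and the {0,1} labels.  Soft voting
   averages, per class, the probabilities of the K−1 models involving
   that class; the argmax wins, ties going to the earlier class in
   canonical order (control first, then the herbicide table order).
6. **Validation.** Leave-one-out cross-validation within a day, and
   day-to-day validation (train on one day, test on another with every
   fitted parameter frozen).  Results are confusion matrices with
   per-class accuracy/error and overall accuracy OA = trace/total,
   error rate = 1 − OA.

## Reflectance scale and the segmentation threshold

The red-edge operator is scale-covariant: multiplying reflectance by g
multiplies every slope by g, so a fixed threshold only has meaning
relative to a numeric convention.  The package names three —
`fraction` (0–1), `percent` (0–100) and `tenthousandths` (0–10000, the
common scaled-reflectance convention) — and defaults segmentation to
`tenthousandths`.  The choice is forced by arithmetic: over a 43-band
window with ramp −21..21 the largest least-squares slope any spectrum
bounded by 100 can achieve is 100·Σ(1..21)/6622 ≈ 3.5 per band step,
so a threshold of 7 can never fire on the percent scale, let alone the
fraction scale.  On the ten-thousandths scale a realistic red edge
(≈ 0.007 reflectance fraction per 1.2 nm band) has slope ≈ 70, an
order of magnitude above the threshold, while a flat background sits
near 0 — which is what makes 7 a sensible operating point.  A unit
test pins the percent-scale impossibility bound.

## Red-edge window construction

Window band indices are the bands nearest 680 and 732 nm, inclusive.
If that window has even length it is trimmed by one band from the
high-wavelength end so that a symmetric, zero-sum integer ramp exists
(the zero sum is what makes the operator insensitive to the spectrum's
mean level).  On a grid where the window holds 41 bands the ramp is
the classic −20..20 vector; on the default 1.2 nm grid it holds 43
bands and the ramp is −21..21.  The slope is normalized per band step,
matching the `lin·x / lin·lin` formula literally, not per nm.

## Preprocessing discipline

All model-side preprocessing is fit-on-train / apply-on-test.  Each
binary pair model owns its own chain, fitted on that pair's training
rows and applied frozen to any spectrum the model scores.  This keeps
every binary problem internally consistent (its MSC reference is the
mean of its own two classes), is leak-free, and makes leave-one-out
caching exact: holding out a sample from outside a pair leaves that
pair's model bit-identical.  The alternative — one chain fitted on the
full training set serving all 36 pairs — was considered and rejected
as it couples every pair model to rows it was never trained on.
log(1/R) uses base 10 (the chemometric absorbance convention; the base
only rescales).  Reflectance at or below 1e−4 is floored with a
warning before the logarithm.  The MSC reference is the training
column mean (not median).

## Leave-one-out protocol

Per class pair: hyperparameters are selected once by RMSEcv over the
pair's rows (preprocessing refit inside every fold); the selected
model's fold predictions — each produced by a model fitted without the
held-out row — are the cross-validated probabilities used for that
pair's rows in soft voting.  Rows outside the pair are scored by the
full-pair model, which never saw them.  No sample is ever scored by a
model fitted on it.  Full nested re-selection per outer fold would
multiply cost by the grid size for no change in leakage status; the
cross-validated-probability protocol is also the natural reading of
soft voting from cross-validated binary classifiers.

SVM probabilities come from a logistic (Platt-style) calibration of
the decision value, fitted on the training rows by regularized
logistic regression — deterministic, unlike calibration via internal
random refolds.  PLS-DA probabilities are the continuous prediction
clipped to [0, 1]; the clip is the simplest monotone map and is
recorded in the model descriptor.

## The synthetic study generator

The study data the pipeline targets are not public, so the generator
emulates them with known ground truth.

* **Leaf optics.** A parametric healthy-vegetation endmember: green
  bump at 550 nm, chlorophyll wells in the blue and red, sigmoidal red
  edge near 705 nm rising to an NIR plateau (~0.55), 970 nm water
  feature.  Severely damaged tissue is a second endmember with a
  collapsed NIR plateau (~0.35), flattened blue-shifted red edge and
  weak pigment absorption.
* **Treatment signatures.** Each herbicide perturbs reflectance with
  1–2 multiplicative Gaussian bands at class-specific centers spread
  over 533–923 nm (the range where herbicide-discriminative bands are
  found), with day-1 amplitudes of 7–22%.  Localizing the class signal
  at known centers is what makes feature-selection recovery checkable.
* **Temporal dynamics.** Signatures evolve as
  `severity_growth^(day−1)`; the paraquat- and glyphosate-like signals
  fade (growth 0.45 and 0.60) while photosynthesis-inhibitor signals
  strengthen.  Independently, damage accumulates as
  `w = 1 − exp(−rate·severity·(day−1))` and mixes the damaged endmember
  into the spectrum — all treated classes converge toward the same
  damaged spectrum at class-specific rates (contact herbicides 0.25/day,
  systemic inhibitors 0.08–0.15/day).  Both mechanisms leave 1 DAT
  untouched; together they are what makes a day-1 model degrade on
  day-2 spectra (fading signals slide classes back toward the control
  cluster; convergence moves them off the training manifold), the
  behaviour reported for real day-to-day validation.  An earlier
  design iteration using only a shared additive chlorosis band moved
  every class parallel to the pair decision boundaries and produced no
  transfer degradation at all; it was replaced by the
  fading-plus-convergence model above.
* **Per-plant and per-measurement variation.** Each plant draws
  endmember parameter jitter and a severity factor once; each
  measurement draws a multiplicative gain (σ = 4%), an additive offset
  (σ = 0.004) — the scatter MSC is there to remove — and white sensor
  noise (σ = 0.004 reflectance).
* **Design counts.** Defaults mirror the study design: 9 classes, 16
  plants per herbicide and 32 controls per round, 2 rounds (320
  plants), days 1–7, and 5 treated plants rendered necrotic
  (near-zero flat reflectance) from 2 DAT and flagged as outliers.
* **Scenes.** `render_scene` forward-models a raw cube
  `dark + gain(λ)·illum(column)·reflectance + noise` with a
  halogen-like lamp spectrum, cosine illumination non-uniformity
  across the line, a white frame imaging a unit-reflectance target
  (near the top of a 12-bit DN range) and a constant dark frame, so
  calibrating the noiseless scene recovers the endmember exactly.
  Default scenes are 96×128 pixels × 542 bands (380–1030 nm at
  1.2 nm); the spatial size is a memory-conscious stand-in for the
  instrument's ~1000-pixel lines and is a config field.
* **Determinism.** All randomness flows from one root seed through
  `numpy.random.SeedSequence` spawning (one child per plant for
  biology, one stream for measurements, one for outlier choice), so
  every dataset is bit-reproducible.

What the generator does **not** emulate: radiative transfer
(no PROSPECT-style leaf model), 3-D plant architecture, mixed
plant/background pixels at silhouette edges, real herbicide
biochemistry beyond band-localized effects, and instrument artifacts
such as spectral smile or keystone.  Passing tests therefore show that
the pipeline's algorithms are correct and recover known structure
under realistic noise — not that real herbicide SOAs are separable at
these accuracies.

## Experiment sizes and numerical choices

* Leave-one-out and day-to-day experiments on the default study use
  day-1/day-2 data (315 rows per day after outlier exclusion) and the
  coarse SVM grid (3 C × 3 γ points plus 3 linear-kernel points over
  the same ranges); the full 6×6+6 grid is the library default for
  single fits.  The coarse grid keeps a full LOO experiment in the
  low minutes on one core.
* The permuted-label null experiment uses a balanced design (16
  controls per round instead of 32): the chance level 1/K is only the
  correct null reference when classes are exchangeable and equally
  sized — with a doubled control group the permutation null shifts to
  the prior-weighted rate Σp_c².
* RMSEcv ties are broken toward the simpler model: fewer latent
  variables; linear kernel, then smaller C, then smaller γ (the
  candidate enumeration order, with a 1e−12 improvement threshold).
* Degenerate inputs: MSC raises on spectra with |slope| < 1e−12
  against the reference; calibration raises naming the first pixel and
  band where white − dark ≤ 0; empty plant masks raise ("no plant
  pixels") so callers can drop samples the imaging failed to capture,
  and classes with fewer than 2 samples are dropped from experiments
  with a warning.
* PLS latent-variable counts are additionally capped at n−2 so every
  leave-one-out fold remains well-posed at tiny n.

## Known limitations

* Binary SVM probabilities use regularized logistic calibration on
  training decision values; with few samples the probabilities are
  compressed toward 0.5 (the ranking, which is what soft voting uses,
  is unaffected).
* The ENVI reader supports the interleaves, integer/float dtypes and
  header fields this pipeline writes and reads (BIL/BSQ/BIP,
  little-endian, wavelength lists), not the full format zoo.
* Confusion-report rendering is deliberately basic (annotated heatmap
  plus accuracy/error columns); it is a reporting surface, not a
  plotting library.
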