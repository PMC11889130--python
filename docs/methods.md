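# Methods

This note documents the models and procedures `leafspec` implements, the
assumptions behind them, the defaults and why they were chosen, and the
numerical decisions that matter when reproducing results.

## The estimation problem

The target is leaf chlorophyll content measured as a SPAD meter reading
(unitless, typically 30–60 for healthy leaves), paired with leaf-level
reflectance spectra on a 350–2500 nm grid at 1 nm (2151 bands).
Reflectance is unitless in [0, 1]. The pipeline assumes one spectrum and
one SPAD value per sample (field replicates averaged upstream), samples
aligned by id, and treats the spectra→SPAD mapping as a supervised
regression problem evaluated on a single 70/30 hold-out split.

## Scatter correction

Per-sample affine distortion — multiplicative gain from surface
scattering and particle-size effects, additive baseline offset and
drift — is the dominant nuisance in leaf reflectance. Both corrections
assume the distortion is affine per spectrum across wavelengths:

* **SNV**: each spectrum is centered by its own mean and divided by its
  own sample standard deviation (m−1 denominator). SNV output is exactly
  invariant to a·x + b with a > 0; the result is unitless with row mean
  0 and row s.d. 1 (the container enforces this to 1e−9 on SNV-tagged
  data). A spectrum whose s.d. is at rounding level (≤ 1e−12 relative to
  its mean) is rejected by name — a flat spectrum is corrupt data, not
  signal.
* **MSC**: the "ideal spectrum" is the column mean of the *training*
  spectra; each spectrum is regressed on it by ordinary least squares,
  x_i ≈ k_i·x̄ + b_i, and corrected as (x_i − b_i)/k_i. Held-out samples
  are corrected against the stored training mean with freshly fitted
  (k_i, b_i), so no test information enters the reference. Slopes with
  |k| ≤ 1e−8 are a hard error rather than being clipped: inverting a
  near-zero slope would amplify noise without bound.

On data whose only corruption is affine, MSC applied twice (with a refit
in between) changes nothing, and SNV of corrupted data equals SNV of
clean data — both properties are asserted by the test suite.

## Band screening and feature extraction

Screening computes the Pearson correlation between each band and SPAD
and keeps bands with **|r| ≥ 0.6**, the conventional strong-correlation
cut. The magnitude is thresholded, not the signed value, because
chlorophyll *lowers* green-peak reflectance: the most diagnostic visible
bands are negatively correlated. Zero-variance bands get r = 0 with a
warning. If no band passes the screen the mask is empty and downstream
extractors fail loudly; the grid runner records such cells as failed
rather than silently relaxing the cut. (Under realistic scatter this is
the expected behaviour for *uncorrected* spectra, and is precisely the
argument for preprocessing.)

Three extractors condense the screened bands; all fit on training data
only and carry enough state to transform held-out spectra:

* **Split-count importance** (gradient-boosted trees, 200 estimators,
  depth 4, learning rate 0.1): a band's importance is the number of
  times it is used as a split node anywhere in the ensemble; the top 10
  bands are kept, ties broken toward the lower wavelength. Two
  safeguards make split counts meaningful on spectra, where neighbouring
  bands are near-duplicates. First, columns are fitted in a seeded
  random permutation: the booster breaks equal-gain ties by column
  order, and without the permutation every tied split in a correlated
  block lands on the block's first column, inflating the lowest
  wavelength of the mask regardless of signal. Second, a minimum split
  loss (`min_split_loss` = 1.0, in squared SPAD units) prunes splits
  that barely reduce the training loss; late in boosting the residual is
  mostly noise, and without the floor those noise splits dominate the
  counts. With both safeguards the selector recovers planted sensitive
  bands essentially perfectly; without them it ranks the mask's edge
  bands highest.
* **RFE** (random-forest base, 100 trees, `sqrt` feature sampling,
  impurity importance): one band — the least important survivor — is
  eliminated per refit until 10 remain, and the elimination order is
  recorded. One-at-a-time elimination is the most literal reading of
  recursive elimination; `sqrt` feature sampling keeps the n-refits cost
  tractable on masks of several hundred bands.
* **PCA**: screened bands are mean-centered with training statistics
  (no variance scaling — bands share units) and the smallest number of
  leading components whose explained-variance ratios sum to **≥ 0.99**
  is kept (≥ at the boundary, with a 1e−12 numerical guard).

## Regression models

**GA-BP** is the fully implemented model: a one-hidden-layer perceptron
with 7 sigmoid hidden units and a linear output, trained on min-max
scaled features and target. The chromosome is the flattened
(W1, b1, W2, b2), length 7d + 15 for d inputs, initialized uniform on
[−1, 1]. The GA runs 50 generations on a population of 40: fitness
1/(training MSE + 1e−12), roulette selection with the single best
chromosome carried unchanged (so the best-fitness trace is
non-decreasing), arithmetic crossover at rate 0.7, per-gene Gaussian
mutation (rate 0.05, s.d. 0.1), genes clipped to [−3, 3]. Training MSE
is the fitness because the sample sizes involved (tens of training
rows) do not support an inner validation split. The best chromosome is
then refined by full-batch gradient descent for up to 1000 iterations,
stopping early at MSE ≤ 1e−6.

The descent uses an accepted-step rule: a trial step that would increase
the loss is rejected and the step size halved; accepted steps grow it by
5% (initial 0.01, capped at 1). This makes refinement monotone from the
GA's best chromosome — asserted in the tests — and removes the usual
sensitivity of plain gradient descent to the step-size choice. With the
GA disabled (`max_generations=0`) the model degenerates to plain BP from
a random start; averaged over seeds its held-out R² is no better than
the full GA-BP's, which is the testable core of the genetic
initialization's claimed benefit.

The forest (1000 trees, minimum leaf 3) and kernel (RBF, gamma 0.001,
cost 1000, ε-tube 0.1) regressors wrap scikit-learn's
`RandomForestRegressor` and `SVR`; the ε-tube width is a package default
since only gamma and cost are conventionally reported. All three models
are deterministic given data, configuration and seed (single-threaded
fits).

## Evaluation harness

* **Split**: seeded uniform shuffle, first ⌊0.7n⌋ samples to train
  (91 → 63/28). Floor rounding is a package choice.
* **Scaling**: min–max to [0, 1] per feature and for the target, fitted
  on training data only; held-out values outside the training range pass
  through un-clipped; constant features map to 0.5 with a warning.
  Min–max was chosen over z-scoring as the conventional normalization
  for magnitude differences ahead of sigmoid networks.
* **Metrics**: computed in SPAD units after inverting the target
  scaling. R² is the standard coefficient of determination,
  1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)² with ȳ the mean of the *measured* values (some
  presentations of this formula ambiguously center the predicted series;
  the standard measured-centered form is used here). NRMSE is RMSE
  divided by the mean measured value, so ≈0.03 means a typical error of
  3% of mean SPAD.
* **Grid**: all 27 preprocessing × selector × model cells share one
  split for comparability. Per-stage seeds are derived deterministically
  from a master seed; preprocessing and selection are computed once per
  (preprocessing, selector) pair and reused across the three models,
  which is exactly equivalent to running cells independently with the
  same derived seeds. A failed cell is recorded with its error message;
  reports are byte-stable under a fixed master seed.

Feature selection (screen + extractor) is fitted on the training split
only. Fitting it on all data before splitting would leak test
information into the band choice; the leakage-free order is asserted by
a refit-and-compare test.

## The synthetic generator

`generate_dataset` emulates a single-campaign leaf survey: 91 samples by
default, SPAD from a truncated normal (mean 45, s.d. 5, bounds 30–60),
matching surveys where chlorophyll concentrates in the 40–50 range. The
clean spectrum R(λ; SPAD) is a closed-form Gaussian/logistic curve:
visible base 0.08; logistic red edge centered at 720 nm (width 15 nm)
rising to a 0.45 NIR plateau, its midpoint shifting +0.2 nm per SPAD
unit above 45; a green peak at 551 nm with amplitude 0.18·exp(−SPAD/40);
a red valley at 670 nm deepening with SPAD (0.05 + 0.002·SPAD, floored
at 0.02 reflectance); SPAD-independent water valleys at 1445 and
1924 nm; everything clipped to [0.01, 0.6].

A closed form was chosen over a radiative-transfer leaf model
deliberately: the SPAD-derivative of the curve is known exactly, so
"which bands truly carry chlorophyll signal" is computable ground truth
(`SimTruth.sensitive_bands`: bands with |dR/dSPAD| ≥ 1e−3 at mean SPAD,
a threshold set so that a one-s.d. SPAD step moves reflectance by at
least the default noise s.d.). One consequence of the stated
parameterization worth knowing: at mean SPAD the red-valley depth
exceeds the reflectance available above the 0.02 floor, so the valley
bottom (~640–690 nm) saturates and carries no derivative — the sensitive
set is the green peak (525–577 nm) plus the valley's upper shoulder and
red edge (690–736 nm). Bands near the saturation boundary respond to
SPAD over only part of its range and are deliberately not labelled
sensitive.

Corruption is per-sample affine plus white noise:
gain·R + offset + tilt·(λ−350) + N(0, noise_sd), clipped at 0, with gain
log-normal (log-s.d. `scatter_sd` = 0.15), offset N(0, 0.02), tilt
N(0, 1e−5 per nm), noise s.d. 0.005. Affine corruption is used precisely
because SNV/MSC are defined to remove it, which turns "preprocessing
helps" into a provable property rather than a hope. The magnitudes are
package choices, not estimates of any instrument.

What the generator does *not* emulate — and what passing tests therefore
do not show about field data: water-content and carotenoid covariates,
wavelength-dependent (non-affine) scattering, instrument-specific noise
structure, within-plot replicate variation, or any canopy-scale effects.
Results on the synthetic data validate the machinery, not field
accuracy.

## Problem sizes

The test suite and the acceptance script run at the survey scale the
package targets: 91-sample grids (63/28 split), 200-sample datasets for
planted-band recovery and the GA-BP function task, 5 replicate grids for
the scatter-correction comparison. These sizes keep every statistical
check sharp while the full suite completes in a few minutes on one core.

## Known limitations

* The 0.6 screening threshold is absolute; on weakly corrupted data it
  can admit hundreds of bands (slowing one-at-a-time RFE), and on
  heavily corrupted raw spectra it admits none, failing those grid cells
  by design.
* GA-BP fitness is training MSE; with very small training sets the GA
  can favour chromosomes that overfit before gradient refinement.
* The split-count selector's `min_split_loss` is expressed in squared
  target units (SPAD²); targets on a very different scale would need it
  adjusted.
* Model persistence for forest/kernel models uses joblib blobs, which
  are not portable across major scikit-learn versions; GA-BP models use
  a stable JSON format.
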