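# Methods

This note documents the models, conventions and design choices behind
`leafspec-n`, in the spirit of a statistical software appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and splits

A dataset is an `n × p` reflectance matrix on a shared, strictly increasing
wavelength axis (nm) plus per-sample metadata: LNC (g/kg dry mass), the
three-level nitrogen category, measurement environment (lab/field),
cultivar, and a split tag. The working range is 430–2500 nm; on a 1-nm grid
that is 2071 variables. Spectra arriving on a coarser or irregular grid can
be linearly interpolated onto the integer 1-nm grid at read time; the
reduction-percentage arithmetic (e.g. 40/2071 → 98.07 %) is only meaningful
on that grid.

**Stratified split.** Within each nitrogen level of size *n* the
calibration/validation/prediction counts are

```
cal = floor(f_cal · n),   val = round(f_val · n),   pre = n − cal − val
```

with a seeded random permutation deciding membership. With the default
60/20/20 fractions this yields 138/46/46 for a 230-sample stratum,
360/120/121 for 601, and 341/114/114 for 569. A pure floor rule was
considered and rejected: it gives 341/113/115 on the 569-sample stratum,
which does not match the canonical composition the split is meant to
reproduce. How the original field study assigned individual leaves to sets
(random, by plot, by date) is unknown; only the per-class counts are
reproduced here.

**Level cutpoints.** LNC bins to low/medium/high at t₁ = 25.01 and
t₂ = 35.0 g/kg. These sit inside the empty gaps between the observed class
ranges (14.99–25.00, 25.02–34.96, 35.02–52.46 g/kg), so every in-range
value bins to its class; the exact position within each gap is arbitrary.

## Preprocessing (FD + SNV)

The first derivative is a Savitzky–Golay filter (default window 7 points,
polynomial order 2, derivative order 1, with polynomial edge fitting so the
output length equals the input length). The derivative estimator itself is
a free choice; a plain central-difference mode is provided as a
cross-check. SNV then centres each spectrum and divides by its **sample**
standard deviation (n−1 denominator — a fixed convention; any consistent
choice only rescales all spectra by one constant). The order is fixed: FD
first, then SNV. The chain is exactly invariant to per-spectrum affine
scatter `a·x + b` (a > 0) in the noiseless limit, because the derivative
annihilates `b` and SNV cancels `a`; this is verified as a test. Constant
spectra are rejected (SNV undefined) rather than silently producing NaN.

## Wavelength selectors

**Random frog.** An iterative subset search scored by selection frequency.
State: a variable subset of size Q (initial size Q₀ = 2, random under
seed). Per iteration a candidate size Q* ~ round(N(Q, θ·Q)) is drawn
(θ = 0.3, clipped to [1, p]). Growing: a 3× surplus of random variables is
drawn, the union is fitted with the inner PLS model, and the Q* most
important variables (largest |coefficient|) are kept — importance-refined
addition, following the algorithm the method descends from; pure random
addition mixes too slowly to be useful at practical iteration counts.
Shrinking: the Q* most important variables of the current subset are kept.
The candidate replaces the current subset if its five-fold cross-validated
error (RMSE for regression, misclassification rate for classification) is
lower, otherwise with probability η·(err_current/err_candidate), η = 0.1.
The score of a variable is the fraction of iterations whose accepted subset
contains it; the top-k (default 40) are selected, ties broken by ascending
wavelength. Default 10 000 iterations; 2000 are used in the acceptance
checks, which suffices for stable recovery on the synthetic conditions.

**WPLS.** A PLS model (PLSR for regression; PLS-DA for classification) is
fitted, and wavelengths at the local extrema — crests and troughs — of the
coefficient curve β(λ) are ranked by |β|; the k largest are returned sorted
by wavelength. An extremum is a point strictly greater (or smaller) than
both neighbours; equal-valued plateaus contribute their leftmost point;
endpoints are excluded. For PLS-DA the p × c coefficient matrix is reduced
to one signed curve by taking, at each wavelength, the class coefficient of
largest magnitude. If k exceeds the number of extrema, all extrema are
returned and the result is flagged.

**Saliency maps.** For a trained CNN, the gradient of the model output —
the true-class logit for classification (logits, not softmax, so the
gradient is not attenuated by confidence), the scalar output for
regression — is taken with respect to the input spectrum, per sample, in
inference mode. Each sample marks its `per_sample_top_k` (default 40)
largest |gradient| wavelengths; the score of a wavelength is the fraction
of samples marking it, and the `final_top_k` (default 40) highest-frequency
wavelengths are selected. The recovery checks use the *classification*
CNN trained for 30 epochs: saliency structure stabilises long before the
loss converges, and across seeds the classification net's saliency spreads
over the informative bands more reliably than the regression net's at
comparable cost (the regression variant remains available).

## Classical models

PLS uses mean-centring only (spectra are already SNV-normalised row-wise;
no per-column autoscaling). PLS-DA regresses a one-hot indicator matrix and
classifies by argmax of the predicted indicators; its latent-variable count
is chosen by five-fold stratified CV **accuracy**, PLSR's by five-fold CV
**RMSE** (both seeded, both capped by the rank limit min(n−1, p)). With the
full number of components PLS reproduces the ordinary least-squares fit on
full-rank data — kept as an oracle-equivalence test. The SVMs use an RBF
kernel with C and γ on integer powers of two from 2⁻⁸ to 2⁸ (a 17 × 17 =
289-cell grid; the grid *step* is a package choice, the range is given),
scored by five-fold CV; ties resolve to the smallest C, then the smallest
γ, and the winner is refit on the whole calibration split.

## CNN architectures and training

*Classification (CNNC):* two blocks of [conv(16 filters, kernel 3, stride
1, same padding) → ReLU → max-pool 2/2 → batch-norm], then dense(64) →
batch-norm → dropout → dense(n_classes). *Regression (CNNR):* two blocks of
[batch-norm → conv(32, 3, 1) → ReLU], a final batch-norm, then dense(64) →
dense(16) → dense(1). Pooling geometry (2/2), "same" conv padding, the
dropout rate (0.5) and the BN→conv→ReLU ordering of the regression blocks
are declared defaults where the source description is silent or ambiguous.
Parameter counts are exposed and tested against closed-form layer-by-layer
arithmetic.

Training: batch size 64; learning rate 0.05 divided by ten every 200 epochs
(0.05 / 0.005 / 0.0005 at epochs 0/200/400); softmax cross-entropy with
plain SGD for classification, L1 loss with Adam (β = 0.9/0.999) for
regression. "Stop when the loss is stable" is implemented as patience:
training ends when the monitored (validation, else training) loss has not
improved by more than 10⁻⁴ for 100 consecutive epochs, or at `max_epochs`
(default 600, covering three learning-rate stages — the final stages do the
fine fitting, so short-budget runs should shorten the decay period too if
they need converged models). Weights are initialised fan-in uniform from
the protocol seed; with a fixed seed and data the loss history is
bit-identical on a single thread. A NaN loss aborts with the epoch index.

The networks run on a small numpy engine written for this package
(channel-last conv1d as shifted GEMMs, explicit backward passes, float32).
Input gradients — required by the saliency selector — are exact
backpropagation to the input in inference mode (batch-norm running
statistics, dropout off) and are verified against numerical differentiation.

## Synthetic generator

The generator is phenomenological Gaussian band algebra, not a
radiative-transfer model (no PROSPECT-style physics, no canopy geometry).
A leaf spectrum is

```
r(λ) = a · [ base(λ) + A · (LNC − 30) · Σ_b s_b · G(λ; c_b, σ) ] + b + tilt(λ) + ε(λ)
```

* `base(λ)`: a fixed composite of Gaussian bumps/dips and sigmoid edges
  with local maxima near 550/1650/1820/2225 nm, minima near
  670/1432/1950 nm, a red edge near 715 nm and a high NIR plateau over
  775–1300 nm, values in (0, 1). A small auxiliary dip near 1730 nm (C–H
  region) is topologically required to separate the 1650 and 1820 nm
  maxima.
* Nitrogen-sensitive bands `c_b` (σ = 8 nm): 554 (−), 1179 (+), 1490 (−),
  1673 (−), 1746 (−), 2046 (−) nm — nitrogen/protein-related absorption
  features plus a positive NIR-plateau carrier — signed so that higher-LNC
  leaves are darker in 520–610 nm and the 1400–1900 / 2000–2500 nm regions
  and brighter on the NIR plateau. Amplitude A = 0.0012 reflectance per
  g/kg about the 30 g/kg reference.
* Scatter: per-sample gain `a ~ 1 + N(0, 0.05)` (clipped positive) and
  offset `b ~ N(0, 0.01)`; removed exactly by FD+SNV in the noiseless
  limit.
* Noise: i.i.d. `ε ~ N(0, noise_sd)` per wavelength. The default
  `noise_sd = 0.012` is a **tuning constant**, calibrated once so that the
  default pipeline's prediction-set R² falls in the 0.7–0.9 regime; it is
  not a measured instrument property. Field samples get the noise sd
  multiplied by 2 and a smooth random linear tilt; the `low_noise()` and
  `noiseless()` variants define the clean regimes used by recovery and
  invariance checks.
* Composition: 230 low / 601 medium / 569 high leaves (truncated normals
  with means 21.73/30.09/40.19 and sds 2.37/2.84/3.60 g/kg on the class
  ranges), 648 of 1400 lab-measured, two cultivar labels.

**What passing tests do and do not show.** The generator reproduces the
*statistical structure* the pipeline assumes — localized nitrogen
information, multiplicative scatter, environment heterogeneity, the class
composition — so green tests demonstrate that the algorithms are
implemented correctly and recover planted structure. Real leaf spectra
have broad, overlapping absorption features, wavelength-correlated noise,
and within-class covariance this band model does not emulate; absolute
accuracies on synthetic data say nothing about accuracies on real cotton
leaves.

## Numerical conventions and degenerate inputs

R² is 1 − SS_res/SS_tot about the evaluated split's own mean (not squared
Pearson correlation); RMSE is in g/kg. Accuracy is percent correct;
confusion matrices are rows-true in low/medium/high order with
row-normalised proportions alongside. Constant true values make R²
undefined and raise. Ties in every selector resolve to ascending
wavelength. All stochastic components (splits, CV folds, subset search,
weight initialisation, batching, dropout) draw from explicit numpy
Generators seeded from user-supplied integers.

## Problem sizes in the shipped checks

The acceptance checks run the full 1400 × 2071 study conditions for PLSR
and all three selectors (random frog at 2000 iterations; the saliency CNN
trained 30 epochs). The CNN regression check trains on the 40 WPLS-selected
wavelengths — mirroring the selected-wavelength modelling arm — and the
separable-classification check uses a 10-nm grid; both choices keep the
demonstrations at desk scale while exercising the full training protocol.

## Known limitations

* The CNN engine is CPU-only and single-threaded by design; wall-clock cost
  on the full 2071-wavelength grid is minutes per hundred epochs, so
  full-spectra CNN calibration at the default 600-epoch budget is a
  long-running job.
* The random-frog acceptance probability and subset-size dynamics follow
  one published variant; other variants differ in detail and would yield
  different (similarly ranked) frequencies.
* Within-class spectral covariance of real leaves is unknowable from
  summary statistics; the generator's independence assumptions are a
  simplification flagged above.
* `wpls_select` on classification reduces multi-class coefficients to one
  curve; alternatives (per-class extrema, norm curves) are defensible and
  not implemented.
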