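# Methods

This note documents the models, algorithms and numerical choices behind
`serscv`, in the order data flows through the package.

## Synthetic data model

The generator emulates a balanced two-class label-free SERS study of serum
with technical replication. A spectrum is

```
y(ν) = s · Σ_b A_b · α_{m(b)} · c_b(class) · L(ν; ν_b, Γ_b)  +  B(ν)  +  ε(ν)
```

- `L` is a Lorentzian with center `ν_b` and FWHM `Γ_b` (default 12 cm⁻¹, a
  typical solution-phase Raman width).
- `A_b` are the library's relative band intensities. The default library
  has 15 bands over 400–1800 cm⁻¹: five uric-acid bands (594, 638, 812,
  888, 1132 cm⁻¹) that rise in the positive class, the dominant
  hypoxanthine band (724 cm⁻¹), four ergothioneine bands (480, 1220, 1442,
  1582 cm⁻¹) and two glutathione bands (664, 912 cm⁻¹) that fall, and
  three class-neutral background bands.
- `α_m` is a per-sample, per-metabolite lognormal abundance multiplier
  (mean 1, CV = `biological_cv`, default 0.1), shared by all replicates of
  a sample — the biological variation.
- `c_b(class)` is the class effect: `1 + δ·α_m` for "up" bands in the
  positive class, its reciprocal for "down" bands, 1 otherwise
  (`δ = effect_size`, default 0.5). `δ = 0` makes the label independent of
  the spectra by construction — the null model.
- `s` is a per-replicate lognormal scale (CV = `intensity_scale_cv`,
  default 0.15) emulating spot-to-spot SERS enhancement variation.
- `B` is a positive degree-4 polynomial with uniform random coefficients
  scaled by `baseline_scale` (default 500 on a band amplitude scale of
  1000) — the fluorescence background.
- `ε` is i.i.d. Gaussian detector noise (`noise_sd`, default 5).

The raw wavenumber axis is a jittered pixel grid (spacing 1.9 ± 0.3 cm⁻¹,
shared by all spectra of a dataset, with one pixel prepended below
400 cm⁻¹ so interpolation never extrapolates). Defaults mirror the
emulated study design: 72 samples per class, 3 replicates, with batch /
day / operator labels rotated identically in both classes so none of them
confounds the class.

What the generator does **not** emulate: peak-position shifts between
classes, substrate/batch-dependent band distortions, heteroscedastic or
correlated noise, cosmic-ray spikes, and any real covariance structure
between metabolites. Passing tests therefore demonstrate the correctness
and calibration of the *analysis machinery* under the stated model, not
clinical performance on real serum spectra.

## Preprocessing

Order: interpolate → average replicates → baseline → crop → normalize.

- **Interpolation** to the uniform 2 cm⁻¹ grid on 400–1800 cm⁻¹ (701
  points) uses local quadratic regression with tricube weights (a loess
  smoother evaluated at the grid). The neighborhood is
  `max(3, round(span·n))` input points; the default span 0.008 (~5 points)
  was chosen so that 12 cm⁻¹-wide Lorentzian bands pass through the
  smoother essentially unchanged (<0.01% L2 distortion); wider spans
  measurably clip band tops. The smoother is precomputed as a linear
  operator per axis, so a whole intensity matrix interpolates in one
  matmul.
- **Replicate averaging** is the arithmetic mean per sample and must
  follow interpolation, since raw axes need not match the grid.
- **Baseline** is the iterative modified-polynomial (modpoly) algorithm:
  least-squares polynomial fit (degree 4), clip the working curve to the
  fit, iterate. Convergence is declared when the fitted curve's L2 change
  drops below `tol = 1e-4` *of the spectrum norm* (measuring the change
  against the fit's own norm fails on baseline-free input, where the fit
  is ~0); `max_iter = 100`, with non-convergence flagged, not raised.
  Polynomials are fitted in the numerically stable scaled domain
  (`numpy.polynomial.Polynomial.fit`).
- **Crop** to 430–1730 cm⁻¹ (651 points) removes baseline edge artifacts.
- **Vector normalization** (unit L2) runs last, so the final
  representation has exactly unit norm on the analysis range. The
  alternative order (normalize before crop) would leave norms slightly
  below 1.

A known property of min-clipping baselines on band-dense Lorentzian
spectra: each extra pass subtracts the polynomial lower envelope of the
current residual (overlapping band tails plus edge behaviour), so the
chain is only approximately idempotent — a second pass moves unit-norm
spectra by ~3% L2 here, independent of noise level. This drift is bounded
and does not accumulate meaningfully beyond the first re-application.

## The RDCV engine

- **Stratified folds**: within each class, members are shuffled and dealt
  round-robin; the dealing start rotates between classes so remainder
  members spread across folds (per-class fold sizes differ by ≤ 1).
- **Inner loop** (k = 7, on the outer-training partition only): one PCA
  per inner fold (centering, no scaling, loadings = leading right singular
  vectors with a deterministic sign convention), then one LDA per
  candidate size a = 1..a_max on the leading a score columns, scored by
  held-out misclassification fraction. `mean_err` and `se_err` (sd/√k,
  ddof = 1) feed the **one-standard-error rule**: the smallest a whose
  mean error is within one SE (taken at the argmin) of the minimum; ties
  at the minimum break toward fewer components. An inner fold draw that
  leaves a single-class training part is re-dealt (≤ 10 attempts) — this
  cannot occur with balanced 72/72 data but can on small synthetic sets.
- **Outer loop** (k = 3): the optimized PCA(a\*)-LDA is refit on the full
  outer-training partition and predicts the untouched fold. Test spectra
  are centered with the *training* mean and projected on *training*
  loadings; nothing flows back. The LD score is the positive-class log
  posterior odds under the two-Gaussian equal-covariance model, so the
  decision threshold is score 0 (posterior 0.5) and the discriminant is
  intrinsically oriented toward the positive class.
- **Repetitions**: one master `SeedSequence` spawns independent per-
  repetition substreams, making every repetition independently randomized
  yet exactly reproducible; `a_max = 7` by default, exposed in the config.
- LDA priors are the training class frequencies (equal here by design).
  A singular pooled covariance raises with the advice to retain fewer
  components.

## Figures of merit and intervals

Per repetition, the outer-fold confusion matrices are summed; sensitivity,
specificity, accuracy, PPV and NPV are computed from the summed matrix
(zero-denominator metrics are NaN, never 0), giving `n_rep` values per
metric. The reported interval for count-based metrics is the exact
Clopper–Pearson interval from beta quantiles at
`x = round(mean · n_denom)`, where `n_denom` is the metric's natural
denominator (72 positives for sensitivity, 144 samples for accuracy, and
the mean predicted-positive count for PPV, rounded).

One ROC per repetition is built from the per-sample positive-class
posteriors pooled across the repetition's outer folds; ties receive half
credit, so the AUC equals the normalized Mann–Whitney statistic. The
average ROC is the mean TPR on a fixed 201-point FPR grid.

The AUC interval is the influence-curve estimator for cross-validated AUC:
per fold, with empirical score CDFs F₀ (negatives) and F₁ (positives),
fold AUC θ_v and positive fraction p_v,

```
IC(y, s) = y/p_v · (F₀(s) − θ_v) + (1−y)/(1−p_v) · (1 − F₁(s) − θ_v)
```

variance = mean over folds of mean(IC²), divided by the total number of
scored observations; Wald interval around the mean fold AUC, truncated to
[0, 1]. All `n_rep × k_outer` folds enter as the fold structure, which is
why this interval is much narrower than the binomial ones. Folds with a
single class are excluded with a warning.

## Permutation test

Class labels are permuted at the sample level (replicates keep one label;
the label multiset is preserved), the full pipeline downstream of
preprocessing is re-run per permutation, and the one-sided add-one
p-value `(1 + #{null ≥ observed}) / (b + 1)` is reported per metric — it
can never be 0 and its floor is `1/(b+1)`. Default b = 100 with the inner
RDCV reduced to 10 repetitions for tractability; `n_rep_null=None` gives
the full-fidelity mode.

## Interpretation

PCA loadings are sign-ambiguous, so all cross-model aggregates first align
each model's components against one reference PCA fitted on the full
preprocessed dataset (sign = sign of the inner product; zero → +1). The
reference feeds only visualization/aggregation, never prediction, so the
figures of merit are unaffected. Median LD scores per sample use the
repetitions in which the sample was tested; median PC scores use only
models in whose *test* fold the sample fell, and only the components each
model retained; loading summaries report pointwise medians and 25/75
percentiles. Mann–Whitney U (ties half credit) is exact by enumeration for
groups of ≤ 10 untied observations and uses the tie/continuity-corrected
normal approximation otherwise. Band assignment is nearest-neighbor within
a tolerance (default ±6 cm⁻¹, i.e. half a band width).

## Problem sizes used in tests and the acceptance script

The test suite runs the engine at 12–50 samples per class with 2–100
repetitions; the acceptance script runs the full default study (72/class,
3 replicates, 100 repetitions, 300 models), a 50/class null calibration at
20 repetitions, and a 20/class permutation run with b = 19 and 2
repetitions per permutation. Null-calibration checks average several
independent datasets because the mean cross-validated accuracy of a single
100-sample null dataset fluctuates with sd ≈ 0.036 (and sits slightly
below 0.5, a known small-sample property of cross-validated null
accuracy).

## Known limitations

- The loess span, modpoly convergence tolerance and sign-alignment scheme
  are this package's own defaults; the workflow the package re-implements
  leaves them unspecified.
- The cvAUC fold grouping pools all repetitions' folds; grouping per
  repetition and averaging would give slightly wider intervals.
- Binary classification only; no PLS-DA/SVM alternatives; no spike
  removal or scatter correction in preprocessing.
- The synthetic generator's realism limits are listed above; absolute
  figures of merit on synthetic data should not be read as clinical
  performance.
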