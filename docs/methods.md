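# Methods

This note records the models, conventions and numerical choices behind
`cspdecode`, in the order the pipeline applies them.

## Preprocessing

A 6th-order Butterworth band-pass at 8–30 Hz isolates the sensorimotor mu
and beta rhythms; epochs are cut half-open in samples,
`[round(t_start·fs), round(t_start·fs) + K)` with
`K = round((t_end − t_start)·fs)`, relative to each cue (0 s).  Filtering
defaults to zero-phase (forward–backward `sosfiltfilt`), which squares the
magnitude response and removes group delay, so band power stays aligned
with the fixed window; a causal single-pass mode is exposed for
online-style processing, since either convention is defensible.  Band
edges must lie strictly below Nyquist, and filtering short recordings
(≤ 3×(order+1) samples) is refused.

## CSP

Class covariances follow the trace-normalized convention: each trial
contributes D Dᵀ / trace(D Dᵀ) and the class mean has unit trace.  The
generalized eigenproblem is solved in symmetric-definite form
(`scipy.linalg.eigh(C1, C2)`), which is numerically symmetric and returns
C2-orthonormal eigenvectors, rather than forming C̄₂⁻¹C̄₁.  A ridge of
`1e-10 · trace(C2)/C` is loaded on C̄₂ first.  Eigenvector signs are fixed
(largest-magnitude component positive) for reproducibility; all features
downstream are even in the filter sign, so this is cosmetic.  `m` defaults
to 3 filters per end.

`compute_class_covariances(..., trace_normalize=False)` averages raw
D Dᵀ/K instead.  This matters for diagnostics: trace normalization rescales
every generalized eigenvalue by the ratio of pre-normalization traces, so a
planted source-variance ratio r between classes appears as a top
eigenvalue near r only on the *raw* covariances (with unit-trace
covariances and a single dominant in-band source the top eigenvalue tends
to 1 instead).  The parameter-recovery checks therefore use the raw route;
the decoding pipeline itself always uses the trace-normalized default,
where only the eigenvector ordering matters.

Log-variance features use the population variance (divide by K); the
normalized ratio f_p = log(var_p / Σ var_i) is insensitive to the divisor
and satisfies Σ exp(f_p) = 1 exactly.

## Sub-band extractors

All three operate on the 2m projected channels.

*Wavelet family.*  db4 throughout; decomposition depth 3 at fs ≤ 128 Hz
and 4 above, so the dyadic edges fall usefully around 8–30 Hz for 100 vs
250/256 Hz data (256 Hz plans identically to 250 Hz).  DWT terminal bands
are A_L, D_L … D_1; packet nodes are reordered from tree (Paley) order to
natural frequency order before intervals are assigned — skipping that
reordering silently mislabels bands, which the localization tests would
catch.  Sub-band intervals are the ideal dyadic edges; real db4 filters
leak across them, so tests assert energy *localization* (e.g. ≥ 70% for an
in-band tone), not exact containment.  The default retention rule keeps a
sub-band if its interval intersects [8, 30] Hz.  This rule makes the
retained interval set invariant to one extra decomposition level (the new
level only splits bands entirely outside the range), which is why depths 3
and 4 at 100 Hz, and 4 and 5 at 250 Hz, select identical frequency
content.  A stricter fully-within rule and explicit index lists exist; note
the within rule is legitimately empty for the 250 Hz DWT tiling and raises
a planning error.  Boundary handling defaults to periodization, under
which the orthogonal transforms conserve energy exactly (the Parseval
tests); symmetric extension is available but breaks exact conservation.
Per sub-band the features are coefficient energy Σ D² and the sample
standard deviation (N−1 divisor), laid out channel-major, energy before
std.

*Filter bank.*  `make_filter_bank(8, 30, 4, 2)` gives the ten bands
8–12, 10–14, …, 26–30 Hz (the count formula is
floor((high−low−width)/step)+1; the 4–40 Hz variant gives 17).  Each band
is a 6th-order Butterworth applied zero-phase; the feature is the natural
log of the population variance, laid out band-major.

## Sparse selection

Both selectors use the same proximal-gradient engine: step 1/γ with
γ = ‖XᵀX‖₂ from power iteration (deterministic start, tolerance 1e-10),
zero initialization, stop when the relative iterate change falls below
1e-6 or after 1000 iterations (non-convergence is reported, not raised).
The engine iterates on the precomputed Gram matrix, which is algebraically
identical to the Xᵀ(Xw − y) form but O(P²) per step.  Features are
column-standardized on the training set (zero-variance columns pass
through unscaled) so one λ grid is comparable across extractors; the
transform is stored and applied frozen at test time.

The log penalty is treated as the separable sum λ Σ log(1 + |wᵢ|/a) with
a = 0.001 — the form consistent with an element-wise shrinkage operator —
and the non-separable variant λ log(1 + ‖w‖₁/a) is additionally evaluated
on the final iterate for reporting.  Two shrinkage modes ship:

- `closed_form` (default): the closed form
  sign(v)/2·(|v| − a + √((a−|v|)² + 4·max(a|v| − λ/γ, 0))) applied
  literally.  When the clamp is active (a|v| ≤ λ/γ) the square root
  collapses and the output is exactly 0 for |v| ≤ a and |v| − a above —
  i.e. with small a this mode zeroes only tiny inputs and debiases the
  rest, which is precisely why LOG keeps larger supports with less-shrunk
  weights than LASSO.
- `exact`: compares the formula's stationary point against the
  boundary 0 and returns the true global minimizer of
  (λ/γ)·log(1+|x|/a) + ½(x−v)².  The modes agree wherever the clamp is
  inactive; the exact mode backs the oracle tests and satisfies monotone
  majorization descent (the objective trace never increases).

For a ≥ 1e4 the exact operator reduces to soft thresholding at (λ/γ)/a,
linking LOG continuously to LASSO.

λ selection: stratified 10-fold CV (seeded fold assignment) over
2^[−5 : 0.2 : 5].  Each candidate's score is the held-out accuracy of an
FLDA fitted on the nonzero-weight features (empty support scores 0); a
squared-error scoring flag exists.  Ties break toward the larger λ, i.e.
the sparser model.  Both the scoring rule and the stratification are
package conventions — reasonable defaults, not uniquely determined by the
method definition.

## Classifier and threshold ensemble

FLDA uses pooled within-class *scatter* S_w, direction
(S_w + ridge·I)⁻¹(μ₊ − μ₋) with ridge 1e-8·trace(S_w)/P′, midpoint bias,
and boundary points assigned +1.  The threshold grid {0, 0.1, …, 0.8}
compares against raw |wᵢ| by default (an optional mode normalizes by
max|w|, making the grid scale-free); subsets are nested and one model is
fitted per non-empty subset.  Evaluation reports the maximum member
accuracy (ties to the smallest threshold).  That max rule deliberately
consults test labels when picking the member — it is kept as the
reference behaviour — and `evaluate_ensemble_cv` is the label-blind
alternative that picks τ by inner CV on training data and reports a single
model's test accuracy.  Pipelines leak nothing else: spatial filters,
standardization, λ, weights and all FLDA models are fitted on training
epochs only (the test suite asserts that flipping every test label changes
no fitted state).

## Synthetic generator

Each trial is `mixing @ sources + noise`: sources are white Gaussian noise
band-passed to their band (4th-order Butterworth, zero-phase, generated
with 2 s padding and center-cropped past transients) and rescaled to an
exact per-trial standard deviation; the mu source's variance is multiplied
by `variance_ratio` (default 4) for class +1.  Defaults: 250 Hz, 2 s
trials (K = 500), 8 channels, 4 sources (mu 8–12, beta 18–26, two
broadband 8–30 backgrounds), unit source variances, sensor noise sd 0.1,
100 trials per class.  Exact per-trial rescaling makes the expected channel
covariance exactly `mixing·diag(source vars)·mixingᵀ + noise²·I`, which
the tests check to 5% at 500 trials.

Because per-trial variances are exact rather than merely in expectation,
the generator is *less* variable than real EEG; it also omits artifacts
(blinks, line noise), nonstationarity, and volume-conduction correlations
beyond linear mixing.  Passing tests therefore demonstrate correctness of
the machinery and recoverability under the stated model, not field
performance on real recordings.

`ground_truth_alignment` scores the top filter in source space: the cosine
of `mixingᵀw` against the ERD source axis.  With more channels than
sources, components of w outside the mixing column space carry no signal
and are not identifiable from variance (at low noise the channel-space
comparison to the unmixing row becomes arbitrary), so the source-space
cosine is the meaningful recovery measure.

Train/test experiments draw both sets from one mixing matrix
(`generate_train_test`) — a session pair from the same simulated subject.
Filters learned on one random head do not transfer to another, so
independent mixings would measure nothing but that truism.

## Problem sizes and determinism

The recovery experiments use 200 trials (eigenvalue recovery, tolerance
10%), 10 seeds at 50 trials/class/set for the high-SNR pipeline claim
(mean accuracy ≥ 0.90) and 20 seeds for the null claim (mean within
[0.35, 0.65]; the max rule inflates the null mean slightly above 0.5,
which the band anticipates).  All randomness flows through explicit seeds:
generator configs carry one, CV fold assignment and the ensemble's inner
CV take one, and `scripts/acceptance.py` derives everything from its
`--seed` argument.

## Known limitations

- Binary classification only; no one-vs-rest multi-class extension.
- No artifact rejection, re-referencing or channel selection.
- The closed-form shrinkage mode applies a formula that is not the exact
  proximal map in the clamped regime; consequences are documented above
  and both modes are first-class.
- EDF/GDF adapters are optional thin wrappers (require mne) and do no
  montage or event semantics beyond a user-supplied label map.
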