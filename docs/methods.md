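# Methods notes

This note records the models, the synthetic world they are exercised in,
and the numerical and design choices a maintainer would want to know.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Onset detection and VRT

A recording's left channel is converted from integer PCM to floats by
dividing by full scale `2^(bits-1)` (8-bit WAV is re-centred first;
float WAV is clipped to [−1, 1]). This is deliberate: per-file *peak*
normalization would force every file's maximum to 1.0 and make every
recording exceed any threshold below 1, leaving nothing to classify as
non-speech. Classification is therefore invariant to bit depth but
sensitive, as it should be, to recording level.

The onset rule is a single strict comparison on absolute amplitude,
`|x_i| > threshold` (default 0.3 of full scale); ties at exactly the
threshold are not onsets. VRT is `onset_index / sample_rate`, i.e. the
latency from recording start (t = 0) to the first supra-threshold sample.
An optional `min_duration_samples` guard additionally requires a run of
samples at or above the threshold starting at the onset, to reject
single-sample clicks; it defaults to 0 (the plain first-exceedance rule).
No prefiltering is applied by default. MFCCs (Hann window, triangular mel
filterbank, orthonormal DCT-II) exist purely as an audit representation
for manual validation; they play no role in classification.

## Validation arithmetic

Speech is the positive class throughout. PPV, NPV and accuracy are exact
rational arithmetic over the 2×2 counts; a metric with a zero denominator
is *undefined*, never 0. Percentages are rounded half-up to one decimal
only at presentation; stored values are never rounded. One consequence
worth recording: the confusion counts TP=35 / FP=0 / FN=14 / TN=136 give
accuracy 171/185 = 92.43%, which renders as 92.4% — a reported figure of
92.5% for these counts cannot be reproduced by this arithmetic, and this
package treats the recomputed value as authoritative.

The validation subsample is a simple random draw of `round(f·N)` rows
without replacement (f = 0.083 by default). The exclusion cascade is a
declarative, reorderable stage list applied sequentially (non-speech →
invalid strategy → missing sleepiness); reordering changes per-stage
removal counts but never the surviving set, since the flags are row
properties.

## The synthetic world

The generator encodes the studied design as its defaults; none of these
values is tuned to test outcomes.

- 16 participants, ages uniform in [56, 74] (minimum 55+ inclusion,
  observed range ~57–74), sex 68.8% female, education 12–20 years peaked
  at 16, MMSE ≥ 24; BZRA use Bernoulli(0.5).
- Weekly sessions on days 1, 8, 15, 22 (an optional fifth week), with a
  single day-level EMA record inherited by all of the day's attempts.
  35 attempts per session by default (≈2,240 total).
- Sleepiness levels drawn from (23.7, 39.5, 17.1, 19.8)% — normalized by
  their sum, since the printed percentages total 100.1% — via a
  latent-normal copula. The copula reduces to exact i.i.d. categorical
  sampling when the per-participant intercept SD is 0, which is the
  default because the downstream models deliberately ignore nesting.
- Non-speech rate 6.1%, invalid-strategy rate 14%, missing-sleepiness
  rate 12.8%, all Bernoulli per attempt/day. A fixture preset instead
  plants *exact* disjoint counts (136/295/286 among 2,230) by seeded
  permutation, so the cascade lands on exactly 1,513 rows.
- The sleepiness→VRT link is lognormal:
  `VRT = exp(b + s·(level−1) + ε)`, `ε ~ N(0, σ²)`. Lognormality
  guarantees positivity and the right skew implied by median 1.68 s <
  mean 2.19 s. The slope s = 0.10 log-seconds per level is a fixed,
  modest positive coupling (the direction the analysis is designed to
  detect; its magnitude is not reported anywhere and was chosen once);
  b = 0.385956 and σ = 0.720370 were then solved numerically so the
  *marginal* mixture under the default level probabilities has median
  1.68 s and mean 2.19 s (implied SD ≈ 1.82 s).
- Caffeine is a Poisson count (mean 1.5 drinks) — the source never states
  units, so a count of caffeinated drinks was chosen; the cognition item
  is ordinal 1–4 mirroring mood, whose response options are likewise
  unstated. One EMA record per test day is assumed.
- Audio: background uniform noise at ±0.05 full scale; a decaying 220 Hz
  burst at 0.8 full scale from the planted onset, whose first sample is
  forced to exactly 0.8 so detection recovers the planted latency within
  one sample. Stereo by default with speech on the left channel. No
  attempt at intelligible speech is made.

What a green test on this world does **not** establish: robustness to
reverberation, variable microphone gain, breath/click artifacts near the
threshold, within-day EMA dynamics, or participant-level confounding
beyond what the optional random intercepts emulate.

A known emergent behavior of the stated world: because attempts inherit
one EMA record per day, only participants × weeks (= 64) independent
sleepiness draws feed ~2,240 rows. Participant-level covariates (age,
education) can therefore absorb chance day-level sleepiness variation and
screen strongly — with the weak default coupling, VRT's node-purity
importance can fall below the absolute screening cutoff. This is faithful
pseudo-replication, not a bug; the controlled property tests plant
stronger couplings where the contract is about signal recovery.

## Association models

Sleepiness enters both models as numeric 1–4 with Gaussian error; an
ordinal-link variant is deliberately out of scope, since only the
Gaussian reading makes the two models' AIC values comparable. Both AICs
are computed by one shared formula (`n·log(2π·RSS/n) + n + 2(edf+1)`,
counting the variance as one parameter), so a spline model shrunk to
linearity reproduces the OLS AIC within rounding.

- **Screening.** Node-purity importance is the total impurity decrease a
  feature's splits achieve, averaged over trees (one-hot columns summed
  into their parent feature). The absolute scale is
  implementation-dependent, so the default cutoffs (50 for screening, 20
  per fold) are meaningful only on this implementation's scale and a
  quantile cutoff is provided. They also scale with n — small cohorts
  need smaller cutoffs. Race is manually excluded by default (category
  imbalance), kept separate from the cutoff rule in the reported
  partition.
- **OLS.** Reference coding: female, mood level 1, BZRA non-use. 95% CIs
  are estimate ± 1.96·SE. Rank deficiency is detected before fitting and
  reported with the offending columns.
- **RESET.** Delegated to statsmodels' `linear_reset` with powers {2, 3}
  of the fitted values (the conventional default) as an F-test. The
  cascade proceeds to the additive model only when RESET rejects at
  α = 0.05.
- **Additive model.** Cubic B-spline bases (default size 10 per smooth,
  capped automatically at the number of unique covariate values) with
  per-smooth penalty weights chosen by a deterministic coordinate-wise
  GCV grid search (log-spaced 10⁻³…10⁵, two sweeps) — chosen over the
  library's Nelder-Mead search for determinism and a ~25× speedup with
  five smooths. Smooth p-values are exact nested-OLS F-tests on the
  unpenalized basis block: penalized drop-term tests proved
  anti-conservative under the null (penalty selection adapts to noise),
  while the unpenalized test is exactly calibrated for Gaussian errors at
  a modest power cost. Effective df are reported from the penalized fit.
- **Comparison.** ΔAIC plus an approximate F-test treating the additive
  model's total effective df as its parameter count — labeled
  approximate because penalized edf are not integer dimensions.

## Prediction

Folds partition patients; each patient sits in exactly one test fold.
Stratification assigns patients grouped by modal sleepiness (ties toward
the lower level), shuffled within group, dealt to the currently smallest
fold. Class balancing acts on training rows only: classes under the floor
(180) are skipped entirely, classes over the cap (500) are downsampled
without replacement. Test rows are never touched — rows of skipped
classes remain in the test set and count against recall, the conservative
reading of "skipped".

Per-fold feature selection removes a feature only when its importance is
below the cutoff in *every* fold's training data. Metrics are computed
from the multiclass confusion matrix; the averaging scheme is an explicit
required choice (macro default, weighted, or binary-collapse at a
configurable positive threshold) because four-class precision/recall/F1
have no single canonical reading — indeed a fold with precision 0.76 and
recall 1.00 has harmonic-mean F1 ≈ 0.864, so a published F1 of 0.90 for
such a fold cannot come from the plain binary formula, and no single mode
reproduces it. Bootstrap CIs are percentile intervals over 1,000
resamples of (label, prediction) pairs. Fold aggregation is the
arithmetic mean and n−1 SD across folds, rounded to two decimals half-up
at presentation.

## Orchestration

One global seed derives all stage seeds through
`SeedSequence(seed).generate_state(...) mod 2³¹`, so stages re-run in
isolation reproducibly and the whole pipeline is byte-deterministic. All
thresholds (0.3, 50, 20, 180, 500, k = 4, B = 1,000, α = 0.05) live in
`RunConfig` defaults only. The package is a library: the pipeline is
driven from Python (`run_all`, the per-stage functions, and the
examples/ scripts); a YAML config loader covers declarative use.

## Known limitations

- The threshold rule is amplitude-only; loud non-speech (coughs, bumps)
  would be misclassified in real audio, which is exactly why the manual
  validation workflow exists.
- Smooth p-values sacrifice power for calibration (see above); effect
  *shapes* should be read from the partial curves, which are reported at
  observed covariate values, not an extrapolation grid.
- The approximate model-comparison F-test and the Gaussian treatment of
  an ordinal outcome are pragmatic choices, adequate for AIC-ordering
  conclusions, not for fine-grained inference on the boundary.
- Balancing seeds derive from the rule's seed plus the fold id; two folds
  with identical class layouts still downsample differently.
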