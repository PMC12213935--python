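# sleepvoice

Voice-onset latency as a passive marker of sleepiness during remote
cognitive testing.

When middle-aged and older adults complete self-administered verbal memory
tests on a phone, every answer is an audio recording — and the delay
before they start speaking carries signal. `sleepvoice` implements the
full analysis chain for that idea:

1. **Verbal reaction time (VRT) extraction.** Each recording's left
   channel is normalized to full scale ([−1, 1]); a recording is *speech*
   iff any sample's absolute amplitude strictly exceeds a threshold
   (default 0.3), and VRT is the time from recording start to that first
   supra-threshold sample. MFCC audit features support manual review.
2. **Classifier validation.** A random subsample is checked against human
   labels; a 2×2 confusion matrix (speech = positive class) yields
   PPV = TP/(TP+FP), NPV = TN/(TN+FN) and accuracy, and discovered false
   negatives are relabeled in a correction pass. An ordered flow ledger
   accounts for every exclusion (non-speech → invalid strategy → missing
   sleepiness).
3. **Association modeling.** With momentary self-reported sleepiness
   (ordinal 1–4, modeled as numeric Gaussian) as outcome: random-forest
   node-purity screening, OLS with a forest-plot-ready term table, the
   RESET test for unmodeled nonlinearity, and — when RESET rejects — a
   penalized B-spline additive model (smooths for VRT, age, education,
   caffeine, test difficulty; linear terms for sex, BZRA use, mood,
   cognition), compared to OLS by a shared-scale AIC and an approximate
   F-test.
4. **Prediction.** Patient-level stratified k-fold cross-validation
   (folds partition participants, never rows), floor/cap class balancing
   of training data (<180 skipped, >500 downsampled), per-fold feature
   selection with an all-folds removal rule, random-forest classification,
   and bootstrap percentile 95% CIs for accuracy/precision/recall/F1.
5. **Synthetic cohort generator.** No raw study data exist publicly, so a
   seeded generator emulates the design: ~16 participants aged ≥55,
   weekly test sessions on days 1/8/15/22, ~2,230 recorded attempts,
   sleepiness level shares 23.7/39.5/17.1/19.8%, ~6.1% non-speech, 14%
   invalid-strategy, 12.8% missing sleepiness, and a lognormal
   sleepiness→VRT link calibrated so the marginal VRT has median 1.68 s
   and mean 2.19 s. WAV audio with planted onsets is synthesized so the
   detector can be tested end to end.

## Worked example

```sh
python examples/04_assemble_describe.py
```

```
Attempt flow
============
  2230 -> non-speech sounds removed (-136) -> 2094
  2094 -> invalid-strategy attempts removed (-295) -> 1799
  1799 -> missing sleepiness removed (-286) -> 1513
analysis-ready: 1513

analysis rows: 1513  excluded rows: 717
cohort: 16 participants, 75.0% female
VRT median 1.68 s (IQR 1.02-2.83), mean 2.25 +/- 1.91 s
sex-difference p-values: {'t_test_p': 0.17, 'mann_whitney_p': 0.14, 'variance_test_p': 0.84}
```

The fixture preset plants exactly 136 non-speech, 295 invalid-strategy and
286 missing-sleepiness attempts among 2,230; the sequential exclusion
cascade therefore ends at 1,513 analysis-ready rows. The VRT summary is
the generator's calibrated lognormal marginal; with no planted sex effect,
all three sex-difference tests (Welch t, Mann-Whitney U, variance F) are
non-significant.

The association cascade on a strongly coupled cohort
(`examples/05_association_cascade.py`) prints:

```
linear model: R^2 0.397, AIC 1249.95
RESET p-value: 0.000406
VRT smooth: edf 1.68, p 4.29e-32
AIC linear 1249.95 vs additive 1130.01 (delta 119.94); additive model preferred; approx. ANOVA p=7.1e-24
```

The lognormal VRT link is nonlinear on the 1–4 sleepiness scale, so RESET
rejects the linear specification and the additive model wins the AIC
comparison — the cascade's designed branch.

Other examples: `01_synthesize_cohort.py` (generator structure),
`02_extract_vrt.py` (WAV round trip and onset detection),
`03_validate_speech.py` (validation arithmetic),
`06_predict_sleepiness.py` (stratified CV prediction),
`07_full_pipeline.py` (one-call `run_all` with persisted artifacts and a
markdown report).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Re-runs the complete pipeline from scratch on the default synthetic
cohort — generation, audio synthesis, onset extraction, validation,
exclusion cascade, the OLS→RESET→GAM cascade, and the cross-validated
prediction — printing the flow ledger, VRT summary, model comparison and
fold metrics, and writing the results JSON to `--out`. All randomness
derives from `--seed`.

## Layout

```
src/sleepvoice/
  syncohort.py        synthetic cohorts, EMA, sessions, WAV synthesis
  voicesignal.py      WAV I/O, onset detection, VRT, MFCC audit features
  speechvalidation.py subsampling, confusion metrics, corrections, flow ledger
  assembly.py         dataset assembly, descriptives, sex-difference tests
  inference.py        screening, OLS, RESET, additive model, comparison
  prediction.py       patient-level folds, balancing, CV forest, bootstrap CIs
  orchestration.py    RunConfig, seed derivation, run_all, artifacts
docs/methods.md       model and design notes
examples/             one narrative script per capability
```
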