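# Methods

## Problem and pipeline

Cuffless wearable devices estimate blood pressure (BP) indirectly from
ECG/PPG-derived features such as the radial pulse arrival time (rPAT). In
24-h ambulatory settings the point estimates carry large, clinically
consequential errors, so the package produces *intervals with a guaranteed
marginal coverage* instead of bare point estimates:

1. **Quantile boosting** (`conformalbp.qboost`): gradient-boosted
   regression trees trained under pinball loss at levels
   γ ∈ {0.05, 0.50, 0.95} map the seven features to a point estimate (the
   median model) and a raw 90% quantile band per record.
2. **Split conformal calibration** (`conformalbp.conformal`): on held-out
   calibration subjects each record is scored by
   `s = max(lower − y, y − upper)`; the threshold `q̂` is the
   ⌈(n+1)(1−α)⌉-th order statistic of the n calibration scores, and the
   calibrated interval is `[lower − q̂, upper + q̂]`. Over exchangeable
   draws the coverage is guaranteed to lie in `[1−α, 1−α + 1/(n+1)]`.
3. **Evaluation** (`conformalbp.metrics`): MAD/ME/SD error metrics with
   IEEE 1708 / AAMI verdicts, Bland–Altman agreement, coverage rate, and
   the ICER trade-off ratio
   `(q̂₀.₀₅ − q̂₀.₁₀)/(Coverage₀.₀₅ − Coverage₀.₁₀)` in mmHg per
   percentage point of coverage.

Real large-scale ambulatory datasets with synchronized wearable features
and reference ABPM readings are access-restricted, so the package ships a
synthetic cohort generator that reproduces the protocol's schema, schedule
and population moments, making every stage testable end to end.

## Synthetic cohort generative model

One 24-h session per subject: readings every 30 min in the daytime window
[08:00, 20:00) (half-open; 24 slots) and every 60 min overnight (12
slots). Reference SBP decomposes as

    sbp(s, t) = μ + b_s + d_s(t) + σ(t)·z_{s,t}

- `b_s ~ N(0, f·σ_pop²)` — between-subject baseline,
  `f = between_subject_fraction` (default 0.6; the within/between split of
  ambulatory cohorts is not standardised, so it is an exposed knob).
- `d_s(t)` — deterministic diurnal profile: cosine with amplitude 5 mmHg
  peaking at 14:00 (plus a per-subject phase jitter, SD 0.5 h) minus a
  10 mmHg nocturnal dip during nighttime slots, centred over the schedule
  so the pooled mean is exactly μ.
- `z` — standardised AR(1) (ρ = 0.6) with unit marginal variance;
  `σ(t)` is solved from the variance budget
  `f·σ_pop² + Var(d) + E[σ(t)²] = σ_pop²` and inflated ×1.3 at night, so
  the pooled SD equals the configured population SD (123.48 ± 20.04 /
  75.80 ± 14.47 mmHg SBP/DBP defaults) *by construction* and nighttime
  per-subject CV exceeds daytime CV, as observed in ambulatory data. An
  infeasible budget (diurnal variance exceeding the within-subject share)
  raises immediately.

DBP shares the same standardised components through a fixed correlation
(0.7) with SBP, scaled to its own moments, with baseline profiles redrawn
in the rare case DBP ≥ SBP.

Features are linear-Gaussian in the SBP deviation: rPAT −1 ms/mmHg around
250 ms (noise SD 10), dP/dt +0.008 (a.u./s)/mmHg, heart rate +0.1 bpm/mmHg
on a subject baseline (SD 8 bpm between subjects, 5 bpm within), HRV −0.2
ms/mmHg; arm angle and PPG quality carry no BP signal, and beat length is
`60000/HR` plus jitter (conditionally independent of BP given HR). Records
are flagged invalid with probability `p_missing` (default 0.05).

What the generator does *not* emulate: real waveform morphology, motion
artifacts, activity- or drug-driven BP excursions, demographic covariates,
and non-Gaussian error tails. Passing tests therefore demonstrate the
statistical machinery (quantile recovery, conformal guarantee, metric
arithmetic), not device-level accuracy on real patients.

### Analytic quantile oracle

Because BP and the linked features are jointly Gaussian for configs
without deterministic diurnal structure (`CohortConfig.homoscedastic()`),
the conditional law of BP given the features is Gaussian with closed-form
posterior mean and a feature-independent posterior SD (≈ 8.0 mmHg under
the default links). `true_conditional_quantile` returns
`posterior_mean + z_γ · posterior_sd`; for general configs the same
formula is a moment-matched approximation (the pooled SD still equals the
population SD by construction). Quantile-recovery tests use the
homoscedastic preset, where the oracle is exact.

## Preprocessing rules

Daytime hours are downsampled to their first valid reading (the second is
used when the first is invalid; an hour with no valid reading is left
blank), then every subject is placed on the cohort-wide hourly grid and
blank or invalid slots are filled with a copy of the most recent preceding
record (timestamp moved to the slot); a leading blank is back-filled from
the first available record — forward fill alone leaves it undefined. Hour
buckets align to on-the-hour clock times. The result: every subject
contributes the same 12 daytime + 12 nighttime hourly records, balancing
the phases in every split. Splits are by subject (60% train / 24%
calibration / 16% test; train gets ⌊0.6n⌋, calibration ⌊0.6·remainder⌋,
test the rest), redrawn independently for each of the five repeats.

## Boosting details

- Initial prediction: empirical γ-quantile of the training targets.
- Per round: a least-squares regression tree (scikit-learn
  `DecisionTreeRegressor`, depth ≤ 8, ≥ 4 samples/leaf by default) is fit
  to the pinball negative gradient (+γ below the prediction, −(1−γ)
  above, 0 at the tie — a subgradient choice with no effect in
  expectation); each terminal leaf's value is then replaced by the exact
  per-leaf line-search optimum, the γ-quantile of the current residuals in
  the leaf; the tree enters the ensemble scaled by the learning rate.
  The per-leaf exact step is the standard realisation of the
  one-dimensional line search for pinball loss and strictly dominates a
  single global step size.
- Defaults lr = 0.01, 800 trees, depth 8, min leaf 4 (the grid-search
  optimum for this model family on ambulatory data); `grid_search`
  re-derives them by exhaustive validation-MAD search with ties broken
  toward smaller ensembles.
- At γ = 0.5 the pinball loss equals exactly half the MAE (same gradient
  direction, same leaf medians), so the median model is the MAE model;
  the factor of two is a bookkeeping convention, not a modelling choice.
- Trees are scale-invariant, so features enter unscaled; SBP and DBP get
  independent ensemble triples.
- Quantile crossing in the raw triple is repaired by sorting the three
  values (monotone, preserves the point estimate's rank); repairs are
  counted and logged.
- `splitter="best"` trees are deterministic; the config seed feeds each
  tree's `random_state` so any tie-breaking is reproducible, and
  predictions are invariant to training-row order.

## Conformal details

- α is the error rate; the raw band trained at γ = {0.05, 0.95} is reused
  for both α = 0.10 and α = 0.05 by default (the conformal threshold
  absorbs the mismatch); matched bands at γ = {α/2, 1−α/2} can be trained
  by passing the corresponding gammas to `fit_triple`.
- The rank ⌈(n+1)(1−α)⌉ is computed with a 1e-9 guard before the ceiling:
  in binary floating point `20·0.9 = 18.000000000000004`, and a naive
  ceiling would inflate the order statistic by one.
- Rank > n yields an explicit infinite sentinel (unbounded interval)
  rather than clamping to the max score — preserving the finite-sample
  guarantee and surfacing undersized calibration sets.
- `q̂` may be negative (raw band over-covers → interval shrinks);
  intervals are closed at both endpoints and never clipped at the point
  estimate.
- Calibration is stratified by day/night phase in the full pipeline
  (nocturnal thresholds are systematically larger); the pooled mode is
  the one with an exact exchangeability guarantee and is what the
  coverage experiments use.

## Problem sizes and numerical choices

The repeated-split coverage experiment in the test-suite and in
`scripts/acceptance.py` uses a 180-subject (tests) / 270-subject
(acceptance script; 44 test subjects × 24 records ≥ 1000 test rows)
cohort, 20 independent splits, and a reduced boosting budget (200 trees,
depth 4, lr 0.05): split-conformal coverage is guaranteed whatever the
regressor's accuracy, so the scaled-down ensembles change interval width,
not the property under test. Quantile-recovery checks use the default
800-tree configuration on ~5000 homoscedastic records, where the fitted
q0.95 − q0.50 spread lands within 10% of the analytic 1.6449σ oracle.
All randomness flows from one integer seed through
`numpy.random.SeedSequence` (stage order: cohort, splits, boosting),
keeping every derived seed below 2³¹.

## Known limitations

- Marginal coverage only: intervals have fixed width per (target, phase,
  α) cell; conditional (per-subject) conformal prediction is out of
  scope.
- The exchangeability guarantee is exact for pooled calibration; the
  phase-stratified thresholds inherit it only within each stratum.
- The generator's linear-Gaussian links make the estimation problem
  easier than real wearable data; error magnitudes on synthetic cohorts
  are not comparable to device studies.
- With per-subject AR(1) correlation, coverage across splits has larger
  Monte-Carlo variance than iid sampling would suggest; the experiments
  average ≥ 20 splits and report Monte-Carlo standard errors.
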