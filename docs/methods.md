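# Methods

## Data model

A diary is a time-ordered series of prompt-level reports for one subject:
`(timestamp_min, response)`, where the timestamp is minutes since the
subject's study start (real-valued; the analysis only uses inter-prompt gaps,
so wall-clock datetimes and timezones are deliberately out of scope) and the
response is one token from the emotion alphabet, `no_emotion`, or `missing`.
Missed prompts are explicit rows rather than absent ones so that missingness
is visible to the pair-extraction rule and testable.  The format enforces one
response per prompt; a multi-select protocol would need a different format
and is not supported.

The default alphabet has k = 10 categories (happy, anxious, angry, shame,
disgust, sad, guilt, interest, envy_jealousy, unspecific); `unspecific`
("an emotion I cannot name") is treated identically to the named emotions
everywhere, including in ARF denominators.  Alphabets are configurable; all
combinatorics are expressed in k.

## Sequence extraction

A pair is formed from prompts i, i+1 iff neither response is `missing` and
the gap is at most `max_gap` minutes.  **Default `max_gap` = 20 min**: the
schedule is 15 ± 1 min, so any gap above 20 min implies at least one skipped
prompt or the overnight sleep window, after which two reports are no longer
"successive" at the sampling cadence.  The value is configurable; results are
insensitive to it within (16, 30) because simulated gaps are either ~15 min
or ≥ 30 min.

Pairs where both responses are `no_emotion` are not sequences; they are
tallied separately (`n_none_none`) so that the conservation identity
`Σ counts + n_none_none = n_pairs` can be asserted on every diary.

## Adjusted relative frequency

`ARF(E1→E2) = f_S(E1→E2) / (f_S(E1)·f_S(E2) + 1)` per subject, where
`f_S(E)` counts all non-missing prompts reporting E over the whole diary
(missing prompts contribute to no marginal: a marginal should count observed
reports only).  For activation and down-regulation sequences one endpoint is
the no-emotion state; the default treats its marginal like any other —
`f_S(no_emotion)` — so the formula is total and uniform over all 120 keys,
normalising every sequence by the subject's opportunity to produce it.  An
alternative mode (`denominator="emotion_only"`) divides those keys by
`f_S(emotion endpoint) + 1` instead, for sensitivity analyses.  Bounds follow
directly: `0 ≤ ARF ≤ f_S(E1→E2)`, with equality at zero iff the count is
zero.

## Group comparison

All inference is rank-based with mid-ranks and tie-corrected variances; ties
are structural (most subjects have ARF = 0 for most sequences), not
incidental.  All tests are two-sided.

* **Wilcoxon rank-sum** reports both the focal group's rank-sum W and the
  Mann–Whitney U (software conventions differ on which is printed; reporting
  both removes the ambiguity).  The p-value is exact — exhaustive enumeration
  of all C(N, n_a) rank-subset assignments, two-sided by doubling the smaller
  tail — when n_a + n_b ≤ 12, and otherwise uses the normal approximation
  with tie and continuity corrections.  If all pooled values are identical
  the result is flagged `degenerate` with p = 1.
* **Kruskal–Wallis** uses the tie-corrected H with a χ²(g−1) reference
  (delegated to scipy), with the same degenerate-input handling.
* **Dunn post hoc** z divides the difference of mean pooled ranks by
  `sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j))`, with Bonferroni
  multiplication over the pairwise contrasts, capped at 1.  Post hocs are
  gatekept: computed only when the omnibus rejects (configurable).

Alpha policy: the replication and specificity steps default to the fixed
level **.014**; the exploratory scan defaults to **.05/k** (.005 for k = 10).
A fixed level and a base/divisor rule are both expressible, so either
convention for the replication correction (.014 as stated, or .05/7 ≈ .0071)
can be selected explicitly.

Mean-rank summaries pool all subjects per key, mid-rank, and report per-group
means with SE = sd/√n_g; the pooled mean is (N+1)/2 by construction, which
the tests assert.

## Synthetic cohorts

Emotion dynamics are first-order Markov at the prompt cadence over the 11
states (10 categories + no_emotion) — the minimal sufficient generator for an
analysis that only measures lag-1 structure.  `no_emotion` is an ordinary
chain state so activation and down-regulation have a generating mechanism.
Prompt times start at the waking start (default 07:00–23:00, a 16-h window in
a 24-h day) and advance by 15 ± 1 min (uniform jitter); the overnight gap
breaks chains automatically via `max_gap`.  Missingness is independent per
prompt (MCAR, default 5%) — informative missingness is out of scope — and the
underlying state advances whether or not the prompt is answered.

`build_transition_model(base_persistence, boosts)` starts every row with
self-transition `base_persistence` and uniform off-diagonal mass, applies
additive increments to targeted entries, and rescales each row's non-boosted
entries proportionally so rows sum to 1 (checked to 1e−12).  The initial
distribution defaults to the stationary distribution of the built matrix
(eigen-decomposition), so chains start at equilibrium.  RNG is numpy's PCG64;
subject streams are spawned from the master seed via `SeedSequence`, making
every cohort a pure function of its config.

Shipped presets (`hc`, `bpd`, `ptsd`, `bn`, base self-transition 0.25) are
**illustrative mechanisms, not estimates of any real sample**: occupancy
rates per emotion are unpublished, so the presets only encode the direction
of the group differences of interest — controls with high no-emotion/happy
occupancy; a focal clinical model with sticky anxiety and sadness,
anxious↔sad oscillation and anxious→angry switches; a second anxious-sticky
clinical model; and a model with anger→disgust and disgust→unspecific
switches.  The default study cohort is 43/28/20/28 subjects (119 total)
across the four presets.

## Validation studies

`emoseq.studies` runs the actual pipeline on many simulated cohorts.

* **Type-I calibration**: four groups of 20 subjects drawn from one *shared*
  model over 500 cohorts; every rejection is a false positive.  The shared
  model is the **uniform transition matrix** (self-transition 1/11): the
  fully unstructured null, chosen so that the pipeline is tested against
  data with no lag-1 structure at all.  Per-key rejection counts are checked
  against simultaneous 95% binomial bands of each step's nominal alpha (the
  band adjusts its per-key coverage for the number of keys in the step, 7 or
  113, so the joint check has 95% coverage under exact calibration; marginal
  95% intervals applied to 113 keys at once would fail a perfectly calibrated
  test about half the time).  Observed rates run slightly below nominal —
  the discreteness of rank statistics under heavy zero-ties makes the tests
  mildly conservative, which is the safe direction.
* **Effect recovery**: one group's anxious self-transition raised by +0.25
  over the uniform baseline, 40 vs 28 subjects, 200 cohorts; the replication
  step must flag persistence(anxious) and the boosted group must show the
  highest mean ranked ARF.  The uniform baseline makes the planted boost the
  *only* structure separating the groups — the cleanest ground truth.  On a
  sticky baseline (self-transition well above 1/11) the same boost also
  raises anxious occupancy, which enlarges the ARF denominator and attenuates
  the ARF contrast; power against a fixed additive boost is therefore
  baseline-dependent, which is a property of the ARF normalisation itself,
  not of the tests.

## What passing tests do and do not show

The simulator emulates the sampling design (cadence, jitter, sleep window,
missingness, categorical lag-1 dynamics), so green tests demonstrate that the
pipeline counts correctly, holds its nominal level under heavy ties, and
recovers planted lag-1 effects at realistic group sizes.  Real emotion series
are not first-order Markov at 15-min resolution (circadian structure,
event-driven cascades, autocorrelated missingness, reporting styles), so the
studies say nothing about the substantive validity of any clinical finding —
only about the correctness and calibration of the measurement and testing
machinery one would apply to such data.

## Numerical and degenerate-input choices

* Mid-ranks everywhere; tie corrections in every variance.
* Exact-enumeration cutoff at N = 12 keeps the worst case at C(12,6) = 924
  subsets per test.
* Identical-everything inputs return p = 1 flagged `degenerate` instead of
  raising, so batch scans over 120 keys never abort on an empty key.
* Diary validation is strict (closed vocabulary, strictly increasing
  timestamps, known groups) and error messages name the offending row and
  token; analysis entry points additionally require ≥ 2 groups (≥ 3 for
  omnibus steps) with ≥ 2 subjects each.
* CSV round-trips are exact: floats are written with `%.17g` and parsed in
  round-trip precision mode.

## Problem sizes

Default test-suite problem sizes: 1,000 random diaries for the counting/ARF
oracle comparison, 500 null cohorts (4×20 subjects) for calibration, 200
boosted cohorts (40 vs 28) for power; the acceptance script reuses the same
routines at 150/100 cohorts.  These sizes give Monte-Carlo error comfortably
inside the asserted bands while keeping a full run in a couple of minutes.
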