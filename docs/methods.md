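# Methods

## The scientific question

When a voluntary movement is triggered by a startling (loud) auditory cue,
reaction times shorten dramatically (the *StartReact* effect), plausibly
because brainstem circuits with reticulospinal output participate in
releasing the prepared movement. Reticulospinal projections diverge onto
many motoneuron pools, while corticospinal projections are focal; if the
rapid responses leaned more heavily on the reticulospinal tract, the
muscle activity they produce should be less *fractionated* — fewer
independent degrees of freedom across muscles. This package implements
the analysis that tests this: compare the dimensionality (and the
task-specificity) of multi-muscle EMG patterns between loud- and
quiet-cued trials.

## Pipeline

1. **Onset detection** (`startreact.onsets`). EMG is rectified; each
   muscle's threshold is the mean + 3 SD of the rectified baseline over
   the half-open window [−200, 0) ms before the cue (SD with n−1
   denominator). The reaction time is the first post-cue sample strictly
   above threshold within a 500 ms search window; the trial's earliest
   reaction time (eRT) is the minimum across muscles. An optional
   `debounce_ms` requires crossings to persist for a minimum duration.
   The pipeline default is 1 ms; with Gaussian-like baseline noise about
   0.9 % of rectified samples exceed mean + 3 SD, so a single-sample
   criterion false-triggers on essentially every trial whose true onset
   is late — the debounce is the automated stand-in for visual
   inspection and manual correction of such artifacts. Explicit
   per-trial/muscle overrides are also supported
   (`apply_overrides`). Trials in which no muscle crosses threshold are
   dropped from all later stages with a logged warning.

2. **Window features** (`startreact.windows`). Mean rectified EMG per
   muscle in windows 0–10, 10–20, 20–30 and 50–100 ms after the eRT
   (half-open, so adjacent windows share no sample) — one nonnegative
   15-vector per trial and window.

3. **Exclusion and matching.** Loud trials with eRT > 100 ms show no
   startle shortening and are excluded; an equal number of quiet trials
   is removed uniformly at random, pooled over tasks within subject, so
   both condition matrices keep identical row counts. Because the quiet
   removal is random, the whole CPVE computation is repeated (default
   100×) with fresh draws and the per-subject quiet curve is the mean
   over repeats; the loud curve cannot depend on the draw and the code
   asserts this rather than assuming it.

4. **CPVE** (`startreact.cpve`). Each n × 15 condition matrix is
   z-scored per muscle (n−1 SD; zero-variance columns are flagged
   degenerate and zeroed so the eigen-analysis stays defined), its
   covariance eigendecomposed, eigenvalues sorted descending and
   cumulated into the cumulative percent variance explained. A slowly
   rising CPVE curve = highly fractionated muscle use.

5. **Monte Carlo comparison** (`startreact.mctest`). CPVE components are
   cumulative and therefore strongly dependent; standard multiplicity
   corrections do not apply. Instead the condition labels are swapped
   within subjects in all 2^S ways (1,024 for ten subjects, identity
   included), giving the exact null distribution of the difference of
   condition means. Per-component thresholds are the n-th smallest and
   n-th largest surrogate values; n is calibrated to the largest value
   for which at most 51 of the 1,024 surrogate curves have *any*
   component strictly outside the thresholds — a family-wise bound at
   P ≤ 0.05 across the 15 components. The observed difference is then
   compared against the same thresholds; "outside" is strict, so ties
   never count and the final component (identically zero, both curves
   end at 100) can never be flagged. When the model is fitted with a
   different subject count, the bound is rescaled proportionally
   (⌊51·2^S/1024⌋) so the level stays at 0.05. Above 20 subjects the
   enumeration falls back to 2^20 seeded random assignments with the
   identity forced in.

6. **Similarity** (`startreact.similarity`). Cosine similarity
   x·y/(|x||y|) between the *non*-z-scored window vectors (cosine is
   scale-invariant per trial, so amplitude normalisation is unnecessary).
   Four pooled sets: same-task quiet–quiet, same-task loud–loud,
   different-task quiet–quiet, same-task quiet–loud. Pairs are unordered
   without self-pairs; cross-cue uses all within-task pairs; pairs are
   always formed within subject (across-subject pairs would compare
   different electrode placements). Summaries report means, the fraction
   of values above 0.8, and Welch t-tests of each set against the
   same-task quiet–quiet reference (plus loud–loud vs quiet–loud). The
   t-tests ignore the dependence between overlapping pairs, exactly as
   is conventional for pooled similarity samples; read them with the
   effect sizes. The similarity stage uses a single seeded exclusion
   draw (the seed is recorded in the report).

## Synthetic experiments

`startreact.simulate` generates experiments with known ground truth so
every stage is testable without recordings.

* **Design defaults**: 10 subjects × 32 tasks × 5 trials per cue,
  15 muscles, 5 kHz; recording spans −250…+700 ms around the cue.
* **Reaction times**: truncated normal per cue, lower bound 30 ms
  (negative or near-zero RTs are nonphysical). The location parameter is
  solved numerically so the *truncated* distribution's mean equals the
  configured mean — quiet 204 ms (SD 79), loud 144 ms (SD 75); naive
  truncation would otherwise bias the loud mean upward by ~10 ms. A
  fraction `loud_slow_fraction` (default 0.15) of loud trials draws from
  the quiet distribution instead, exercising the >100 ms exclusion path
  with realistic per-subject exclusion counts.
* **Patterns**: each subject owns `synergy_rank` (default 8) nonnegative
  synergy vectors (half-normal weights, a fraction `pattern_sparsity`,
  default 0.3, zeroed per synergy). Each task engages a random subset of
  the synergies (between one and half of them) with coefficients
  U[0.2, 1], so distinct tasks recruit visibly different muscle
  combinations the way a varied movement battery does, while every
  pattern stays inside the synergy span. Sparsity acts on the synergies,
  not on the mixed patterns, and amplitude is normalised once per
  subject (median task peak = `pattern_amplitude`, default 10× the
  baseline-noise SD): per-task operations would push patterns out of the
  synergy span or cancel the mixing coefficients, destroying the
  controlled dimensionality that makes rank recovery testable. Setting
  `synergy_rank_loud` gives loud trials their own basis — the positive
  control for the Monte Carlo test.
* **Signal**: amplitude-modulated Gaussian noise, the standard surrogate
  for interference-pattern EMG: baseline noise of SD `noise_sd` plus a
  zero-mean carrier whose SD follows the activation envelope (linear
  ramp over `onset_ramp_ms`, default 10 ms, to weight × (1 + 10 %
  jitter)). The mean rectified level is then monotone in the envelope,
  making window means approximately linear in the pattern weights. Each
  active muscle starts at the trial's drawn eRT plus a uniform lag up to
  `muscle_lag_max_ms` (default 10 ms); one active muscle leads at zero
  lag so the programmed earliest onset is exactly the drawn value.
* **Reproducibility**: all randomness descends from `SynthConfig.seed`
  via `numpy.random.SeedSequence` keyed by purpose and trial; the same
  seed yields byte-identical trial stores on disk.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis consumes — design
counts, cue-dependent RT distributions, controllable fractionation rank,
task-specific nonnegative patterns, rectifiable AM-noise EMG — but not
motor-unit biophysics, electrode cross-talk, the hardware notch/band-pass
chain (emulated only as generator parameters), postural drift, or the
actual per-task muscle assignments of the movement battery (tasks are
distinct random patterns). Passing tests therefore validate the
*analysis machinery* and its statistical calibration, not claims about
any particular recording.

### Detection latency

A threshold detector fires only after the envelope clears
baseline-mean + 3 SD, so detected onsets lag programmed onsets by a few
ms (≈5–6 ms at the defaults: 10 ms ramp, ~10:1 peak SNR, 1 ms
debounce). Both cues incur the same latency, so the quiet − loud
difference recovers the programmed 60 ms essentially unbiased, while the
per-cue detected means sit slightly above 204/144 ms. Exact recovery of
the per-cue means to within sampling error (±2 SEM at n = 50,000, i.e.
±0.7 ms) is not attainable with any nonzero rise time and is not claimed;
tests bound the recovery at ±10 ms and the difference at ±3 ms.

## Numerical choices

* Eigenvalues are clipped to zero when negative by less than
  10⁻¹⁰ × trace; larger negatives raise (the input was not PSD — a bug,
  not round-off). An all-zero covariance raises: no variance to
  apportion.
* The final CPVE value is pinned to exactly 100 against round-off.
* Exclusion-repeat r of subject s uses seed (base_seed, crc32(s), r);
  runs are reproducible and repeats independent.
* Rank-sum comparisons use the Mann–Whitney form (exact null for small
  tie-free samples, normal approximation otherwise); normality is
  assessed with the Lilliefors-corrected Kolmogorov–Smirnov test since
  distribution parameters are estimated.
* Z-scoring flags zero-variance columns instead of erroring; the flag
  propagates to reports.
* `generate_cpve_samples` projects noisy curves back onto the valid set
  (clip to [0, 100], running maximum, final value 100). The projection
  is applied identically to both conditions, so exchangeability under
  the null — the only property the Monte Carlo test requires — is
  preserved exactly.

## Problem sizes used by the test suite

End-to-end checks run reduced designs chosen so that every stage still
has work to do: 10 subjects × 12 tasks × 5 trials per cue for the
null/positive-control verdicts (enough loud trials survive the >100 ms
exclusion for stable covariance estimates), 1,000 replicates for the
test-level calibration check, and 50,000 trials per cue for
reaction-time recovery. The default full design (10 × 32 × 5 × 2 =
3,200 trials) runs end to end in a few minutes on one CPU.

## Known limitations

* The calibrated level is ≤ 51/1024 by construction but discrete: the
  achieved count is typically a little below the bound, making the test
  marginally conservative.
* The power of the Monte Carlo test for a given CPVE difference depends
  on the mean/SD curves supplied to `power_analysis`; the package ships
  the machinery, not a canonical experimental spectrum.
* Similarity t-tests treat overlapping pairs as independent (standard
  practice, anti-conservative); the permutation machinery is not applied
  there.
* The synthetic loud RT distribution is unimodal; real StartReact RT
  histograms are bimodal (fast startle-released trials plus slow
  ordinary ones). The `loud_slow_fraction` mixture approximates this
  only coarsely.
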