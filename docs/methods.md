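# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the known limitations. Defaults live in the dataclasses named below;
everything here can be overridden per call.

## Data model and time

All behavioral input is a dense per-larva, per-bin table of seconds-active
(`ActivityMatrix`), validated on construction: values in [0, bin width],
strictly increasing bin starts with constant spacing, no duplicate
(larva, bin) pairs. Time is seconds since experiment start; clock-time
anchoring comes only from `EpochSchedule` (default 14 h light : 10 h dark,
lights on 09:00, off 23:00). Day N runs lights-on→lights-off of
developmental day N; night N runs lights-off→next lights-on. Missing bins
are an error rather than imputed: the upstream tracker emits dense bins,
so a gap indicates a corrupted export. Vendor column layouts are handled
by a small dialect adapter (column names + delimiter), not by parsing
proprietary formats.

## Sleep scoring (`sleep_metrics`)

A sleep minute is a 60-s bin with activity exactly 0. The movement
quantization threshold lives upstream in the tracker (its detection/
burst/freeze settings are acquisition metadata), so the scoring itself is
parameter-free; a `zero_threshold` knob exists for sensitivity analyses
but defaults to 0. Conventions the underlying literature leaves open,
decided here and flagged in the output:

- **Epoch-boundary bouts** are split at the boundary and the clipped
  portions counted in each epoch (affects bout counts by at most 1).
- **Sleep latency** is measured from epoch start; when a larva never
  sleeps it is censored at the epoch length and flagged
  (`latency_censored`), keeping group means defined while letting users
  drop censored values to reproduce the other convention. Latency is
  computed identically for day and night epochs.
- **Waking activity** divides total activity by non-sleep minutes; a
  larva asleep for a whole epoch reports 0 with `waking_defined=False`.

These choices make the identities sleep + wake = epoch length,
waking_activity × waking minutes = total activity, and
bout_count × mean bout length = sleep hold exactly; the test suite
asserts them on random traces.

The heat-shock ratio divides each larva's post-induction night sleep by
the *genotype mean* of the pre-induction night (×100), so individual
percentages share a common denominator within genotype.

## Arousal threshold (`arousal_assay`)

Responses are scored as any movement in the 5 s after a tap, mirroring
the 5-s pre-stimulus window used for the background estimate (the
post-window length is a config argument; 5 s is the package default
since the assay's inter-trial interval of 1 min makes windows
non-overlapping by construction). Response fractions are aggregated per
power over all (larva, event) observations — equivalent to per-event
averaging for the balanced 14-power × 30-trial design. Background b is
the per-larva fraction of the 420 pre-windows with movement, averaged
over the group; the corrected response c(p) = r(p) − b keeps negative
values (clipping would bias the fitted bottom upward).

The four-parameter logistic is fit in log₁₀ power by
`scipy.optimize.least_squares` (Levenberg–Marquardt, ftol/xtol 1e-12)
with 5 deterministic multi-start initializations spanning the observed
log-power range (jitter from a fixed seed); the best sum of squares
wins. The bottom is fixed at 0 by default because responses are
background-corrected; all four parameters can be freed. Degenerate
inputs (fewer than 5 powers, all-equal responses) raise instead of
returning a meaningless fit.

Nested-curve comparison: groups are fit separately (SS_sep, df_sep) and
jointly with the named parameter(s) tied (SS_sh, df_sh); then
F = ((SS_sh − SS_sep)/(df_sh − df_sep)) / (SS_sep/df_sep) with p from
the F distribution. Sharing only `log_etp50` tests a threshold shift,
only `top` a maximal-response change, `all` any curve difference. The
joint SS is clamped at SS_sep to absorb optimizer noise (F ≥ 0 by
construction). Both the fitted top and the empirical maximum corrected
response are reported, since "maximal response" can mean either.

## Optogenetics (`optogenetic_assay`)

Windows per 30-min light trial: baseline = 30 min pre-onset minus the
final minute; response = 30 min post-onset minus the first minute, ending
at light offset so the offset burst never enters any statistic. Each
larva's response total is divided by its genotype's mean baseline total
(per trial), per-larva ratios are averaged over the night's trials with
equal weight, and genotype means are expressed as percent of a reference
genotype. Response dynamics use the genotype-mean 10-s trace averaged
across trials, smoothed with a centered 5-bin (50-s) moving average
('valid' convolution, so edge bins lacking full support do not compete);
A is the maximum and T_A the time from onset to the center of the first
bin attaining it, ties broken earliest. The 5-bin kernel is a default,
not a claim: the right window depends on the noise level of the
genotype-mean trace.

## Calcium (`calcium_dff`)

ΔF/F₀ = (F − F₀)/F₀ per trial, with F₀/F the means of the 10 frames
before/after the stimulation marker ("10 frames post stimulation" is
read as the first 10 imaging frames). The sub-0.1-s gap between the last
stimulation pulse and imaging start is treated as zero. Negative values
are retained; s.e.m. uses n−1 ddof. Aggregation by neuron or by
condition requires ≥ 2 trials per group.

## Statistics (`stats`)

One-way ANOVA is computed from the explicit SS decomposition; Tukey
(Tukey–Kramer for unequal n) uses the studentized-range distribution
with the pooled MS_within. Proportions get exact Clopper–Pearson
intervals. A nonparametric all-pairs alternative (Steel–Dwass) is
deliberately not implemented; users needing it should use a dedicated
nonparametric package.

## Synthetic data (`synthetic_data`)

The generators produce data with the *statistical structure each
estimator assumes*, so recovery of planted parameters validates the
estimators — it does not validate the biology, and passing tests say
nothing about detector artifacts, habituation, circadian drift or
inter-animal correlation, none of which are simulated.

- **Sleep/wake** is an alternating-renewal process at 1-min resolution:
  geometric bout lengths (minimum 1 min) with epoch-dependent means,
  gamma-distributed activity in waking minutes (clipped to (0, 60]),
  exact zeros in sleep minutes. Defaults (day: 40-min wake bouts,
  1.5-min sleep bouts, 10 s/min waking activity; night: 8-min wake,
  4-min sleep, 6 s/min) are order-of-magnitude choices producing
  day-active, night-sleeping larvae; published bout-length distributions
  are not available to calibrate against. Geometric bouts make the
  planted mean exact under minute discretization and, being memoryless,
  leave start-of-epoch clipping unbiased.
- **Tap assay**: 14 log-spaced powers over 1–36.31, 30 trials per power
  in random order at 1-min intervals, 90 larvae; response probability
  from the planted logistic (ETP₅₀ 3.1, slope 2, top 0.34), OR-composed
  with background movement (b = 0.05) in any window. The OR composition
  means the corrected response converges to r(p)(1−b), so the fitted top
  is biased low by the factor (1−b) while ETP₅₀ is essentially
  unaffected; recovery tolerances account for this. A table-level
  binomial generator (`simulate_tap_tables`) draws the same statistics
  without materializing 1-s traces, for calibration studies needing
  hundreds of replicates.
- **Optogenetic night**: 3 trials at 3-h intervals; per-bin activity is
  binomial(10, rate/10) seconds with a rate profile of baseline →
  30-s onset burst → linear rise to the peak over `rise_time_min` →
  linear decline to `end_fraction` (default 0.9) of the peak at offset →
  offset burst. The mild decline makes the maximum unique: with a
  perfectly flat plateau, the argmax of a noisy trace is uniform over
  the plateau and T_A would be unidentifiable at any tolerance.
- **Calcium**: baseline F₀ plus an exponentially decaying transient
  (τ = 4 s, GCaMP6s-like) and Gaussian frame noise. The amplitude
  parameter is defined as the *expected 10-frame post-window ΔF/F*: the
  exponential is rescaled by 1/mean(e^(−tᵢ/τ)) over the window, so a
  planted 30% is recovered as 30% rather than attenuated by the decay
  within the measurement window.

## Problem sizes

The recovery and calibration studies use the assay's own design sizes
where stated (14 powers × 30 trials × 90 larvae; 96 larvae × 10 h;
3 light trials × 48 larvae; 8 calcium trials), with replicate counts of
50–500 chosen so Monte-Carlo error is well inside each tolerance while a
full run of the suite and the acceptance script completes in minutes on
one CPU.

## Limitations

- Sleep scoring consumes the tracker's quantized movement output; no
  pixel-level reanalysis, and no modeling of sleep homeostasis or
  circadian phase.
- The dose–response module implements only the four-parameter logistic;
  other psychometric shapes and habituation dynamics are out of scope.
- Background correction uses the group-mean b; a per-larva correction is
  a one-line variant but changes the interpretation of c(p) and is not
  the default.
- The optogenetic "percent of reference" operates on baseline-normalized
  activity; comparing raw totals instead would differ whenever genotypes
  differ at baseline.
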