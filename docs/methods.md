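# Methods

This note records the scientific and numerical choices behind `fspheno`:
what each stage computes, which parameters matter, what the synthetic
cohort does and does not emulate, and where the design was genuinely open.

## Percentile-threshold scoring

Severity scores are data-driven: no fixed physiological cut-offs exist for
"too much freezing", so each variable is binned against empirical
percentiles of a reference distribution. Percentiles use sorted linear
interpolation with inclusive endpoints (`numpy.percentile`,
`method="linear"`), so p=0/100 are the sample extremes and cuts are
continuous in the data.

Three rules cover the behavioral variables:

* **FS tail** (novelty freezing/escaping). Control animals barely freeze or
  escape in a novel context, so the control distribution cannot grade
  severity. Score 0 extends to the control 95th percentile; scores 1/2/3
  start at the 75th and 95th percentiles of the pooled shocked dataset.
  If an FS cut falls below the control cut the cuts are clamped monotone
  (running maximum), preserving ordered severity on degenerate inputs.
* **Bidirectional** (elevated-plus-maze open-arm time and velocity). Open-arm
  behavior has an adverse pole (avoidance: less time, slower) and a
  protective/risk-taking pole. The map is: 0 inside the control
  interquartile range; on the adverse side 1 between the 5th and 25th
  percentiles, 2 beyond the 5th, 3 beyond the control minimum; on the
  protective side deviations beyond the 95th percentile score 1, capped
  there — risk-taking is atypical but not graded as escalating pathology.
  The full interval map is a package decision: the underlying idea
  (0 = adapted, monotone severity outward, opposite directions scored
  relative to 0) admits several concrete maps and we fixed one.
* **Startle ratios.** Habituation ratios below 1 (amplitude) or above 1
  (latency) mark intact habituation. The hyperarousal gates are fixed
  constants — amplitude ratio ≥ 0.95, latency ratio ≤ 1.05 — and inclusive
  on the hyperarousal side, the one deliberate exception to the global
  tie-break. Scores 2/3 use the control median and 75th (amplitude) or
  25th (latency) percentile beyond the gate, clamped so the cut sequence
  stays monotone; when the control median sits below the 0.95 gate the
  upper bins collapse and any non-habituated animal scores 3.

Global tie-break: a value exactly on a cut takes the lower-severity score.
Non-finite values propagate as missing scores; a missing component voids
the composite (the animal is excluded from classification, not imputed) —
complete-case analysis keeps the composite's [0, 24] scale comparable
across animals.

Startle sessions are 40 trials; trials with pre-stimulus movement are
excluded before taking the first/last five valid trials. Windows shrink to
a minimum of three valid trials; below that, or when the first-window
median is zero, the ratio is missing (with a warning).

## Two-step classification

The susceptibility cut-off is recomputed from the supplied control group
(never hard-coded) as the *maximum* control composite: controls define the
upper bound of adapted behavior. A composite exactly at the cut-off is
resilient — the cut-off is itself a control score, and the reference group
must remain non-susceptible under its own rule. The escaper criterion is
the presence of at least one escape attempt (wall climb or jump) during
day-28 full-context re-exposure, regardless of freezing level; the control
95th percentile of day-28 freezing is recorded as QC metadata, and a
susceptible animal with neither high freezing nor any escape attempt is
labelled freezer with a QC flag rather than given a fourth class.
Phenotype percentages are reported relative to the shocked total, rounded
to the nearest 0.5 percentage point.

## Sleep metrics

An episode is a maximal run of identical 5-s epochs, with no smoothing or
merging of brief interruptions — the simplest fully auditable rule. A
configurable `merge_gap_epochs` exists for sensitivity analyses but
defaults to 0, so episode counts are exact run counts and
episode_count × mean_duration equals total state time identically.

Sleep-onset latency is the start time (minutes from the recording origin)
of the first episode lasting ≥ 25 s (5 epochs); shorter entries into the
state do not qualify. When no qualifying episode exists the latency is the
sentinel `None`, excluded from group statistics. The origin is lights-on
at baseline and cue placement on day 14; both coincide with epoch 0 of the
respective recording, so no offset arithmetic is applied.

Sleep entry (latency + episode count) and continuity (% time + mean
duration) scores reuse the bidirectional percentile rule against control
metrics. Direction conventions are a package decision: longer latency,
fewer episodes, less state time and shorter episodes are all treated as
the adverse direction for both SWS and REM, so a *higher* entry score
means *more altered* sleep entry. Wake is not scored (only the two sleep
states carry radar scores).

The epoch classifier is deliberately minimal: WAKE if EMG power exceeds a
threshold (default 3.0, in the generator's arbitrary power units, between
the wake ≈ 10 and sleep ≈ 1 levels); otherwise REM if theta/delta > 1.5
(REM ≈ 4, SWS ≈ 0.25), else SWS. `ClassifierConfig.from_quantiles` derives
both thresholds per recording from the feature distributions given rough
prior state fractions, for inputs on other scales. It is a stand-in for
full polysomnographic scoring, adequate when the state-conditional feature
distributions are well separated (as the generator's are), and not
validated on real EEG/EMG.

## c-Fos counting

Detection: Gaussian smoothing (sigma 2 px) → intensity threshold → local
maxima (minimum distance 5 px) as seeds → watershed over the binary mask →
objects below 16 px² dropped. The threshold defaults to the 0.95 quantile
of the smoothed image, since absolute intensities are
acquisition-dependent; an absolute mode is available and every parameter
is recorded in `SpotDetectionParams`. Defaults were set on synthetic
scenes with ~5% spot coverage; dense tissue will need a lower quantile.

Mask combination is object-level: a nucleus is c-Fos+ if its footprint
overlaps the c-Fos mask (any shared pixel by default; an overlap-fraction
option exists). This never increases the object count. Objects are
assigned to ROIs by centroid; densities are counts divided by ROI area in
mm² from the supplied pixel size; per-animal regional values are medians
over up to three slices, flagged when fewer than three are available.
ROIs arrive as label-mask images — atlas registration and PKC-δ-based CeL
delineation are assumed already encoded in the mask.

Activation scores use a one-sided higher-is-more-activated rule with cuts
at the control median, 75th percentile and maximum. The one-sided choice
means a control-range 25th percentile plays no role; hypo-activation is
not graded, matching the combined-score definitions (sums of 0–3
activations into 0–6).

## Statistics

Kruskal–Wallis uses the tie-corrected H (scipy); identical pooled values
short-circuit to H = 0, p = 1. Post hoc comparisons are Dunn's z-tests on
pooled midranks with tie-corrected variance, unadjusted by default with an
optional Holm flag — the post hoc method is a package choice among several
defensible ones, and is attached only when the omnibus p < 0.05. Friedman
uses the tie-robust chi-square form (ranking within subjects with
midranks), which reduces to the classic column-rank-sum statistic without
ties and to the sign-test ordering for two timepoints; missing cells are
an error (complete-case). The one-sample signed-rank test drops zero
differences, uses the exact null distribution when n ≤ 25 and the absolute
differences are tie-free, and otherwise a normal approximation with
continuity correction. Spearman uses midranks with two-sided p; constant
vectors yield an undefined (NaN) correlation rather than ±1.

## The synthetic cohort

The generator exists so that every stage has ground truth. Families per
variable: truncated normals on [0, 100] for percentage-of-session
variables (bounded, allows mass near 0), log-normals for velocities,
distances and habituation ratios (positive, right-skewed,
multiplicative), and a zero-inflated 1 + Poisson mixture for escape-attempt
counts (most animals never attempt; attempters make a few). Default
archetype parameters encode the qualitative orderings the analysis is
meant to detect — freezer novelty-freezing ≫ controls, escaper escaping
and failed startle habituation, resilient animals control-like except for
cue-conditioned freezing — with overlap left in place so classification is
non-trivial (planted-label recovery is ~96–99%, not 100%).

Hypnograms come from a first-order Markov chain over {WAKE, SWS, REM} at
5-s resolution with WAKE→REM transitions forbidden (standard rodent
sleep-stage grammar; also keeps REM latency well defined). Matrices are
constructed by `transition_matrix` from target long-run fractions and mean
bout lengths (SWS 100 s, REM 60 s, 70% of REM exits to wake) by solving the
stationary flow-balance equations, so the stationary law equals the
targets exactly and can be verified independently by eigen-analysis.
Default fractions: ~45/47/8% (WAKE/SWS/REM) for controls at both
timepoints; resilient animals move from 6% REM at baseline to 11% on day
14 while both susceptible archetypes drop to 6.5–7% — producing the
planted negative REM-vs-severity correlation. Epoch features are
state-conditional normals (floored at 10⁻³ so ratios stay defined) with
noise SD 0.6 against mean separations of ≥ 5 units, giving a ~99.9%
separable classification problem.

What the generator does *not* emulate: within-animal correlations across
tests beyond the archetype structure, circadian (light/dark) modulation of
the sleep chain, raw EEG/EMG waveforms, estrous effects (the emulated
design used males only), imaging artifacts beyond additive Gaussian noise,
and any left/right asymmetry. Passing tests therefore demonstrate the
*pipeline's* correctness on data with the assumed structure, not
robustness to real-data pathologies such as scorer drift or staining
variability.

Determinism: all sampling uses `numpy` PCG64 generators seeded with the
tuple (global seed, archetype index, animal index, purpose counter), so
outputs are byte-identical under a fixed seed and single animals can be
regenerated without resampling the cohort.

## Problem sizes

The packaged checks use: n = 50 per archetype (200 animals) for
pipeline-level label recovery; a single 24-h recording (17,280 epochs) for
classifier agreement; 10 simulated days (172,800 epochs) for the
stationary-law comparison (2% absolute tolerance, generous relative to the
observed < 1% fluctuation); 50-spot scenes (radius 6 px, 45 px spacing,
peak amplitude 100, noise SD up to 20) for imaging recovery; and ≥ 1,000
random small instances per primitive for oracle equivalence. These sizes
make all statistical checks stable under any seed while keeping the full
suite under a minute of compute.

## Known limitations

* The bidirectional and startle score-2/3 bin maps, the sleep score
  direction convention, and the one-sided activation rule are fixed
  package conventions chosen among several defensible readings of the
  percentile-scoring idea; alternatives would shift individual scores by
  ±1 but preserve orderings.
* The epoch classifier is not a validated sleep scorer.
* Detection defaults are tuned for sparse, roughly circular nuclei;
  densely packed tissue requires parameter adjustment.
* Group-level inference assumes independent animals; littermate or cage
  effects are not modelled.
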