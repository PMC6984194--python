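# Methods

This note documents the models, numerical choices and known limitations of
`mibci`.  It is written for users who want to judge what a passing test
suite does — and does not — establish about real EEG.

## The paradigm being modelled

A participant sits with their right hand hidden; an anthropomorphic robotic
hand lies beside it.  In a fixed-structure *training block* (~50 runs of
about 14 s: 5 s rest, LED cue, 1.5 s imagined flexion, 5 s rest, LED cue,
1.5 s imagined extension, with imagery onset 300 ms after the LED), the
robotic hand moves in synchrony with the instructed imagery.  Classifiers
calibrated on this block then drive a *feedback block* in which the hand
moves whenever the decoder detects new imagery — self-paced, with no trial
structure.  Feasibility is assessed on three levels: electrophysiology
(event-related desynchronization, ERD, of the 8–30 Hz sensorimotor rhythm),
subjective embodiment (questionnaire constructs), and performance
(training and feedback accuracies).

## Synthetic EEG generator (`synthdata`)

No public recordings exist for this paradigm, so the generator *is* the
data source, and its design decides what the tests demonstrate.

**Signal model.**  Each imagery class has its own cortical source: a comb
of constant-amplitude cosines (flexion 11/15/19/23 Hz, extension
13/17/21 Hz), each tone's instantaneous frequency wandering slightly
(Ornstein–Uhlenbeck, relaxation 2 s, spread 0.25 Hz), with a common slow
multiplicative amplitude jitter (5%).  Sources are projected through fixed
spatial topographies with disjoint channel support — flexion over
C3/CP1/FC1, extension over C4/CP2/FC2, a mediolateral weight shift over
sensorimotor cortex — and added to per-channel 1/f background (σ = 2) plus
white sensor noise (σ = 0.5); oscillator amplitude is 5 (arbitrary
microvolt-like units, ~25× the in-band background power on the carrier
channels).

**Why a comb, and why interleaved.**  Three properties are needed at once:
(i) power spread across the whole 10–25 Hz analysis band, so that the
per-frequency-bin dB statistics see the effect; (ii) a nearly
deterministic short-time band power, so that injected effects are exact at
the single-trial level; and (iii) mutually incoherent class sources.  A
filtered-noise oscillator fails (ii): its Rayleigh-distributed envelope
makes single-trial band power fluctuate ~30%, which defeats any
threshold-crossing latency estimator.  Identical combs in the two sources
fail (iii): same-frequency tones are phase-coherent within an epoch, CSP
mixes the sources, and slow cross-source beats corrupt the extracted
component.  The interleaved combs (2 Hz offsets) make the sources
orthogonal over 1.5 s epochs while every analysis bin stays
tone-dominated.  Beat terms within a class fall on multiples of 4 Hz and
are nulled exactly by the 0.25 s moving average used in the latency traces.

**ERD injection.**  During an imagery trial the class's source amplitude
is multiplied by √(1−d) from `erd_latency` after onset to the end of the
1.5 s period, so the injected fractional band-power drop is exactly `d`.
Defaults: depth 0.3, latency 0.51 s (control preset) / 0.63 s (stroke
preset); the presets are simulation conditions mirroring observed group
means, not claims about stroke physiology.  A 2 s rest tail is appended
after the last run so ±analysis windows around the final trial stay in
bounds.

**Feedback scenarios.**  A `UserModel` (reaction delay, compliance
probability, spontaneous-imagery rate in events/min) drives the latent
mental-state trace: the rest-vs-move task alternates eight 30 s phases
with deliberate imagery bouts every ~6 s during move phases; the
command-following tasks issue open/close/grasp commands (default every
20 s) to which a compliant user responds with up to three 1.5 s bouts of
the required class (extension then flexion for grasp).  The ground-truth
intention trace is returned for evaluation oracles.

**What the generator does *not* emulate:** bursty SMR envelopes (raise
`amp_jitter` to approximate them), eye/muscle artifacts beyond amplitude
outliers, non-stationary background, volume-conduction mixing beyond fixed
rank-1 topographies, or inter-channel correlated noise.  Consequently the
decoding accuracies reached on synthetic data at a given ERD depth are
upper bounds on what the same depth would yield in real EEG, and passing
recovery tests demonstrate correctness of the estimators, not their
real-data power.

## Signal processing (`sigproc`)

* Band-pass: 4th-order Butterworth (SOS), 8–28 Hz; single-pass (causal)
  on the online path, forward–backward (zero-phase) offline.
* Epochs: 1.5 s from imagery onsets; two rest epochs per run starting
  1.75 s into each 5 s rest period (centered, clear of movement-offset
  transients), labelled `rest_open` before flexion and `rest_closed`
  before extension — hence the exact 2:1 rest:imagery ratio.
* Artifact rejection: epochs whose peak amplitude or mean variance exceeds
  5 robust z-scores (median/MAD across epochs) are dropped; this replaces
  manual inspection with a deterministic, automatable rule.
* CSP: per-trial covariances normalized by trace and averaged per class;
  `Σ_A w = λ(Σ_A+Σ_B)w` solved with `scipy.linalg.eigh`; components
  ordered by λ descending; sign fixed so each component's largest-magnitude
  pattern weight is positive; candidates = first 4 + last 4; optional
  diagonal-loading shrinkage (default 0).  The analysis pipeline passes
  shrinkage 0.2: unregularized filters trained on narrow-band data pick up
  large admixtures of low-variance background directions which explode
  when the filter is applied to broadband recordings for the
  time–frequency analysis.
* Plausibility selection: candidates whose squared pattern weight over the
  sensorimotor channel set (C3, CZ, C4, FC1, FC2, CP1, CPz, CP2, CP5, CP6)
  is ≥ 50% of the total are kept; at least the best-concentrated one
  always survives.

## Decoding (`decode`)

Logistic regression with L2 penalty λ = 1 on standardized log-variance
features (scikit-learn, lbfgs, tol 1e-10 — deterministic); ties at p = 0.5
classify as the negative class.  Block-wise CV uses k = 5 contiguous
temporal blocks with CSP refit per fold, so paired trials from one run
never straddle folds.  The chance level is the smallest k/n whose exact
binomial upper-tail probability is below α; feedback accuracies are tested
by the Wilson score interval (above chance iff its lower bound exceeds the
guessing rate).

## Controller (`controller`)

All decisions happen on the 50 ms tick grid; elapsed times are whole
ticks, so traces are exactly reproducible and an independent hand
simulation can be compared bitwise.  Threshold comparisons are inclusive
(≥ θ); in the transient "just" states a threshold crossing at the timeout
tick wins over the timeout; the flexion-vs-extension classifier outputs
p(flexion), and its extension probability is the complement.  The
state-gated combination is implemented as pure gating with AND-ed
thresholds — the transition narrative fully specifies this, and no numeric
weighting scheme is defined anywhere.  The online path projects the
causally filtered recording once per classifier and evaluates sliding
1.5 s windows; this is tick-for-tick identical to refiltering each window
(tested), just faster.

## ERD analysis (`erdlab`)

* Morlet transform: fixed 6 cycles, 5–50 Hz in 1 Hz steps, computed on
  −2..3 s segments, cropped to −0.8..2.3 s, analyzed −0.5..2 s.
* Percent power change: per frequency bin, power → dB → difference from
  the mean baseline dB (−0.5..0 s) → averaged across trials in the dB
  domain → mapped back to percent, `100(10^{ΔdB/10}−1)`.  Averaging before
  linearization matters: the exponential map is convex, and averaging
  per-trial percents under heavy single-trial fluctuations biases the
  statistic upward (on planted data the naive order gave +34% where the
  truth was −40%).  The dB change is exactly zero-mean over the baseline
  window by construction.
* The SMR statistic is the 10–25 Hz × 0.5–1.5 s submatrix mean.  With
  late ERD onsets part of that fixed window precedes the ERD, so the
  statistic is structurally diluted: at depth 0.3/onset 0.6 s the recovery
  tests measure ≈ −27% for an injected −30%.
* Latency: per-trial band-mean power (linear), smoothed with a 0.25 s
  moving average, expressed as percent of the trial's mean baseline power;
  onset = first analyzed time point ≤ −30%; non-crossing trials excluded;
  participant latency = 20th percentile (linear interpolation) of the
  onsets; NaN if no trial crosses.  The grammar of "20th percentile of
  trials exceeding the threshold" is ambiguous; this reading (percentile
  of per-trial onset times) is the one implemented.
* Component choice: among the retained candidates, prefer
  sensorimotor-concentrated patterns with a genuine *desynchronization*
  (imagery log-variance below rest); this avoids compensatory directions —
  trace normalization makes non-imagery channels look relatively louder
  during imagery, creating components whose variance rises with imagery.
* Quality rubric: six boolean criteria per filter (pattern concentration,
  filter concentration, class effect size |d| ≥ 0.5, single-trial
  AUC ≥ 0.65, band-power drop ≤ −20% on pattern-weighted channels,
  Shapiro–Wilk normality p > 0.05 per class), summed over one
  flexion-contrast and one extension-contrast filter; max 12, plausible at
  ≥ 10.  The discriminability criteria are **cross-fitted**: CSP is refit
  on each temporal half, the refit component most aligned with the filter
  under evaluation (cosine) is applied to the other half, and effect size,
  AUC and normality are computed on pooled held-out features.  Scored
  in-sample, the best of eight candidate filters on pure noise shows
  |d| ≈ 1.4 and AUC ≈ 0.84 at realistic trial counts — the rubric would
  certify noise.  These quantitative proxies replace visual judgment and
  are not canonical.

## Evaluation (`evalmetrics`)

Trial reconstruction restarts the 5 s grid at each command; the series of
intended-movement trials ends with the trial containing the satisfying
movement (TP; earlier trials FN), the rest series starts at that movement
(which is not itself counted as a rest violation) and is truncated by the
next command, partial segments are dropped, and movements before any
command count against an implicit initial rest series.  A wrong-direction
movement inside an intended-movement trial scores FN and is logged
separately as a wrong-polarity event (the four-cell scheme has no slot for
it); for grasp commands both movement directions are legitimate progress.
Phase intervals in the rest-vs-move task are left-closed.  Questionnaire
constructs average three items (controls: two/one) on the −3..+3 scale;
induction is declared at mean ≥ 1, inclusive; control constructs are
scored but never flagged.

## Bootstrap statistics (`bootstat`)

The mixed 2×2 ANOVA F statistics use the classical decomposition (between
effect over subjects-within-groups; within and interaction over the
condition-by-subject residual; df (1, N−2)).  The bootstrap null centers
the within-subject factor by removing each condition's mean, resamples N
subjects with replacement, and re-randomizes group labels preserving group
sizes; p = (1+#{F*≥F})/(B+1).  Centering each *subject* on their own mean
— a tempting alternative reading — is degenerate: it zeroes both the
between-groups sum of squares and its error term, leaving the null F for
the group effect numerically undefined.  The t test draws both samples
from the pooled data; its reported CI is the 2.5/97.5 percentile interval
of the *null* t distribution (which is what makes published CIs of
strongly significant tests straddle zero).  Correlations are tested by
permuting one variable.  Default B = 3000; the calibration tests use
B = 1000 over 200 null datasets for runtime and verify type-I rates in
[0.02, 0.08] at α = 0.05.  Holm's step-down correction is implemented
directly and checked against statsmodels.

## Simulated study (`study`, `cli`)

`run_study` pushes a 9 + 9 cohort (defaults: depth mean 0.30 with SD
0.08/0.05 stroke/control, latency presets 0.63/0.51 s with SD
0.14/0.13 s, clipped to sane ranges) through the complete chain and pools
bootstrap statistics; questionnaire ratings are simulated with a shared
per-respondent trait (SD 0.9) that induces the inter-construct
correlations, item noise SD 0.8, discretized to the 7-point scale.  Every
random stage derives its seed from the study seed; result bundles embed
the seed and a config hash and reproduce exactly.  The problem sizes used
by the test suite and the acceptance script (50-run blocks, 5 seeds per
recovery cell, 200 calibration datasets at B = 1000) are chosen to give
stable estimates at interactive runtimes.

## Known limitations

* The generator's stable-envelope oscillator makes decoding *easier* than
  real SMR at the same ERD depth; treat synthetic accuracies as upper
  bounds.
* The SMR statistic's fixed 0.5–1.5 s window dilutes deep-late ERDs (see
  above); the latency estimator inherits a small early bias (~tens of ms)
  from smoothing and the 20th-percentile summary.
* The rubric's cutoffs (0.5 concentration, 0.5 effect size, 0.65 AUC,
  −20% ERD) are configurable conventions standing in for expert judgment.
* EDF export is not implemented (no writer backend); recordings persist as
  FIF via MNE, events and command logs as TSV/JSON.
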