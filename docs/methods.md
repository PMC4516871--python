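# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `alphapress`, in the spirit of a package methods
appendix: what is computed, under which assumptions, and what the defaults
mean.

## Task model and decision variable

Each trial presents a 1 s stereo click train whose left and right counts
sum to Ω ∈ {25, 32, 39, 46} (drawn uniformly per trial). Conditional on its
count, a homogeneous Poisson process places events as i.i.d. uniform order
statistics on [0, 1], so click times are sorted uniforms — exact, and free
of any rate parameter.

The decision variable is the running sum of per-click log-likelihood
ratios, log P(side | button) / P(side | saccade), with the side likelihoods
estimated from pooled click counts over all trials of each choice class.
Estimation is add-one floored at 1/(1 + Σω) per class so degenerate
sessions keep finite logs. During simulation the observer must act before
any such table exists, so the closed loop drives behavior with a fixed
provisional symmetric table (0.6/0.4); after the session the table is
re-estimated from the realized trials and every trial's end-of-stimulus DV
is recomputed with it. The two DV scales are proportional to good
approximation, so this two-pass scheme changes no qualitative result.

## Adaptive staircase

The evidence map E = 2/(1 + exp(−β(Cr−Cl)/Ω)) − 1 is inverted as
Cr = Ω/2 · (1 + L/β), L = logit((E+1)/2), rounded and clipped to [0, Ω].
Per trial, ten candidate stimuli are generated at the current β from fresh
uniform evidence draws and the one whose realized evidence is nearest the
trial's target E is presented (ties to the lowest index).

β starts at 8 and follows β ← β · 1.2^((A−75)/10) with A the percent
correct over the last 20 valid trials, clipped to [0.5, 200] for numerical
safety. The update fires once per completed block of 20 valid trials, not
every trial: re-applying the compounding rule each trial on an overlapping
window makes log β a high-gain random walk (the window lags the change it
caused, so corrections over- and under-shoot in alternation), which in
simulation drove β across two orders of magnitude. Block updates keep the
loop stable; with the default observer the staircase holds accuracy within
a point of the 75% set point and β typically lives between 7 and 20.
Saturation at a bound (an observer whose accuracy ignores difficulty) is
flagged in the log.

## The simulated observer

Behavior is generated from the end-of-stimulus DV:

* **Choice** — P(button) = lapse/2 + (1 − lapse) · logistic(slope · DV);
  slope 1.2 per DV unit, lapse 0.02.
* **Reaction time** — RT = 640 − 40·|DV| + N(0, 50) ms, so stronger
  evidence means faster responses; valid responses must land in
  (200, 800] ms.
* **Confidence** — sure iff |DV| + N(0, 0.5) ± s > 1.0, with s = 0.12 a
  sequential shift toward repeating the previous report. This
  balance-of-evidence account, with the defaults above, yields ≈60% sure
  reports, higher accuracy and faster RTs on sure trials, and a
  several-point sequential dependence — the qualitative behavioral
  pattern the analyses assume.
* **Validity** — premature/late responses, fixation breaks, double
  responses and wrong-direction saccades occur at difficulty-independent
  rates (6%/4.5%/2%/0.5%/3%) chosen to leave ≈85% of trials valid. Keeping
  these errors independent of difficulty matters: error rates that grow
  with evidence strength would bias the staircase's trailing window toward
  hard trials and destabilize β.
* **Feedback** — ±10 points for correctness, ±10 more when the report was
  calibrated to the generated difficulty (|E| ≥ 0.5 counted as easy; the
  boundary itself is classed easy).

## Signal synthesis

Epochs span −0.5 to 2.5 s around stimulus onset at 256 Hz, 16 EEG + 2 EMG
+ 2 gaze channels. EEG is 1/f-amplitude background noise (10 μV s.d.) plus
a 10 Hz oscillation with random phase whose envelope (20 μV at full gain)
drops during the stimulus/pre-movement period by alpha_effect · g, where
g ∈ [0, 1] is a monotone weighted drive: 0.5·confidence +
0.3·min(|DV|/3, 1) + 0.2·speed, normalized. The drop ramps in over
0.3–0.6 s, holds to movement onset, and on button trials converges to a
condition-independent pre-movement level (0.8·alpha_effect) before
decaying — the bound-like reconvergence expected of a decision-terminating
signal. The topography peaks at P3/CP3 (gain 1.0) and is attenuated
elsewhere (0.25–0.55). EMG channels carry 20–100 Hz band-limited noise
with a burst beginning 150 ms before the button press; gaze is fixation
noise with a 15° leftward ramp at movement onset on saccade trials.

None of this is biophysical. The generator reproduces the statistical
relations the analyses test (who correlates with what, and when), not
volume conduction, eye-blink artifacts, or realistic spectra beyond the
1/f + alpha structure. Passing tests therefore certify the analysis code
and its sensitivity under these relations — not performance on real EEG.
The default alpha_effect (0.5) gives a much cleaner effect than real
recordings; decoding accuracies in the 90s rather than near 60% are
expected and intended, since the desk-scale checks target structural
properties (chance levels, endpoints, monotonicity) rather than an
absolute accuracy.

## Preprocessing and spectral estimation

* **CAR** — per sample, the mean over the 16 EEG channels is subtracted
  from each EEG channel; EMG/gaze pass through.
* **Artifact rejection** — each EEG channel is drift-corrected with a
  causal 2nd-order Butterworth high-pass at 0.05 Hz initialized at steady
  state on the first sample (zero-phase filtering is the wrong tool here:
  with a corner period of 20 s against a 3 s epoch, reflection padding
  turns any edge transient into a whole-epoch offset). A trial is dropped
  when any stimulus-period sample strictly exceeds ±100 μV; a sample
  exactly at the bound is kept.
* **Band-pass filters** — elliptic designs (0.1 dB ripple, 41 dB stopband
  per pass) applied forward–backward, giving zero net phase and ≥80 dB at
  7/13 Hz (alpha) and 19/105 Hz (EMG). Attenuation is asserted by test on
  the realized frequency response, not assumed from design constants.
* **Windowed power** — mean squared amplitude in 300 ms windows sliding in
  30 ms steps (100 ms variant for higher temporal resolution), windows
  entirely inside the epoch, timestamps at window centers relative to the
  alignment event. "Power" is defined as mean square; the alternative
  reading of "30 ms" as overlap rather than step is available through the
  step parameter.
* **Burg AR spectra** — the time-frequency map estimates an AR(15) model
  per window by Burg's lattice recursion (implemented here and verified
  against peak-location, white-noise flatness, and known-AR oracles) and
  evaluates the one-sided PSD on a 1–80 Hz grid; grid mass approximates
  window variance. Channel averaging is always of per-channel power.
* **Modulation** — (subject mean − power)/subject mean, so larger values
  mean deeper desynchronization. The decoder feeds on modulation, which
  makes "higher value ⇒ sure" the natural rule direction.

## Regression models

The forward models regress per-trial neural power on predictors with one
fixed intercept per subject (OLS; rank deficiency raises an error naming
the collinear columns). Repeating the fit per time window yields effect
time courses; instantaneous regressors (DV, EMG power, gaze) take their
value at the window center, and windows before stimulus onset are excluded
there because the DV is identically zero in them. Significance runs are
reported as ≥10 consecutive windows with p < 0.01, timed from the first
window center. Two-sided p-values throughout.

The reverse model regresses confidence on neural power, DV, RT, EMG and
gaze, each variable normalized to its 2.5th–97.5th percentile range, with
per-subject random intercepts and slopes (6 terms per subject via
statsmodels MixedLM, ML). Small synthetic datasets often cannot support six
variance components, so non-convergence falls back to OLS with subject
intercepts — loudly, via a warning and a `method` field, never silently.

Divergence onsets between trial groups use a Wilcoxon rank-sum test per
time sample; the onset is the first sample opening a run of ≥10
consecutive p < 0.01 samples.

## Confidence decoder

Training values are split by label; a criterion c ∈ [0, 1] places the
threshold at unsure-median + c · (sure-median − unsure-median); values
strictly above predict sure (a tie predicts unsure — a measure-zero event
on continuous features, fixed for determinism). Leave-one-out refits the
medians on every fold; a fold may hold a single trial of a class (its
median is that value), and only a fold that loses a class entirely is
skipped, with a warning. Accuracy is reported per class and as the
unweighted class mean. The permutation null reshuffles labels within the
trial set (1000 times by default; configurable), repeats the full
leave-one-out evaluation each time, and summarizes the null with a fitted
normal whose upper tail gives the p-value.

Two structural properties anchor the desk-scale checks: the permutation
null centers on 50% regardless of the true effect, and at criterion 1.0
(threshold at the sure-class median) the sure class is at chance, because
roughly half of held-out sure values exceed the median of the remaining
sure values. The scheme is rank-based up to the interpolated threshold:
under a strictly monotone transform of the feature only values lying
between the two class medians can change side, so accuracies are invariant
to within a few points.

The feature window defaults to the confidence-significance run located by
the partial-effect regression on the training session (clipped to the
stimulus period), with a fixed 0.4–1.0 s fallback for sessions too small
to localize a run stably.

## Problem sizes and defaults

The end-to-end study defaults to 6 subjects × 250 trials with 200
permutations per subject, completing in a few minutes on one CPU; the
acceptance script uses 10 × 2000 behavior-only sessions for the staircase,
200 trials/1000 permutations for the null, and 500 trials for the
criterion endpoint. These sizes were chosen so every check is comfortably
powered for the structural property it asserts while remaining desk-scale.

## Known limitations

* The EEG generator is phenomenological; no forward head model, no
  artifacts beyond what the rejection threshold is tested with, no
  saccadic spike potentials or blinks.
* Click-side likelihoods are estimated once per session, pooled over
  trials; no online updating of the table during a session.
* EDF files are read (via MNE's built-in reader) but sessions are written
  as FIF + CSV; no EDF writer is bundled.
* The mixed-effects confidence model assumes a linear probability model for
  the binary report, as the weight-comparison convention requires; a
  logistic mixed model is out of scope.
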