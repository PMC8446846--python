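# Methods

## Pipeline

Raw 6-channel IMU recordings (tri-axial acceleration in g, tri-axial angular
velocity in °/s, 20 Hz) are median-filtered per channel, segmented into
per-repetition windows by an annotation table, reduced to a 60-dimensional
feature vector per window, and passed through a two-stage feature selection:
a statistical filter followed by a classifier-wrapped greedy search. The
selected subset is finally evaluated on a held-out stratified test split.

## Preprocessing

The median filter removes isolated outlier samples (sensor glitches,
transmission errors) before any feature is computed. The window length is
configurable and defaults to 3 samples — at 20 Hz this suppresses
single-sample spikes while leaving 1–4 s movements essentially undistorted.
At the signal boundaries the window shrinks to the available samples instead
of padding, so no values are fabricated; a window of 1 is the identity.
Filtering precedes segmentation and is applied to each channel
independently. Annotations use 0-based half-open `[start, end)` sample
intervals, so a window's length is exactly `end − start`. Magnetometer
columns, if present in input files, are ignored with a logged notice.

## Features

Ten feature types per channel, 60 in total, in a fixed channel-major order
(`mean, std, max, min, kurtosis, skewness, iqr, avg_power, avg_frequency,
median_frequency` per channel):

- `std` is the sample standard deviation (divisor T−1).
- `skewness = m3 / m2^1.5` and `kurtosis = m4 / m2^2 − 3` (excess form, 0
  for a Gaussian), with `mk` the biased central moments. Both are defined
  as 0 for a zero-variance window; a `DegenerateSignalWarning` flags the
  case rather than aborting the pipeline.
- `iqr` uses linear interpolation between order statistics (the common
  convention, fixed so results are bit-stable).
- `avg_power` is the time-domain mean square `(1/T)·Σx²`; by Parseval this
  equals the spectral integral while avoiding windowing choices.
- `avg_frequency` (power-weighted spectral mean) and `median_frequency`
  (first bin at which cumulative power reaches half the total) are computed
  on the one-sided, unwindowed, non-detrended periodogram with the **DC bin
  excluded**: slow limb movements carry a large quasi-constant component
  that would otherwise pin both statistics near 0. The "first bin ≥ 50%"
  rule makes the median frequency deterministic on discrete spectra. For a
  constant window the convention is `avg_power = c²`,
  `avg_frequency = median_frequency = 0`.

Windows must contain at least 4 samples (the minimum for variance and
spectral statistics).

## Filter stage

For each feature, a two-sample t test is run on every unordered class pair.
The Welch form (unpooled variances, Welch–Satterthwaite degrees of freedom)
is used because the statistic is written with separate per-sample standard
deviations; P values are two-sided. Degenerate pairs (both samples constant)
return p = 1 for equal means and p = 0 otherwise, so an everywhere-constant
feature gets s = 1 and ranks last.

The significance index combines the pairwise P values as
`s = mean + sample SD` (SD defined 0 for a single pair, i.e. C = 2). Both a
small mean and a small SD are necessary for a feature that separates *every*
class pair, which is what "smaller s = stronger classification capacity"
requires; the aggregator is nevertheless pluggable (`aggregator=` argument)
so alternatives such as mean-only can be swapped in. Ranking is ascending in
s with ties broken by ascending feature index — a total order, so ranks are
a reproducible permutation of 1..F. The candidate set keeps features with
`s` strictly below the threshold (default 0.05); an empty candidate set is
an explicit error advising a larger threshold rather than a silent fallback.

## Wrapper stage

Sequential forward selection evaluates, at each step, the stratified k-fold
(default 5) cross-validated error of the current subset extended by each
remaining candidate — standard SFS, not rank-order insertion; the filter
ranking determines only membership and tie-breaking. The extension with the
strictly lowest error is accepted (ties go to the earlier candidate in the
ascending-s order); the search stops when the best extension fails to
strictly reduce the current error, and immediately after reaching zero
error, which no extension can improve. Every candidate evaluation costs
`folds` classifier fits; the cumulative fit count is recorded in the trace
together with each evaluation, so any reported cost reconciles with the
trace. Fold assignment is seeded and stratified by class; the seed is a
required, logged parameter because random partitions are otherwise
irreproducible.

Wrapping components: kNN with Euclidean distance (default k = 1 — the
smallest, assumption-free choice, configurable), Gaussian naive Bayes
(per-feature Gaussian likelihoods, appropriate for continuous features), and
a random forest with 20 trees whose bootstraps derive from the classifier
seed. The plain-wrapper baseline (`wrapper_select`) runs the identical SFS
over all features ordered by ascending s, so a pass-through threshold makes
the hybrid and the baseline coincide exactly.

## Evaluation harness

The feature table is split stratified into training and testing parts
(default fraction 0.7 — conventional; the original experimental ratio is not
recoverable). Selection runs on the training part only; held-out error is
reported for the selected subset. `error_curve` scores the top-j ranked
features for j = 1..F and reports the smallest j attaining the minimum CV
error as the optimal feature count. Wall-clock time is logged but the
portable cost metric is the classifier-fit count. A single seeded split is
the default; multi-seed averaging is available by rerunning with different
seeds.

## Synthetic data generator

The generator emulates the study protocol: 5 exercise classes, 21 subjects,
3 repetitions each, durations uniform on 1–4 s, 20 Hz, 6 channels. Each
class × channel template is a Hann-enveloped fundamental plus second
harmonic over a constant offset,
`x(t) = offset + A·env(t)^shape·[sin(2πft+φ) + h·sin(4πft+φ₂)]` — smooth,
bump-like traces of the kind wrist-worn IMUs record during discrete
exercises; biomechanical realism beyond that is a non-goal.

In the default protocol spec, four channels (acc_x/y/z, gyr_x) are
informative: per class the offset steps by 0.2, the amplitude by 0.2 from
0.8, the fundamental frequency by 0.6 Hz from 0.6 Hz, the harmonic ratio by
0.15 from 0.2, and the envelope exponent by 0.25 from 0.5. Each parameter
drives a different feature family (offset → mean; amplitude → spread-type
features and power; frequency → spectral location; harmonic ratio and
envelope exponent → skewness and kurtosis), so between any two classes every
feature type differs in expectation, with mean separations of roughly 2–10
within-class SDs. The remaining two channels (gyr_y, gyr_z) share one
template across classes and act as distractors.

Variability has three seeded components chosen to mimic how repetition data
actually vary: per-subject multiplicative amplitude jitter (SD 0.1) and time
warp (SD 0.05), per-repetition amplitude/timing jitter (SD 0.07) and an
additive per-repetition offset perturbation (SD 0.07), plus i.i.d. Gaussian
sensor noise (SD 0.05 per channel). The per-repetition components matter:
without them the class-conditional feature distributions barely overlap and
a single feature classifies perfectly, which no real IMU dataset does.
Optional outlier spikes (`outlier_rate`, `outlier_scale`) exercise the
median filter. Everything — durations, jitters, noise — is drawn from one
`numpy` generator seeded by the spec, so datasets are bit-reproducible.

What the simulator does **not** model: sensor bias and drift, magnetometer
output, pathological (e.g. post-stroke) movement profiles, inter-exercise
transitions, or label noise. Passing tests on this data therefore
demonstrate that the pipeline recovers planted statistical structure under
realistic repetition-level variability — not that the reported error rates
transfer to clinical recordings.

## Problem sizes and numerical choices

Tests and the acceptance script run the generator at the full protocol scale
(315 windows) for filter-stage and end-to-end checks, and at reduced subject
counts for wrapper-heavy checks, keeping the whole suite fast while
exercising every code path. Greedy-search equivalence is checked against an
independently coded brute-force greedy oracle on 50 small instances (6
candidates, 3 classes). Degenerate inputs (constant windows, constant
features, zero-variance pairs) follow the explicit conventions above instead
of raising, and are flagged with warnings. The Welch degrees-of-freedom
denominator can underflow for near-constant samples; the implementation then
falls back to the pooled value n+m−2.

## Known limitations

- The significance index assumes approximately continuous features;
  heavily discretised features would violate the t test's assumptions.
- SFS is greedy: it cannot recover from early selections, and offers no
  backtracking (no floating variants are implemented).
- With very strong features the wrapper may stop at one or two features;
  the error-vs-feature-count curve is the better tool for studying the
  accuracy/dimensionality trade-off.
- The candidate-set threshold trades coverage against search cost; 0.05 is
  a default, not a universal constant, and the empty-candidate error exists
  precisely because low thresholds can reject everything.
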