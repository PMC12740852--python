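# Methods

This note documents the models, parameter choices, and numerical
conventions behind `saligaze`, and what the synthetic-data tests do and
do not establish about real recordings.

## Fixation detection (I-VT)

Gaze speed is estimated by central differences on positions smoothed
with a short moving average (default 5 samples).  At 150 Hz with ~5 px
measurement jitter, raw point-to-point velocity noise is of the order of
500–1000 px/s — the same magnitude as the saccade threshold — so without
smoothing every fixation fragments; a 5-sample window suppresses the
noise term to ~150 px/s while leaving saccadic velocities (≥ ~1200 px/s
for the smallest planted saccades) detectable.  Reported fixation
positions are means of the raw (unsmoothed) samples in a group.

The velocity threshold defaults to 1000 px/s, i.e. roughly 30°/s for a
60 cm viewing distance on a 31 cm / 1920 px display — the conventional
I-VT cutoff; it is configurable, as is the 150 ms minimum duration.
Invalid samples terminate a group so blinks are never bridged.  A
fixation's duration is its sample span plus one sample period, so a
constant trace of n samples at rate r has duration n/r.  Velocity can
only be computed in pixel units here; an angular-units variant would
need the full display geometry and is deliberately out of scope.

ds/dt follow the convention of means over consecutive pairs: sums over
i = 1…N−1 divided by N−1 (an upper index of N would reference a
non-existent fixation N+1; this is the only well-defined reading).
dt uses onset-to-onset intervals, since each fixation carries a single
timestamp tᵢ.

## Quality control

"Inside the image" is judged by the fixation's mean position against
half-open pixel bounds [0, w) × [0, h).  A trial is excluded when the
outside fraction reaches 30 %; remaining outside fixations are removed
and the metrics re-chained over the survivors.  A subject/condition is
excluded when more than 30 % of its trials are bad by the same 30 %
criterion.  The data-driven alternative — flagging trials more than 2 SD
above the cohort-mean outside fraction — is provided as
`flag_outlier_trials`.

## Saliency metrics

Saliency maps are consumed as numeric grids and min-max rescaled to
[0, 1] per image before any thresholding, so that a threshold θ is
comparable across images regardless of the model's output units
(probability, log-density, …).  Fixation-to-pixel lookup is
nearest-pixel rounding, 0-based, origin top-left; a coordinate that
rounds onto the far edge from inside the half-open bound is clamped to
the last pixel.  A fixation's saliency is a point sample (not a local
average) — the simplest convention, and the one that makes the
closed-form tests exact.  Time bins are half-open [b·w, (b+1)·w) on
fixation onsets, five 600 ms bins for a 3 s trial by default.

## Cluster entropy

Clusters are 8-connected components of {map ≥ θ} (4-connectivity is a
config option).  Entropy uses the natural log by default (`base=2`
available); SE is computed over the in-cluster fixation distribution
only, images with fewer than two clusters are excluded, and an image
whose fixations all miss the clusters contributes a missing value.  The
threshold sweep runs θ = 0.05…0.95 in steps of 0.01 — fine enough to
locate both range bounds.  "The point where the mean cluster count
starts to decline" is operationalized as the first strict decrease after
the global maximum (first occurrence); the lower bound is the smallest θ
with ≥ 70 % multi-cluster images.  Both rules fail loudly (naming the
rule) when a sweep does not contain them.

## EEG

Filtering: zero-phase 4th-order Butterworth band-pass 0.5–90 Hz plus a
narrow notch (Q = 30) at 50 Hz; harmonics of the line frequency lie
above the band edge and are removed by the band-pass.  Epochs are
non-overlapping 2 s segments; epochs whose peak-to-peak amplitude on any
channel exceeds 150 (input units) are rejected — a simple, deterministic
stand-in for interactive artifact screening, sufficient for artifact-free
synthetic data; subjects with fewer than 50 retained epochs are flagged
for exclusion (configurable).

Spectra: multitaper with spectral bandwidth 4 Hz (time-bandwidth product
NW = 4 for 2 s epochs, 2·NW−1 = 7 DPSS tapers, non-adaptive weights),
1–40 Hz at the native 0.5 Hz resolution.  Linear power is averaged
across epochs (and channels, for the summary curve) *before* the log₁₀.
Band aggregation uses half-open interior edges [lo, hi) — a shared bin
belongs to the band whose lower edge it is — with the topmost band
closed at 40 Hz so the declared range is fully covered.

LZc: the analytic-signal magnitude per epoch/channel is z-scored and
median-split (strictly above the median → 1, ties → 0; with even length
and no ties this yields exactly half ones).  The LZ76 exhaustive-history
parse counts phrases, each the shortest prefix of the remaining input
not copyable from the already-seen text (overlapping copies allowed);
the final remainder counts as a phrase.  The raw phrase count is
reported, matching the count-of-substrings definition; an n/log₂(n)
normalization is available as a flag.  A constant signal yields a
degenerate all-zero sequence and a warning.

## Statistics

Wilcoxon signed-rank on HIGH−LOW differences, two-sided; zeros dropped
(Wilcoxon's original rule), ties mid-ranked.  The exact null is used
whenever it is attainable (no zeros, no ties), otherwise the mid-rank
normal approximation.  Effect size is the rank-biserial correlation
(W⁺ − W⁻)/(W⁺ + W⁻).  Uncorrected p-values are always reported;
BH-FDR is applied only within groups where independence is defensible
(the five saliency time bins), not across entropy thresholds.

The frequency-cluster test forms clusters from contiguous runs of
per-frequency one-sample t values beyond the two-sided α = 0.05
threshold (df = n−1), scores them by summed t, and compares each
observed mass against the permutation distribution of the maximum
cluster mass under whole-subject sign flips (p = (1 + #{max ≥ obs}) /
(n_perm + 1), 5000 permutations by default, seed-controlled).  Positive
and negative clusters are formed separately; the null maximum is taken
over both signs, controlling the familywise error across the spectrum.

## Synthetic-data generator

The generator emulates the study conditions the pipeline targets:
800 × 600 px stimuli, 150 Hz gaze over 3 s trials, 500 Hz EEG, paired
LOW/HIGH conditions over a shared image set.

*Maps* are mixtures of five Gaussian bumps with widths 4–8 % of the
image height and near-equal amplitudes (0.9–1.0), min-max rescaled —
several comparably dominant compact regions per scene, mirroring
stimulus sets designed around multiple dominant objects.  Near-equal
amplitudes matter: they are what allows a stronger salience bias to
spread fixations *across* clusters rather than concentrating them on a
single dominant blob.

*Gaze* alternates fixations (gamma-distributed durations, mean 0.28 s,
floor 0.12 s) with ~40 ms linearly interpolated saccades.  Fixation
targets are drawn from a softmax over an every-8th-pixel candidate grid
with log-weight β·saliency − distance/saccade_scale; candidates closer
than 50 px are excluded (a minimum saccade amplitude — sub-50 px jumps
at 40 ms fall below any velocity threshold and would be undetectable in
principle).  Samples get isotropic Gaussian jitter, SD 5 px — below the
detector's resolution so planted fixations are recoverable.  With
probability `outside_rate` (default 0.05) a fixation center is pushed
beyond the image bounds to exercise QC.  The generator does not emulate
pupil dynamics, blinks, smooth pursuit, calibration drift, or realistic
saccade kinematics; gaze-noise parameters are conventions, not estimates
from real trackers — so passing tests certify the pipeline's logic and
statistical calibration, not tracker-specific robustness.

*EEG* is unit-variance 1/f background (exponent 1.0) plus sinusoids at
band centers (2.5, 6, 10, 20, 35 Hz) with per-band amplitudes (LOW:
delta 1.2, theta 1.2, alpha 2.5, beta 0.8, gamma 0.4).  No blink/EMG
artifacts are simulated.

*Planted condition effects* (HIGH vs LOW): saccade_scale 180 → 130 px,
salience bias β 1.2 → 4.5, oscillation amplitudes × 0.72.  Between-
subject variability is lognormal (σ = 0.12) on all three parameters;
subject-by-condition jitter σ = 0.10 (saccade), 0.35 (bias), 0.18
(amplitudes) sets the paired noise floor.  These values were calibrated
once, by simulation, so the recovered metric-level effects land near
one paired SD at n = 20 — measured d: ds ≈ −1.8, mean saliency ≈ +1.7,
in-range cluster entropy ≈ +1.6, band log-power ≈ −1.0, LZc ≈ +1.2,
with N and dt near zero.  The direction pattern (ds down, saliency and
entropy up, broadband power down, complexity up, N/dt null) is the
pipeline's target signature.

## Problem sizes in tests

The statistical acceptance checks use reduced problem sizes chosen as
the package's own trade-off between Monte-Carlo resolution and runtime:
null calibration uses 2000 replicate 10-subject cohorts (two 320 × 240
images per subject for the gaze metrics; 4 s single-channel EEG and 500
permutations for the cluster test), and planted-effect recovery uses 100
replicate 20-subject cohorts over a fixed set of six full-size images
with 12 s of 4-channel EEG.  The per-threshold entropy comparison is
summarized as each subject's mean entropy over the selected θ range.
For the integer-valued metric N the exact Wilcoxon is inherently
conservative (discrete differences produce zeros and ties), so its null
calibration asserts only the upper bound of the rejection rate;
continuous metrics are additionally checked against the exact test's
attainable size (0.0469 at n = 10), computed by enumerating the
signed-rank null.

## Known limitations

- EEG I/O is plain-text CSV (channels × samples with a rate header);
  binary tracker/EEG formats are out of scope.
- Velocity is computed in pixels; angular conversion is left to the
  caller.
- The amplitude-criterion artifact rejection is not a substitute for
  component-based artifact removal on real EEG.
- The generator's candidate-grid softmax gives only approximately
  uniform spatial sampling at β = 0 on bounded images (edge effects of
  the jump kernel); tests of the unbiased case therefore use a flat
  kernel.
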