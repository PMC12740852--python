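# saligaze

Saliency-referenced gaze analysis and resting-state EEG metrics for
paired within-subject designs.

`saligaze` is a tested re-implementation of an analysis pipeline for
studies that compare free-viewing eye-tracking and resting-state EEG
between two within-subject conditions (here labelled **LOW** and
**HIGH**, e.g. two dosing conditions).  It is aimed at cognitive- and
perceptual-neuroscience researchers who want each stage of such an
analysis — fixation detection, data-quality exclusion, saliency-referenced
gaze metrics, cluster entropy, spectral power, signal complexity, and the
paired nonparametric statistics — as a reusable, unit-tested library
rather than a one-off script.  A synthetic-data generator with known
ground truth makes every stage verifiable without access to raw study
data: real inputs (gaze CSVs, saliency maps from a normative model such
as DeepGaze II, EEG recordings) can be dropped in through the same
interfaces.

## What it computes

**Fixation statistics.** Fixations are detected with a velocity-threshold
(I-VT) algorithm (default 1000 px/s ≈ 30°/s, minimum duration 150 ms).
Trials with ≥ 30 % of fixations outside the image are excluded, as are
subjects with bad data on over 30 % of trials; out-of-image fixations are
removed.  Per trial, with fixation positions (xᵢ, yᵢ) and onsets tᵢ:

    N  = number of fixations inside the image
    ds = 1/(N−1) Σᵢ √((xᵢ₊₁−xᵢ)² + (yᵢ₊₁−yᵢ)²)     [px]
    dt = 1/(N−1) Σᵢ (tᵢ₊₁ − tᵢ)                      [s]

averaged over trials to one value per subject and condition.

**Saliency metrics.** Each fixation samples the normalized saliency map
at its pixel; the trial average and its time course over five 600 ms bins
quantify salience preference and its dynamics.

**Cluster entropy.** The saliency map is binarized at a threshold θ,
8-connected supra-threshold clusters are labelled, and the Shannon
entropy of the distribution of fixations across clusters,

    SE = −Σᵢ pᵢ ln pᵢ ,   pᵢ = fixations in cluster i / fixations in any cluster,

measures how evenly salient regions are visited.  The analysis is swept
over θ ∈ [0.05, 0.95]; the reported range runs from the smallest θ at
which ≥ 70 % of images have more than one cluster up to the first decline
of the mean cluster count.

**EEG.** Recordings are band-passed 0.5–90 Hz, notch-filtered at 50 Hz,
cut into 2 s epochs with peak-to-peak artifact rejection, and summarized
as (i) multitaper log₁₀ power spectra over 1–40 Hz at 0.5 Hz resolution,
aggregated into delta/theta/alpha/beta/gamma bands, and (ii) Lempel-Ziv
complexity (LZ76 phrase count) of the median-split-binarized Hilbert
envelope, averaged over epochs per channel.

**Statistics.** Paired two-sided Wilcoxon signed-rank tests with
rank-biserial effect sizes, Benjamini–Hochberg FDR where independence
holds (e.g. across time bins), Pearson/Spearman correlations, and a
cluster-based permutation test across frequencies (sign-flip null, summed
t-mass, 5000 permutations) for the spectral comparison.

## Worked example

```bash
python examples/05_full_pipeline.py
```

runs the whole pipeline on a 10-subject synthetic cohort and prints:

```
              n_pairs       p     rbc direction
metric
ds                 10  0.0020 -1.0000  HIGH<LOW
avg_saliency       10  0.0020  1.0000  HIGH>LOW
power_alpha        10  0.0098 -0.8909  HIGH<LOW
lzc                10  0.0137  0.8545  HIGH>LOW

entropy threshold range [0.05, 0.63], 44 in-range thresholds significant
EEG cluster 1.0-12.0 Hz: reduced power in HIGH, p=0.0070
EEG cluster 18.0-22.0 Hz: reduced power in HIGH, p=0.0430
```

The generator plants shorter saccades, a stronger salience preference,
and weaker oscillations in HIGH; the report recovers exactly that
pattern: mean inter-fixation distance `ds` drops, sampled saliency and
cluster entropy rise, band power falls (with a significant low-frequency
cluster), and envelope complexity `lzc` rises.  `N` and `dt` stay null.
The other scripts in `examples/` demonstrate each stage on its own, and
`saligaze run --config config.yaml` exposes the same pipeline from the
shell.

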