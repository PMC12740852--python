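"""Synthetic gaze and EEG cohorts with known ground truth.

This module generates the three kinds of data the analysis pipeline
consumes — normative saliency maps, fixational gaze traces, and
resting-state EEG — with the statistical structure the analysis assumes,
so that every downstream stage (fixation detection, salience sampling,
cluster entropy, spectral power, Lempel-Ziv complexity, paired statistics)
admits parameter-recovery and calibration tests.

The generative models:

* **Saliency maps** are mixtures of 2-D Gaussian bumps, min-max rescaled
  to [0, 1].
* **Gaze** is an alternating fixation/saccade process.  Fixation centers
  are drawn from a softmax over a down-sampled candidate grid with weight
  ``exp(beta * saliency - distance / saccade_scale)``: ``beta`` (the
  salience-preference bias) pulls fixations toward salient regions,
  ``saccade_scale`` sets the typical inter-fixation jump.  Gaze samples
  are the fixation center plus isotropic Gaussian jitter at the tracker
  rate; saccades are short linear sweeps (~40 ms).  With probability
  ``outside_rate`` a fixation center is displaced beyond the image bounds
  to exercise the QC filters.
* **EEG** is 1/f^slope background noise (unit variance per channel) plus
  band-limited sinusoids at canonical band center frequencies with
  per-band amplitudes.

Conditions differ through :class:`ParamSet`: the default HIGH set plants
a smaller ``saccade_scale``, a larger salience bias, and reduced
oscillation amplitudes relative to LOW — the direction of the effects the
pipeline is designed to detect.  Per-subject and per-subject-by-condition
lognormal parameter jitter makes the planted effects roughly one paired
standard deviation at the recovered-metric level for a 20-subject cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .fixations import GazeRecording
from .salience import SaliencyMap

__all__ = [
    "ParamSet",
    "SynthConfig",
    "GroundTruth",
    "Cohort",
    "make_saliency_map",
    "simulate_gaze_trial",
    "simulate_eeg",
    "simulate_cohort",
    "BAND_CENTERS",
]

#: canonical band center frequencies (Hz) used for planted oscillations
BAND_CENTERS = {"delta": 2.5, "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 35.0}

_DEFAULT_AMPS_LOW = {"delta": 1.2, "theta": 1.2, "alpha": 2.5, "beta": 0.8, "gamma": 0.4}


def _scaled(amps: Mapping[str, float], factor: float) -> dict[str, float]:
    return {k: v * factor for k, v in amps.items()}


@dataclass(frozen=True)
class ParamSet:
    """Condition-level generative parameters.

    ``salience_bias`` (beta) is dimensionless and >= 0; ``saccade_scale``
    is the length scale (px) of the exponential jump kernel, so larger
    values plant longer saccades and a larger recovered ``ds``;
    ``eeg_osc_amp`` holds per-band sinusoid amplitudes in units of the
    (unit-variance) 1/f background.
    """

    salience_bias: float = 1.2
    saccade_scale: float = 180.0
    fixation_dur_mean: float = 0.28
    outside_rate: float = 0.05
    eeg_osc_amp: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_AMPS_LOW))
    eeg_slope: float = 1.0
    jitter_sd: float = 5.0
    min_saccade_px: float = 50.0
    fixation_dur_min: float = 0.12
    fixation_dur_shape: float = 10.0
    saccade_duration: float = 0.040

    def __post_init__(self):
        if self.salience_bias < 0:
            raise ValueError("salience_bias must be >= 0")
        if self.saccade_scale <= 0 or self.fixation_dur_mean <= 0:
            raise ValueError("scales must be positive")
        if not 0.0 <= self.outside_rate <= 1.0:
            raise ValueError("outside_rate must be a probability")
        if any(a < 0 for a in self.eeg_osc_amp.values()):
            raise ValueError("oscillation amplitudes must be >= 0")


def default_condition_params() -> dict[str, ParamSet]:
    """The planted LOW/HIGH study conditions.

    HIGH: shorter saccades (more localized exploration), stronger salience
    preference, and broadband-reduced oscillatory power relative to LOW.
    """
    low = ParamSet()
    high = replace(
        low,
        saccade_scale=130.0,
        salience_bias=4.5,
        eeg_osc_amp=_scaled(_DEFAULT_AMPS_LOW, 0.72),
    )
    return {"LOW": low, "HIGH": high}


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level configuration; defaults mirror the study conditions:

    800 x 600 px stimuli, 150 Hz gaze sampling over 3 s trials, 24-channel
    EEG at 500 Hz, the same image set in both conditions.
    """

    seed: int = 0
    n_subjects: int = 20
    n_images: int = 20
    image_size: tuple[int, int] = (800, 600)
    gaze_rate: float = 150.0
    trial_duration: float = 3.0
    eeg_rate: float = 500.0
    eeg_channels: int = 24
    eeg_duration: float = 60.0
    n_blobs: int = 5
    condition_params: Mapping[str, ParamSet] = field(default_factory=default_condition_params)
    subject_sd: float = 0.12         # between-subject lognormal sigma
    # subject-by-condition lognormal sigmas (per effect-carrying parameter)
    within_sd_saccade: float = 0.10
    within_sd_bias: float = 0.35
    within_sd_amp: float = 0.18
    candidate_stride: int = 8

    def __post_init__(self):
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError("image size must be positive")
        if self.gaze_rate <= 0 or self.eeg_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if self.n_subjects < 1 or self.n_images < 1:
            raise ValueError("need at least one subject and one image")
        if set(self.condition_params) != {"LOW", "HIGH"}:
            raise ValueError("condition_params must have exactly LOW and HIGH")


@dataclass(frozen=True)
class PlantedFixation:
    x: float
    y: float
    onset: float
    duration: float
    outside: bool


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    fixations: dict            # (subject, condition, image) -> list[PlantedFixation]
    subject_params: dict       # (subject, condition) -> ParamSet
    condition_params: dict     # condition -> base ParamSet
    effect_sizes: dict


@dataclass
class Cohort:
    config: SynthConfig
    maps: list
    gaze: dict                 # (subject, condition, image) -> GazeRecording
    eeg: dict                  # (subject, condition) -> np.ndarray (channels x samples)
    ground_truth: GroundTruth

    @property
    def subjects(self) -> list:
        return list(range(self.config.n_subjects))


def make_saliency_map(
    seed,
    image_size: tuple[int, int] = (800, 600),
    n_blobs: int = 5,
    centers: np.ndarray | None = None,
    sigma_range: tuple[float, float] = (0.04, 0.08),
    amp_range: tuple[float, float] = (0.9, 1.0),
) -> SaliencyMap:
    """Mixture of 2-D Gaussian bumps, min-max rescaled to [0, 1].

    ``centers`` (``(n_blobs, 2)`` array of (x, y) px) pins the bump
    locations for constructed test maps; by default they are drawn
    uniformly inside the central 70 % of the image.  Bump widths are drawn
    from ``sigma_range`` as fractions of the smaller image dimension.
    """
    w, h = image_size
    if w <= 0 or h <= 0:
        raise ValueError("image size must be positive")
    if n_blobs < 1:
        raise ValueError("need at least one blob")
    rng = np.random.default_rng(seed)
    if centers is None:
        cx = rng.uniform(0.15 * w, 0.85 * w, n_blobs)
        cy = rng.uniform(0.15 * h, 0.85 * h, n_blobs)
    else:
        centers = np.asarray(centers, dtype=float).reshape(-1, 2)
        if len(centers) != n_blobs:
            raise ValueError("centers must match n_blobs")
        cx, cy = centers[:, 0], centers[:, 1]
    smin = min(w, h)
    sig = rng.uniform(sigma_range[0] * smin, sigma_range[1] * smin, n_blobs)
    amp = rng.uniform(amp_range[0], amp_range[1], n_blobs)

    xs = np.arange(w)
    ys = np.arange(h)[:, None]
    grid = np.zeros((h, w))
    for j in range(n_blobs):
        gx = np.exp(-0.5 * ((xs - cx[j]) / sig[j]) ** 2)
        gy = np.exp(-0.5 * ((ys - cy[j]) / sig[j]) ** 2)
        grid += amp[j] * gy * gx
    return SaliencyMap(grid).normalized()


class _CandidateGrid:
    """Down-sampled candidate locations with cached saliency values."""

    def __init__(self, smap: SaliencyMap, stride: int):
        h, w = smap.grid.shape
        xs = np.arange(stride // 2, w, stride)
        ys = np.arange(stride // 2, h, stride)
        gx, gy = np.meshgrid(xs, ys)
        self.xy = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
        self.sal = smap.grid[gy.ravel(), gx.ravel()]


def _draw_center(
    rng: np.random.Generator,
    cand: _CandidateGrid,
    beta: float,
    prev: np.ndarray | None,
    saccade_scale: float,
    min_saccade_px: float,
) -> np.ndarray:
    logw = beta * cand.sal
    if prev is not None:
        d = np.hypot(cand.xy[:, 0] - prev[0], cand.xy[:, 1] - prev[1])
        logw = logw - d / saccade_scale
        feasible = d >= min_saccade_px
        if feasible.any():
            logw = np.where(feasible, logw, -np.inf)
    w = np.exp(logw - logw.max())
    cw = np.cumsum(w)
    idx = min(np.searchsorted(cw, rng.random() * cw[-1]), len(cw) - 1)
    return cand.xy[idx].copy()


def simulate_gaze_trial(
    smap: SaliencyMap,
    params: ParamSet,
    seed,
    rate: float = 150.0,
    trial_duration: float = 3.0,
    candidate_stride: int = 8,
) -> tuple[GazeRecording, list[PlantedFixation]]:
    """Simulate one free-viewing trial and return its ground truth.

    The trial alternates fixations (gamma-distributed durations, mean
    ``fixation_dur_mean``) with ~40 ms saccades.  Gaze samples at ``rate``
    are the scheduled trajectory plus isotropic Gaussian jitter of SD
    ``params.jitter_sd``.  Deterministic given ``seed``.
    """
    if trial_duration < params.fixation_dur_min:
        raise ValueError("trial too short for a single minimal fixation")
    rng = np.random.default_rng(seed)
    cand = _CandidateGrid(smap, candidate_stride)
    w, h = smap.width, smap.height

    # schedule fixations and saccades until the trial is filled
    planted: list[PlantedFixation] = []
    segments = []  # (t0, t1, kind, p_from, p_to)
    t = 0.0
    prev = None
    while t < trial_duration - 1e-9:
        center = _draw_center(rng, cand, params.salience_bias, prev,
                              params.saccade_scale, params.min_saccade_px)
        outside = False
        if rng.random() < params.outside_rate:
            outside = True
            side = rng.integers(4)
            off = rng.uniform(10.0, 0.15 * max(w, h))
            if side == 0:
                center[0] = -off
            elif side == 1:
                center[0] = w - 1 + off
            elif side == 2:
                center[1] = -off
            else:
                center[1] = h - 1 + off
        if prev is not None:
            t_sac = min(t + params.saccade_duration, trial_duration)
            segments.append((t, t_sac, "saccade", prev, center))
            t = t_sac
            if t >= trial_duration - 1e-9:
                break
        shape = params.fixation_dur_shape
        dur = rng.gamma(shape, params.fixation_dur_mean / shape)
        dur = max(dur, params.fixation_dur_min)
        t_end = min(t + dur, trial_duration)
        segments.append((t, t_end, "fixation", center, center))
        planted.append(
            PlantedFixation(x=float(center[0]), y=float(center[1]),
                            onset=float(t), duration=float(t_end - t),
                            outside=outside)
        )
        t = t_end
        prev = center

    # sample the scheduled trajectory on the uniform time grid
    n = int(round(trial_duration * rate))
    ts = np.arange(n) / rate
    bounds = np.array([s[0] for s in segments] + [trial_duration])
    seg_idx = np.clip(np.searchsorted(bounds, ts, side="right") - 1, 0, len(segments) - 1)
    pos = np.empty((n, 2))
    for i, (t0, t1, kind, p0, p1) in enumerate(segments):
        sel = seg_idx == i
        if not sel.any():
            continue
        if kind == "fixation":
            pos[sel] = p0
        else:
            frac = (ts[sel] - t0) / max(t1 - t0, 1e-12)
            pos[sel] = np.asarray(p0) + np.outer(frac, np.asarray(p1) - np.asarray(p0))
    pos += rng.normal(0.0, params.jitter_sd, (n, 2))

    rec = GazeRecording(
        t=ts, x=pos[:, 0], y=pos[:, 1], valid=np.ones(n, dtype=bool),
        rate=rate, screen=(w, h),
    )
    return rec, planted


def simulate_eeg(
    params: ParamSet,
    duration_s: float,
    seed,
    rate: float = 500.0,
    n_channels: int = 24,
    band_centers: Mapping[str, float] = BAND_CENTERS,
) -> np.ndarray:
    """Multichannel EEG: unit-variance 1/f^slope noise + band sinusoids.

    Each channel gets independent background noise and an independent
    random phase per oscillation.  Returns a ``(n_channels, n_samples)``
    array; deterministic given ``seed``.
    """
    if duration_s < 4.0:
        raise ValueError("EEG duration must be at least 4 s")
    if n_channels < 1:
        raise ValueError("need at least one channel")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate

    white = rng.standard_normal((n_channels, n))
    if params.eeg_slope != 0.0:
        spec = np.fft.rfft(white, axis=1)
        f = np.fft.rfftfreq(n, 1.0 / rate)
        scale = np.ones_like(f)
        nzf = f > 0
        scale[nzf] = f[nzf] ** (-params.eeg_slope / 2.0)
        scale[0] = 0.0
        shaped = np.fft.irfft(spec * scale, n=n, axis=1)
        sd = shaped.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        signal = shaped / sd
    else:
        signal = white

    for band, amp in params.eeg_osc_amp.items():
        if amp == 0.0:
            continue
        f0 = band_centers[band]
        phases = rng.uniform(0, 2 * np.pi, n_channels)
        signal = signal + amp * np.sin(2 * np.pi * f0 * t[None, :] + phases[:, None])
    return signal


def _jittered(base: ParamSet, rng: np.random.Generator,
              subj_eps: np.ndarray, sigma_w: tuple[float, float, float]) -> ParamSet:
    """Apply lognormal subject (shared across conditions) and
    subject-by-condition jitter to the effect-carrying parameters."""
    w_eps = rng.normal(0.0, 1.0, 3) * np.asarray(sigma_w)
    return replace(
        base,
        saccade_scale=base.saccade_scale * math.exp(subj_eps[0] + w_eps[0]),
        salience_bias=base.salience_bias * math.exp(subj_eps[1] + w_eps[1]),
        eeg_osc_amp=_scaled(base.eeg_osc_amp, math.exp(subj_eps[2] + w_eps[2])),
    )


def simulate_cohort(config: SynthConfig, maps=None) -> Cohort:
    """Paired per-subject LOW/HIGH datasets over a shared image set.

    Every subject sees the same saliency maps in both conditions; the
    realized per-subject-condition parameter sets and all planted fixations
    are returned in the ground truth.  Deterministic given ``config.seed``.
    Pass ``maps`` to reuse a fixed stimulus set (e.g. across replicate
    cohorts of new subjects); by default maps are generated from the seed.
    """
    if config.n_subjects < 2:
        raise ValueError("a paired cohort needs at least 2 subjects")
    root = np.random.SeedSequence(config.seed)
    ss_maps, ss_subj = root.spawn(2)

    if maps is None:
        maps = [
            make_saliency_map(s, config.image_size, config.n_blobs)
            for s in ss_maps.spawn(config.n_images)
        ]
    else:
        maps = list(maps)
        if len(maps) != config.n_images:
            raise ValueError("supplied maps do not match n_images")
        if maps[0].grid.shape != (config.image_size[1], config.image_size[0]):
            raise ValueError("supplied maps do not match image_size")

    gaze: dict = {}
    eeg: dict = {}
    fixations: dict = {}
    subject_params: dict = {}

    for subj, ss in enumerate(ss_subj.spawn(config.n_subjects)):
        ss_param, ss_trials, ss_eeg = ss.spawn(3)
        prng = np.random.default_rng(ss_param)
        subj_eps = prng.normal(0.0, config.subject_sd, 3)
        trial_seeds = ss_trials.spawn(2 * config.n_images)
        eeg_seeds = ss_eeg.spawn(2)
        for c, cond in enumerate(("LOW", "HIGH")):
            params = _jittered(
                config.condition_params[cond], prng, subj_eps,
                (config.within_sd_saccade, config.within_sd_bias,
                 config.within_sd_amp))
            subject_params[(subj, cond)] = params
            for img in range(config.n_images):
                rec, planted = simulate_gaze_trial(
                    maps[img], params, trial_seeds[c * config.n_images + img],
                    rate=config.gaze_rate, trial_duration=config.trial_duration,
                    candidate_stride=config.candidate_stride,
                )
                gaze[(subj, cond, img)] = rec
                fixations[(subj, cond, img)] = planted
            eeg[(subj, cond)] = simulate_eeg(
                params, config.eeg_duration, eeg_seeds[c],
                rate=config.eeg_rate, n_channels=config.eeg_channels,
            )

    base = config.condition_params
    rt2 = math.sqrt(2.0)
    effect_sizes = {
        "log_saccade_scale": math.log(
            base["HIGH"].saccade_scale / base["LOW"].saccade_scale
        ) / (rt2 * config.within_sd_saccade),
        "log_salience_bias": math.log(
            max(base["HIGH"].salience_bias, 1e-12) / max(base["LOW"].salience_bias, 1e-12)
        ) / (rt2 * config.within_sd_bias),
        "log_osc_amp": math.log(
            (sum(base["HIGH"].eeg_osc_amp.values()) + 1e-12)
            / (sum(base["LOW"].eeg_osc_amp.values()) + 1e-12)
        ) / (rt2 * config.within_sd_amp),
    }
    gt = GroundTruth(
        fixations=fixations,
        subject_params=subject_params,
        condition_params=dict(base),
        effect_sizes=effect_sizes,
    )
    return Cohort(config=config, maps=maps, gaze=gaze, eeg=eeg, ground_truth=gt)
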