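"""End-to-end orchestration: synth -> fixations -> salience -> eeg -> stats.

:func:`run_full` drives the whole analysis from a single
:class:`RunConfig` — either on a synthetic cohort (no external inputs) or
on user-supplied gaze/map/EEG files — and writes a self-describing results
bundle: every intermediate table, the statistical report, a config
snapshot, and a log.  One seed governs the run; it is fanned out
deterministically to the generator and to every stochastic test.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .eeg import BANDS, band_aggregate, lzc, multitaper_psd, preprocess
from .fixations import (aggregate_subject, detect_fixations, subject_qc,
                        subject_metrics_frame, trial_qc)
from .salience import (sample_saliency, select_threshold_range,
                       threshold_sweep, time_binned_saliency)
from .stats import cluster_permutation_freq, condition_compare_report
from .synth import SynthConfig, simulate_cohort

logger = logging.getLogger(__name__)

CONDITIONS = ("LOW", "HIGH")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All run parameters; recorded verbatim into the output bundle."""

    mode: str = "synthetic"            # "synthetic" | "data"
    seed: int = 0
    out_dir: str = "saligaze_out"
    # synthetic-cohort size (defaults are deliberately modest; the study
    # conditions themselves live in SynthConfig/ParamSet defaults)
    n_subjects: int = 20
    n_images: int = 12
    image_size: tuple = (800, 600)
    gaze_rate: float = 150.0
    trial_duration: float = 3.0
    eeg_rate: float = 500.0
    eeg_channels: int = 24
    eeg_duration: float = 60.0
    # data-mode inputs
    gaze_dir: str | None = None
    maps_dir: str | None = None
    eeg_dir: str | None = None
    # fixation detection
    velocity_threshold: float = 1000.0
    min_duration: float = 0.150
    # salience / entropy
    n_bins: int = 5
    theta_lo: float = 0.05
    theta_hi: float = 0.95
    theta_step: float = 0.01
    min_fraction: float = 0.70
    # eeg
    epoch_length: float = 2.0
    reject_ptp: float = 150.0
    min_epochs: int = 50
    psd_bandwidth: float = 4.0
    # stats
    n_perm: int = 5000
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = sio.read_yaml(path) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.image_size, list):
            cfg.image_size = tuple(cfg.image_size)
        return cfg

    @property
    def theta_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.theta_lo, self.theta_hi + 1e-9, self.theta_step),
            6,
        )


@dataclass
class ResultsBundle:
    config: RunConfig
    subject_metrics: pd.DataFrame
    trial_table: pd.DataFrame
    sweep: pd.DataFrame
    entropy: pd.DataFrame
    threshold_range: object
    spectra: pd.DataFrame
    band_power: pd.DataFrame
    lzc_table: pd.DataFrame
    report: pd.DataFrame
    cluster_result: object
    significant_thresholds: list
    out_dir: Path


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage-named rethrow
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise StageError(name, exc) from exc
            logger.info("stage %s: done", name)
            return out
        return wrapper
    return deco


@_stage("synth")
def _load_or_simulate(cfg: RunConfig, seed: int):
    """Return (maps, gaze, eeg_raw) keyed like a synthetic Cohort."""
    if cfg.mode == "synthetic":
        sc = SynthConfig(
            seed=seed, n_subjects=cfg.n_subjects, n_images=cfg.n_images,
            image_size=tuple(cfg.image_size), gaze_rate=cfg.gaze_rate,
            trial_duration=cfg.trial_duration, eeg_rate=cfg.eeg_rate,
            eeg_channels=cfg.eeg_channels, eeg_duration=cfg.eeg_duration,
        )
        cohort = simulate_cohort(sc)
        return cohort.maps, cohort.gaze, cohort.eeg, list(range(sc.n_subjects))
    if cfg.mode != "data":
        raise ValueError(f"unknown mode {cfg.mode!r}")

    maps_dir = Path(cfg.maps_dir)
    gaze_dir = Path(cfg.gaze_dir)
    maps = []
    kept_images = []
    for img in range(cfg.n_images):
        p = maps_dir / f"map_{img:03d}.txt"
        if not p.exists():
            logger.warning("missing saliency map %s; skipping image %d", p, img)
            continue
        maps.append(sio.read_map_text(p).normalized())
        kept_images.append(img)

    gaze = {}
    subjects = set()
    for path in sorted(gaze_dir.glob("gaze_s*_*.csv")):
        stem = path.stem.split("_")          # gaze, s<subj>, <cond>
        subj, cond = int(stem[1][1:]), stem[2]
        subjects.add(subj)
        trials = sio.read_gaze_csv(path, rate=cfg.gaze_rate,
                                   screen=tuple(cfg.image_size))
        for trial_id, rec in trials.items():
            if int(trial_id) in kept_images:
                gaze[(subj, cond, kept_images.index(int(trial_id)))] = rec

    eeg_raw = {}
    if cfg.eeg_dir:
        for path in sorted(Path(cfg.eeg_dir).glob("eeg_s*_*.csv")):
            stem = path.stem.split("_")
            subj, cond = int(stem[1][1:]), stem[2]
            signal, rate, _ = sio.read_eeg_csv(path)
            if abs(rate - cfg.eeg_rate) > 1e-6:
                raise ValueError(f"{path}: rate {rate} != configured {cfg.eeg_rate}")
            eeg_raw[(subj, cond)] = signal
    return maps, gaze, eeg_raw, sorted(subjects)


@_stage("fixations")
def _fixation_stage(cfg: RunConfig, maps, gaze, subjects):
    """Detect, QC, and summarize fixations; keep in-image fixations."""
    rect = (0.0, 0.0, float(cfg.image_size[0]), float(cfg.image_size[1]))
    trial_rows = []
    inside = {}            # (subj, cond, img) -> list[Fixation] inside image
    subj_metrics = []
    qc_flags = {}
    for subj in subjects:
        for cond in CONDITIONS:
            trials = []
            for img in range(len(maps)):
                rec = gaze.get((subj, cond, img))
                if rec is None:
                    continue
                fx = detect_fixations(rec, cfg.velocity_threshold, cfg.min_duration)
                tm = trial_qc(fx, rect)
                trials.append(tm)
                if tm.retained:
                    inside[(subj, cond, img)] = [
                        f for f in fx
                        if rect[0] <= f.x < rect[2] and rect[1] <= f.y < rect[3]
                    ]
                trial_rows.append({
                    "subject": subj, "condition": cond, "image": img,
                    "N": tm.N, "ds": tm.ds, "dt": tm.dt,
                    "frac_outside": tm.frac_outside, "retained": tm.retained,
                })
            qc_flags[(subj, cond)] = subject_qc(trials)
            if not qc_flags[(subj, cond)]:
                logger.warning("subject %s/%s failed QC; excluded", subj, cond)
                continue
            subj_metrics.append(aggregate_subject(trials, subj, cond))
    return (subject_metrics_frame(subj_metrics), pd.DataFrame(trial_rows),
            inside, qc_flags)


@_stage("salience")
def _salience_stage(cfg: RunConfig, maps, inside, subjects):
    sal_rows = []
    fixation_sets = {}
    for subj in subjects:
        for cond in CONDITIONS:
            per_image = []
            for img in range(len(maps)):
                fx = inside.get((subj, cond, img), [])
                per_image.append(fx)
                if not fx:
                    continue
                vals = sample_saliency(fx, maps[img])
                bins = time_binned_saliency(fx, maps[img], cfg.trial_duration,
                                            cfg.n_bins)
                row = {"subject": subj, "condition": cond, "image": img,
                       "avg_saliency": float(vals.mean())}
                row.update({f"saliency_t{b + 1}": bins[b] for b in range(cfg.n_bins)})
                sal_rows.append(row)
            fixation_sets[(subj, cond)] = per_image
    sal_df = pd.DataFrame(sal_rows)
    sweep, entropy = threshold_sweep(maps, fixation_sets, cfg.theta_grid)
    entropy[["subject", "condition"]] = pd.DataFrame(
        entropy["subject"].tolist(), index=entropy.index
    )
    trange = select_threshold_range(sweep, cfg.min_fraction)
    return sal_df, sweep, entropy, trange


@_stage("eeg")
def _eeg_stage(cfg: RunConfig, eeg_raw):
    spec_rows = []
    band_rows = []
    lzc_rows = []
    curves = {}
    for (subj, cond), raw in eeg_raw.items():
        ep = preprocess(raw, cfg.eeg_rate, epoch_length=cfg.epoch_length,
                        reject_ptp=cfg.reject_ptp)
        if ep.n_epochs < cfg.min_epochs:
            logger.warning("subject %s/%s: only %d valid epochs (<%d); excluded",
                           subj, cond, ep.n_epochs, cfg.min_epochs)
            continue
        spec = multitaper_psd(ep, bandwidth=cfg.psd_bandwidth)
        curves[(subj, cond)] = spec.avg_log_power
        freqs = spec.freqs
        spec_rows.extend(
            {"subject": subj, "condition": cond, "freq": float(f),
             "avg_log_power": float(v)}
            for f, v in zip(spec.freqs, spec.avg_log_power)
        )
        bp = band_aggregate(spec)
        row = {"subject": subj, "condition": cond}
        row.update({b: float(v) for b, v in bp.channel_avg.items()})
        band_rows.append(row)
        lz = lzc(ep)
        lzc_rows.append({"subject": subj, "condition": cond,
                         "lzc": lz.mean})
    spectra = pd.DataFrame(spec_rows)
    return spectra, pd.DataFrame(band_rows), pd.DataFrame(lzc_rows), curves


@_stage("stats")
def _stats_stage(cfg: RunConfig, subject_metrics, sal_df, entropy, trange,
                 band_df, lzc_df, curves, seed: int):
    tidy = []
    for metric in ("N", "ds", "dt", "frac_outside"):
        for _, r in subject_metrics.iterrows():
            tidy.append({"subject": r["subject"], "condition": r["condition"],
                         "metric": metric, "value": r[metric]})
    bin_cols = [f"saliency_t{b + 1}" for b in range(cfg.n_bins)]
    if len(sal_df):
        subj_sal = sal_df.groupby(["subject", "condition"], as_index=False).mean(
            numeric_only=True)
        for _, r in subj_sal.iterrows():
            tidy.append({"subject": r["subject"], "condition": r["condition"],
                         "metric": "avg_saliency", "value": r["avg_saliency"]})
            for c in bin_cols:
                tidy.append({"subject": r["subject"], "condition": r["condition"],
                             "metric": c, "value": r[c]})
    if len(band_df):
        for _, r in band_df.iterrows():
            for b in BANDS:
                tidy.append({"subject": r["subject"], "condition": r["condition"],
                             "metric": f"power_{b}", "value": r[b]})
    if len(lzc_df):
        for _, r in lzc_df.iterrows():
            tidy.append({"subject": r["subject"], "condition": r["condition"],
                         "metric": "lzc", "value": r["lzc"]})
    report = condition_compare_report(pd.DataFrame(tidy),
                                      fdr_groups=[bin_cols], alpha=cfg.alpha)

    # entropy per threshold inside the selected range (uncorrected by design)
    sig_thetas = []
    if trange is not None and len(entropy):
        in_range = entropy[(entropy["theta"] >= trange.lower)
                           & (entropy["theta"] <= trange.upper)]
        ent_tidy = in_range.rename(columns={"mean_se": "value"})
        ent_tidy = ent_tidy.assign(metric=ent_tidy["theta"].map(lambda t: f"SE@{t:.2f}"))
        ent_report = condition_compare_report(
            ent_tidy[["subject", "condition", "metric", "value"]])
        ent_report["theta"] = ent_report["metric"].str.slice(3).astype(float)
        sig = ent_report[(ent_report["p"] < cfg.alpha)
                         & (ent_report["direction"] == "HIGH>LOW")]
        sig_thetas = sorted(sig["theta"].tolist())
        report = pd.concat([report, ent_report.drop(columns="theta")],
                           ignore_index=True)

    cluster_res = None
    if curves:
        subjects = sorted({s for s, _ in curves})
        paired = [s for s in subjects
                  if (s, "LOW") in curves and (s, "HIGH") in curves]
        if len(paired) >= 2:
            high = np.array([curves[(s, "HIGH")] for s in paired])
            low = np.array([curves[(s, "LOW")] for s in paired])
            n_f = high.shape[1]
            freqs = np.linspace(1.0, 40.0, n_f)
            cluster_res = cluster_permutation_freq(
                high, low, freqs, n_perm=cfg.n_perm, cluster_alpha=cfg.alpha,
                seed=seed)
    return report, sig_thetas, cluster_res


def run_full(config: RunConfig) -> ResultsBundle:
    """Run the full analysis and write the results bundle to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("saligaze")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        sio.write_yaml(out / "config.yaml", asdict(config))
        ss = np.random.SeedSequence(config.seed)
        synth_seed, stats_seed = (int(s.generate_state(1)[0] % (2**31))
                                  for s in ss.spawn(2))

        maps, gaze, eeg_raw, subjects = _load_or_simulate(config, synth_seed)
        subject_metrics, trial_table, inside, qc_flags = _fixation_stage(
            config, maps, gaze, subjects)
        subject_metrics.to_csv(out / "subject_metrics.csv", index=False)
        trial_table.to_csv(out / "trial_metrics.csv", index=False)
        sio.write_json(out / "qc_report.json", {
            f"{subj}/{cond}": bool(ok) for (subj, cond), ok in qc_flags.items()
        })

        sal_df, sweep, entropy, trange = _salience_stage(
            config, maps, inside, subjects)
        sal_df.to_csv(out / "saliency.csv", index=False)
        sweep.to_csv(out / "threshold_sweep.csv", index=False)
        entropy.to_csv(out / "entropy.csv", index=False)

        spectra, band_df, lzc_df, curves = _eeg_stage(config, eeg_raw)
        spectra.to_csv(out / "spectra.csv", index=False)
        band_df.to_csv(out / "band_power.csv", index=False)
        lzc_df.to_csv(out / "lzc.csv", index=False)

        report, sig_thetas, cluster_res = _stats_stage(
            config, subject_metrics, sal_df, entropy, trange, band_df,
            lzc_df, curves, stats_seed)
        report.to_csv(out / "stats_report.csv", index=False)
        sio.write_json(out / "threshold_range.json", {
            "lower": trange.lower, "upper": trange.upper,
            "significant_thresholds": sig_thetas,
        })
        if cluster_res is not None:
            sio.write_json(out / "clusters.json", {
                "n_permutations": cluster_res.n_permutations,
                "clusters": list(cluster_res.clusters),
            })
        return ResultsBundle(
            config=config, subject_metrics=subject_metrics,
            trial_table=trial_table, sweep=sweep, entropy=entropy,
            threshold_range=trange, spectra=spectra, band_power=band_df,
            lzc_table=lzc_df, report=report, cluster_result=cluster_res,
            significant_thresholds=sig_thetas, out_dir=out,
        )
    finally:
        root.removeHandler(handler)
        handler.close()
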