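"""Plain-text readers and writers for the pipeline's data formats.

Gaze trials travel as CSV (``trial_id, t_s, x_px, y_px, valid``), saliency
maps as whitespace-delimited matrix text or 16-bit grayscale PNG, EEG as
CSV (one row per channel, with a ``# rate=<Hz>`` header line), ground
truth as JSON, and run configuration as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .fixations import GazeRecording
from .salience import SaliencyMap

__all__ = [
    "write_gaze_csv", "read_gaze_csv",
    "write_map_text", "read_map_text", "write_map_png", "read_map_png",
    "write_eeg_csv", "read_eeg_csv",
    "write_json", "read_json",
    "write_yaml", "read_yaml",
]

_PNG_MAX = 65535


def write_gaze_csv(path, recordings: Mapping[object, GazeRecording]) -> None:
    """Write one or more trials (keyed by trial id) to a single CSV."""
    frames = []
    for trial_id, rec in recordings.items():
        frames.append(pd.DataFrame({
            "trial_id": trial_id,
            "t_s": rec.t,
            "x_px": rec.x,
            "y_px": rec.y,
            "valid": rec.valid.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_gaze_csv(path, rate: float, screen: tuple[int, int],
                  image_rect=None) -> dict[object, GazeRecording]:
    df = pd.read_csv(path)
    out = {}
    for trial_id, g in df.groupby("trial_id", sort=False):
        out[trial_id] = GazeRecording(
            t=g["t_s"].to_numpy(), x=g["x_px"].to_numpy(), y=g["y_px"].to_numpy(),
            valid=g["valid"].to_numpy().astype(bool),
            rate=rate, screen=screen, image_rect=image_rect,
        )
    return out


def write_map_text(path, smap: SaliencyMap) -> None:
    np.savetxt(path, smap.grid, fmt="%.6g")


def read_map_text(path) -> SaliencyMap:
    return SaliencyMap(np.loadtxt(path))


def write_map_png(path, smap: SaliencyMap) -> None:
    """16-bit grayscale PNG; values are min-max scaled onto the full range."""
    from PIL import Image

    g = smap.normalized().grid
    arr = np.round(g * _PNG_MAX).astype(np.uint16)
    Image.fromarray(arr).save(path)


def read_map_png(path) -> SaliencyMap:
    from PIL import Image

    arr = np.asarray(Image.open(path), dtype=float) / _PNG_MAX
    return SaliencyMap(arr)


def write_eeg_csv(path, signal: np.ndarray, rate: float, ch_names=None) -> None:
    signal = np.atleast_2d(signal)
    names = ch_names or [f"ch{i:02d}" for i in range(signal.shape[0])]
    with open(path, "w") as fh:
        fh.write(f"# rate={rate}\n")
        fh.write(f"# channels={','.join(names)}\n")
        np.savetxt(fh, signal, fmt="%.6g", delimiter=",")


def read_eeg_csv(path) -> tuple[np.ndarray, float, list[str]]:
    rate = None
    names = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "rate":
                rate = float(val)
            elif key.strip() == "channels":
                names = val.split(",")
    if rate is None:
        raise ValueError(f"{path}: missing '# rate=' header")
    signal = np.loadtxt(path, delimiter=",", comments="#")
    signal = np.atleast_2d(signal)
    if names is None:
        names = [f"ch{i:02d}" for i in range(signal.shape[0])]
    return signal, rate, names


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def read_json(path):
    return json.loads(Path(path).read_text())


def write_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonable(obj), sort_keys=False))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
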