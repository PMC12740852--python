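"""Saliency-referenced gaze metrics and cluster entropy.

Fixations are mapped onto a normative per-pixel saliency map (supplied as
input, e.g. the output of a deep saliency model rescaled to [0, 1]); this
module computes trial/subject average sampled saliency, its time course
over equal viewing-time bins, and the Shannon entropy of the distribution
of fixations across connected high-salience clusters, swept over a range of
binarization thresholds with the two-rule range-selection procedure
(70 %-multicluster lower bound, first decline of mean cluster count upper
bound).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as _sk_label

from .fixations import Fixation

__all__ = [
    "SaliencyMap",
    "ClusterLabeling",
    "EntropyResult",
    "ThresholdRange",
    "sample_saliency",
    "time_binned_saliency",
    "clusterize",
    "cluster_entropy",
    "precompute_labelings",
    "sweep_from_labelings",
    "entropy_from_labelings",
    "threshold_sweep",
    "select_threshold_range",
]

DEFAULT_THETA_GRID = np.round(np.arange(0.05, 0.95 + 1e-9, 0.01), 2)


@dataclass(frozen=True)
class SaliencyMap:
    """Per-pixel salience on the image grid (row 0 = top of the image).

    ``grid`` is indexed ``[row, col]`` = ``[y, x]``.  Analyses assume a map
    normalized to min 0 / max 1; use :meth:`normalized` on raw model
    outputs (e.g. log-densities) before thresholding so that thresholds are
    comparable across images.
    """

    grid: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2 or g.size == 0:
            raise ValueError("saliency map must be a non-empty 2-D grid")
        if not np.all(np.isfinite(g)):
            raise ValueError("saliency map must be finite")
        object.__setattr__(self, "grid", g)

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    def normalized(self) -> "SaliencyMap":
        """Min-max rescale to [0, 1]; a constant map rescales to all zeros."""
        g = self.grid
        lo, hi = g.min(), g.max()
        if hi == lo:
            return SaliencyMap(np.zeros_like(g))
        return SaliencyMap((g - lo) / (hi - lo))


@dataclass(frozen=True)
class ClusterLabeling:
    """Connected components of the supra-threshold set {salience >= theta}."""

    threshold: float
    labels: np.ndarray
    k: int


@dataclass(frozen=True)
class EntropyResult:
    se: float
    proportions: np.ndarray
    n_in_clusters: int


@dataclass(frozen=True)
class ThresholdRange:
    lower: float
    upper: float
    significant_thresholds: tuple = ()


def _pixel_indices(xy: np.ndarray, width: int, height: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-pixel lookup, 0-based, origin top-left, half-open bounds.

    Coordinates must lie in [0, width) x [0, height); after rounding, an
    index landing exactly on the far edge is clamped to the last pixel.
    """
    x = xy[:, 0]
    y = xy[:, 1]
    if np.any((x < 0) | (x >= width) | (y < 0) | (y >= height)):
        raise ValueError("fixation outside the saliency grid; apply QC first")
    ix = np.minimum(np.rint(x).astype(int), width - 1)
    iy = np.minimum(np.rint(y).astype(int), height - 1)
    return ix, iy


def _as_xy(fixations) -> np.ndarray:
    if isinstance(fixations, np.ndarray):
        return fixations.reshape(-1, 2).astype(float)
    return np.array([[f.x, f.y] for f in fixations], dtype=float).reshape(-1, 2)


def sample_saliency(fixations, smap: SaliencyMap) -> np.ndarray:
    """Map each fixation to the saliency value at its (rounded) pixel.

    Accepts a sequence of :class:`~saligaze.fixations.Fixation` or an
    ``(n, 2)`` array of ``(x, y)`` positions.  The trial-average saliency is
    simply ``sample_saliency(...).mean()``.
    """
    xy = _as_xy(fixations)
    if xy.size == 0:
        return np.empty(0)
    ix, iy = _pixel_indices(xy, smap.width, smap.height)
    return smap.grid[iy, ix]


def time_binned_saliency(
    fixations: Sequence[Fixation],
    smap: SaliencyMap,
    trial_duration: float = 3.0,
    n_bins: int = 5,
) -> np.ndarray:
    """Mean sampled saliency per equal viewing-time bin.

    The viewing period is split into ``n_bins`` equal half-open intervals
    ``[b*w, (b+1)*w)`` by fixation *onset*; an empty bin yields NaN.  The
    default (five 600 ms bins over a 3 s trial) matches the time-course
    analysis of salience preference.
    """
    if n_bins < 1 or trial_duration <= 0:
        raise ValueError("need n_bins >= 1 and positive trial_duration")
    onsets = np.array([f.onset for f in fixations], dtype=float)
    if np.any((onsets < 0) | (onsets >= trial_duration)):
        raise ValueError("fixation onset beyond trial duration")
    out = np.full(n_bins, np.nan)
    if len(fixations) == 0:
        return out
    vals = sample_saliency(fixations, smap)
    bins = np.floor(onsets / (trial_duration / n_bins)).astype(int)
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            out[b] = vals[sel].mean()
    return out


def clusterize(smap: SaliencyMap, theta: float, connectivity: int = 2) -> ClusterLabeling:
    """Binarize at ``theta`` and label connected supra-threshold clusters.

    ``connectivity=2`` is 8-connectivity (the default for blob labeling);
    ``connectivity=1`` gives 4-connectivity.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mask = smap.grid >= theta
    labels, k = _sk_label(mask, connectivity=connectivity, return_num=True)
    return ClusterLabeling(threshold=float(theta), labels=labels, k=int(k))


def cluster_entropy(fixations, labeling: ClusterLabeling, base: float | None = None) -> EntropyResult:
    """Shannon entropy of the fixation distribution across clusters.

    ``p_i`` is the proportion of fixations in cluster ``i`` relative to the
    total number of fixations falling inside *any* cluster; fixations on
    the background are excluded from the denominator.  ``SE = -sum p_i
    log(p_i)`` in nats by default (pass ``base=2`` for bits).  Images with
    fewer than two clusters carry no distributional information and are
    rejected; zero in-cluster fixations yield ``SE = NaN``.
    """
    if labeling.k < 2:
        raise ValueError("entropy requires more than one cluster (k >= 2)")
    xy = _as_xy(fixations)
    h, w = labeling.labels.shape
    if xy.size == 0:
        return EntropyResult(float("nan"), np.zeros(labeling.k), 0)
    ix, iy = _pixel_indices(xy, w, h)
    labs = labeling.labels[iy, ix]
    labs = labs[labs > 0]
    n_in = int(labs.size)
    if n_in == 0:
        return EntropyResult(float("nan"), np.zeros(labeling.k), 0)
    counts = np.bincount(labs, minlength=labeling.k + 1)[1:]
    p = counts / n_in
    nz = p > 0
    se = float(-(p[nz] * np.log(p[nz])).sum())
    if base is not None:
        se /= np.log(base)
    return EntropyResult(se=se, proportions=p, n_in_clusters=n_in)


def precompute_labelings(
    maps: Sequence[SaliencyMap],
    theta_grid: np.ndarray = DEFAULT_THETA_GRID,
    connectivity: int = 2,
) -> list[list[ClusterLabeling]]:
    """Cluster labelings for every (theta, image) pair.

    The stimuli (and hence the labelings) are fixed across subjects and
    cohorts, so computing them once and reusing them makes repeated
    entropy analyses cheap.  Returns ``labelings[theta_index][image]``.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size == 0:
        raise ValueError("theta grid is empty")
    if np.any(np.diff(theta_grid) <= 0):
        raise ValueError("theta grid must be strictly ascending")
    return [
        [clusterize(m, theta, connectivity=connectivity) for m in maps]
        for theta in theta_grid
    ]


def sweep_from_labelings(
    labelings: Sequence[Sequence[ClusterLabeling]],
    theta_grid: np.ndarray,
) -> pd.DataFrame:
    rows = []
    for theta, labs in zip(np.asarray(theta_grid, dtype=float), labelings):
        ks = np.array([lab.k for lab in labs])
        rows.append({"theta": theta,
                     "frac_multicluster": float(np.mean(ks > 1)),
                     "mean_k": float(ks.mean())})
    return pd.DataFrame(rows)


def entropy_from_labelings(
    labelings: Sequence[Sequence[ClusterLabeling]],
    fixation_sets: Mapping[object, Sequence],
    theta_grid: np.ndarray,
    base: float | None = None,
) -> pd.DataFrame:
    """Per-(theta, subject) mean entropy over multi-cluster images."""
    subjects = list(fixation_sets)
    xy_cache = {s: [_as_xy(fx) for fx in fixation_sets[s]] for s in subjects}
    rows = []
    for theta, labs in zip(np.asarray(theta_grid, dtype=float), labelings):
        for s in subjects:
            ses = []
            for lab, xy in zip(labs, xy_cache[s]):
                if lab.k < 2:
                    continue
                res = cluster_entropy(xy, lab, base=base)
                if np.isfinite(res.se):
                    ses.append(res.se)
            rows.append({"theta": theta, "subject": s,
                         "mean_se": float(np.mean(ses)) if ses else float("nan"),
                         "n_images": len(ses)})
    return pd.DataFrame(rows)


def threshold_sweep(
    maps: Sequence[SaliencyMap],
    fixation_sets: Mapping[object, Sequence],
    theta_grid: np.ndarray = DEFAULT_THETA_GRID,
    connectivity: int = 2,
    base: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster counts and per-subject entropy across a threshold grid.

    ``fixation_sets[subject][i]`` holds the (QC-retained, in-image)
    fixations of ``subject`` on image ``i``, aligned with ``maps``.  Returns

    * a sweep table with one row per theta: ``frac_multicluster`` (fraction
      of images with k > 1) and ``mean_k``;
    * an entropy table with one row per (theta, subject): the subject's
      mean entropy over images with k > 1 and at least one in-cluster
      fixation.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    labelings = precompute_labelings(maps, theta_grid, connectivity=connectivity)
    sweep = sweep_from_labelings(labelings, theta_grid)
    entropy = entropy_from_labelings(labelings, fixation_sets, theta_grid, base=base)
    return sweep, entropy


def select_threshold_range(sweep: pd.DataFrame, min_fraction: float = 0.70) -> ThresholdRange:
    """Select the robust threshold range from a sweep table.

    The lower bound is the smallest theta at which at least
    ``min_fraction`` of the images contain more than one cluster; the upper
    bound is the first theta, past the global maximum of the mean cluster
    count, at which the mean count strictly declines (loss of information
    about salient regions).  Raises with the name of the rule that failed
    when either bound does not exist or the bounds cross.
    """
    thetas = sweep["theta"].to_numpy()
    frac = sweep["frac_multicluster"].to_numpy()
    mean_k = sweep["mean_k"].to_numpy()

    ok = np.flatnonzero(frac >= min_fraction)
    if ok.size == 0:
        raise ValueError(
            f"lower-bound rule failed: no threshold reaches a {min_fraction:.0%} "
            "multi-cluster image fraction"
        )
    lower = float(thetas[ok[0]])

    i0 = int(np.argmax(mean_k))
    decline = np.flatnonzero(np.diff(mean_k[i0:]) < 0)
    if decline.size == 0:
        raise ValueError(
            "upper-bound rule failed: mean cluster count never declines after its maximum"
        )
    upper = float(thetas[i0 + decline[0] + 1])
    if lower > upper:
        raise ValueError(
            f"threshold range empty: 70%-rule lower bound {lower} exceeds "
            f"first-decline upper bound {upper}"
        )
    return ThresholdRange(lower=lower, upper=upper)
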