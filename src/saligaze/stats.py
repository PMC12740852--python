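"""Paired nonparametric statistics for within-subject dosing designs.

Wilcoxon signed-rank comparisons with rank-biserial effect sizes,
Benjamini-Hochberg FDR correction, Pearson/Spearman correlations, a
cluster-based permutation test across frequencies (sign-flip null on
paired log-PSD difference curves), and a report assembler that runs the
paired comparison for every metric table the upstream modules produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PairedSample",
    "TestResult",
    "ClusterTestResult",
    "wilcoxon_paired",
    "bh_fdr",
    "correlate",
    "cluster_permutation_freq",
    "condition_compare_report",
]


@dataclass(frozen=True)
class PairedSample:
    """Per-subject values under LOW and HIGH, paired by subject id.

    Subjects with a missing value in either condition are dropped listwise
    at construction.
    """

    subjects: np.ndarray
    low: np.ndarray
    high: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.subjects)
        lo = np.asarray(self.low, dtype=float)
        hi = np.asarray(self.high, dtype=float)
        if not (len(s) == len(lo) == len(hi)):
            raise ValueError("subjects, low, high must have equal length")
        keep = np.isfinite(lo) & np.isfinite(hi)
        if not keep.all():
            logger.warning("dropping %d unpaired/missing subject(s)", (~keep).sum())
        object.__setattr__(self, "subjects", s[keep])
        object.__setattr__(self, "low", lo[keep])
        object.__setattr__(self, "high", hi[keep])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value: str = "value",
                   subject: str = "subject", condition: str = "condition") -> "PairedSample":
        wide = df.pivot_table(index=subject, columns=condition, values=value,
                              aggfunc="mean")
        for cond in ("LOW", "HIGH"):
            if cond not in wide:
                wide[cond] = np.nan
        return cls(subjects=wide.index.to_numpy(),
                   low=wide["LOW"].to_numpy(), high=wide["HIGH"].to_numpy())

    @property
    def n_pairs(self) -> int:
        return len(self.subjects)

    @property
    def diffs(self) -> np.ndarray:
        return self.high - self.low


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    effect_size: float
    effect_size_type: str
    n_pairs: int
    degenerate: bool = False


@dataclass(frozen=True)
class ClusterTestResult:
    """Contiguous frequency clusters with permutation p-values."""

    clusters: tuple            # of dicts: freq_lo, freq_hi, mass, p
    n_permutations: int
    t_obs: np.ndarray
    freqs: np.ndarray
    threshold: float

    def significant(self, alpha: float = 0.05):
        return [c for c in self.clusters if c["p"] <= alpha]


def _rank_biserial(diffs: np.ndarray) -> float:
    """Rank-biserial correlation from signed ranks of nonzero differences."""
    d = diffs[diffs != 0]
    if d.size == 0:
        return 0.0
    ranks = ss.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    return float((w_pos - w_neg) / (w_pos + w_neg))


def wilcoxon_paired(sample: PairedSample) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on HIGH - LOW differences.

    Zero differences are dropped (Wilcoxon's original rule), ties are
    mid-ranked, and the effect size is the rank-biserial correlation
    (favorable minus unfavorable rank sum over the total).  All-zero
    differences are a degenerate comparison reported with p = 1.
    """
    d = sample.diffs
    if sample.n_pairs == 0 or np.all(d == 0):
        return TestResult(statistic=float("nan"), p_value=1.0, effect_size=0.0,
                          effect_size_type="rank-biserial", n_pairs=sample.n_pairs,
                          degenerate=True)
    nz = d[d != 0]
    has_ties = np.unique(np.abs(nz)).size < nz.size
    # exact null when attainable; mid-rank normal approximation under ties
    method = "approx" if has_ties else "exact"
    res = ss.wilcoxon(sample.high, sample.low, zero_method="wilcox",
                      alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size=_rank_biserial(d),
        effect_size_type="rank-biserial",
        n_pairs=sample.n_pairs,
    )


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns ``(adjusted_p, reject)``; adjusted p-values are monotone in the
    raw p-value ranks.  An empty input yields empty arrays.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    method: str
    n: int
    degenerate: bool = False


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with two-sided p-value.

    Zero variance in either vector leaves the coefficient undefined; the
    result is flagged degenerate with NaN values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), method, x.size,
                                 degenerate=True)
    if method == "pearson":
        r, p = ss.pearsonr(x, y)
    elif method == "spearman":
        r, p = ss.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(float(r), float(p), method, x.size)


_ROW_STRUCT = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]])


def _row_max_masses(t_mat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per row of ``t_mat``: max summed value over contiguous masked runs."""
    out = np.zeros(t_mat.shape[0])
    labels, n_lab = ndimage.label(mask, structure=_ROW_STRUCT)
    if n_lab:
        idx = np.arange(1, n_lab + 1)
        masses = ndimage.sum_labels(t_mat, labels, index=idx)
        rows = ndimage.minimum(
            np.broadcast_to(np.arange(t_mat.shape[0])[:, None], t_mat.shape),
            labels, index=idx,
        ).astype(int)
        np.maximum.at(out, rows, masses)
    return out


def _clusters_1d(stat: np.ndarray, mask: np.ndarray):
    """Contiguous True runs of ``mask`` with their summed statistic."""
    out = []
    if not mask.any():
        return out
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges, mask.size - 1]
    for s, e in zip(starts, ends):
        if mask[s]:
            out.append((int(s), int(e), float(stat[s : e + 1].sum())))
    return out


def cluster_permutation_freq(
    high: np.ndarray,
    low: np.ndarray,
    freqs: np.ndarray,
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    forming_alpha: float = 0.05,
    seed=None,
) -> ClusterTestResult:
    """Cluster-based permutation test across frequencies for paired curves.

    A one-sample t statistic on the per-subject HIGH - LOW difference
    curves is computed at each frequency; contiguous runs exceeding the
    two-sided t threshold at ``forming_alpha`` (df = n-1) form clusters
    scored by their summed t.  The null distribution of the maximum
    cluster mass comes from ``n_perm`` random whole-subject sign flips;
    each cluster's p-value is ``(1 + #{perm max >= observed}) /
    (n_perm + 1)``, controlling the familywise error at the cluster level.
    """
    high = np.atleast_2d(np.asarray(high, dtype=float))
    low = np.atleast_2d(np.asarray(low, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    if high.shape != low.shape or high.shape[1] != freqs.size:
        raise ValueError("high/low must be (n_subjects, n_freqs) on the freqs grid")
    n = high.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    diffs = high - low

    def t_curve(d: np.ndarray) -> np.ndarray:
        m = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = m / (sd / np.sqrt(n))
        return np.where(np.isfinite(t), t, 0.0)

    t_obs = t_curve(diffs)
    thr = float(ss.t.ppf(1.0 - forming_alpha / 2.0, n - 1))

    observed = []
    for s, e, mass in _clusters_1d(t_obs, t_obs > thr):
        observed.append((s, e, mass))
    for s, e, mass in _clusters_1d(t_obs, t_obs < -thr):
        observed.append((s, e, mass))

    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    # sign flips leave per-frequency sums of squares unchanged
    sum_sq = (diffs**2).sum(axis=0)
    sums = signs @ diffs                            # (n_perm, n_freq)
    means = sums / n
    var = (sum_sq[None, :] - n * means**2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_perm = means / np.sqrt(var / n)
    t_perm = np.where(np.isfinite(t_perm), t_perm, 0.0)

    null_max = np.maximum(
        _row_max_masses(t_perm, t_perm > thr),
        _row_max_masses(-t_perm, t_perm < -thr),
    )

    clusters = []
    for s, e, mass in sorted(observed, key=lambda c: c[0]):
        p = (1.0 + np.sum(null_max >= abs(mass))) / (n_perm + 1.0)
        clusters.append(
            {
                "freq_lo": float(freqs[s]),
                "freq_hi": float(freqs[e]),
                "idx_lo": s,
                "idx_hi": e,
                "mass": mass,
                "p": float(p),
            }
        )
    return ClusterTestResult(clusters=tuple(clusters), n_permutations=n_perm,
                             t_obs=t_obs, freqs=freqs, threshold=thr)


def condition_compare_report(
    table: pd.DataFrame,
    fdr_groups: Sequence[Sequence[str]] = (),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired HIGH-vs-LOW Wilcoxon comparison for every metric in a table.

    ``table`` is tidy with columns ``subject``, ``condition`` (LOW/HIGH),
    ``metric``, ``value``.  Subjects present in only one condition are
    dropped per metric with a logged warning.  Each group of metric names
    in ``fdr_groups`` (e.g. the five time-bin saliency metrics) receives a
    joint BH-FDR correction in the ``p_fdr`` column; metrics outside any
    group keep ``p_fdr = NaN``.  Uncorrected p-values are always reported.
    """
    required = {"subject", "condition", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rows = []
    for metric, sub in table.groupby("metric", sort=False):
        sample = PairedSample.from_frame(sub)
        res = wilcoxon_paired(sample)
        med_diff = float(np.median(sample.diffs)) if sample.n_pairs else float("nan")
        rows.append(
            {
                "metric": metric,
                "n_pairs": res.n_pairs,
                "statistic": res.statistic,
                "p": res.p_value,
                "rbc": res.effect_size,
                "median_diff": med_diff,
                "direction": "HIGH>LOW" if med_diff > 0 else
                             ("HIGH<LOW" if med_diff < 0 else "none"),
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows).set_index("metric")
    out["p_fdr"] = np.nan
    for group in fdr_groups:
        group = [g for g in group if g in out.index]
        if group:
            p_adj, _ = bh_fdr(out.loc[group, "p"].to_numpy(), alpha=alpha)
            out.loc[group, "p_fdr"] = p_adj
    return out.reset_index()
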