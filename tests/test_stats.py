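"""Paired tests, FDR, correlations, and the frequency-cluster permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from saligaze.stats import (PairedSample, bh_fdr, cluster_permutation_freq,
                            condition_compare_report, correlate,
                            wilcoxon_paired)


def exact_wilcoxon_p(diffs):
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    w_all = np.array([np.sum(np.array(signs) * ranks)
                      for signs in itertools.product((0, 1), repeat=n)])
    p_lo = np.mean(w_all <= w_obs)
    p_hi = np.mean(w_all >= w_obs)
    return min(1.0, 2 * min(p_lo, p_hi))


def sample(low, high):
    return PairedSample(subjects=np.arange(len(low)), low=low, high=high)


class TestWilcoxon:
    def test_identical_vectors_degenerate_p_one(self):
        res = wilcoxon_paired(sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.degenerate and res.p_value == 1.0

    def test_six_positive_differences_exact_p(self):
        low = np.zeros(6)
        high = np.array([1.0, 2, 3, 4, 5, 6])
        res = wilcoxon_paired(sample(low, high))
        assert res.p_value == pytest.approx(2 / 2**6)
        assert res.effect_size == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        low = rng.normal(0, 1, 8)
        high = low + rng.normal(0.3, 1, 8)
        res = wilcoxon_paired(sample(low, high))
        assert res.p_value == pytest.approx(exact_wilcoxon_p(high - low))

    def test_rank_biserial_from_rank_sums(self):
        # diffs: +1 +2 +3 -4 -> ranks 1..4, W+ = 6, W- = 4, RBC = 0.2
        res = wilcoxon_paired(sample(np.zeros(4), np.array([1.0, 2, 3, -4])))
        assert res.effect_size == pytest.approx(0.2)

    def test_invariant_under_monotone_transform_of_differences(self):
        """Sign/rank structure (hence statistic, p, RBC) is preserved by any
        strictly monotone odd transform of the paired differences."""
        rng = np.random.default_rng(11)
        d = rng.normal(0.2, 1.0, 12)
        base = wilcoxon_paired(sample(np.zeros(12), d))
        trans = wilcoxon_paired(sample(np.zeros(12), np.cbrt(d)))
        assert trans.p_value == pytest.approx(base.p_value)
        assert trans.effect_size == pytest.approx(base.effect_size)

    def test_unpaired_subjects_dropped_listwise(self):
        s = PairedSample(subjects=np.arange(5),
                         low=[1.0, 2, 3, np.nan, 5],
                         high=[2.0, 3, 4, 5, np.nan])
        assert s.n_pairs == 3


class TestFDR:
    def test_single_p_unchanged(self):
        p_adj, rej = bh_fdr([0.03])
        assert p_adj[0] == pytest.approx(0.03) and rej[0]

    def test_equal_ps_stay_equal(self):
        p_adj, _ = bh_fdr([0.2, 0.2, 0.2])
        np.testing.assert_allclose(p_adj, 0.2)

    def test_hand_computed_step_up_values(self):
        p_adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(p_adj, [0.04, 0.04, 0.04, 0.5])
        assert list(rej) == [True, True, True, False]

    def test_adjusted_monotone_in_raw_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 30)
        p_adj, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_empty_input(self):
        p_adj, rej = bh_fdr([])
        assert p_adj.size == 0 and rej.size == 0


class TestCorrelate:
    def test_linear_relation_pearson_one(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman_one(self):
        x = np.linspace(-2, 2, 15)
        assert correlate(x, x**3, method="spearman").r == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        res = correlate(np.ones(5), np.arange(5.0))
        assert res.degenerate and np.isnan(res.r)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 30))
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert correlate(x, y).r == pytest.approx(r_oracle)


class TestClusterPermutation:
    FREQS = np.arange(1.0, 40.5, 0.5)

    def _null_curves(self, seed, n=12):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n, len(self.FREQS)))

    def test_all_zero_differences_give_no_clusters(self):
        z = np.zeros((8, len(self.FREQS)))
        res = cluster_permutation_freq(z, z, self.FREQS, n_perm=200, seed=0)
        assert res.clusters == ()

    def test_planted_band_reduction_detected(self):
        """A 1-SD broadband log-power reduction in 8-13 Hz yields a
        significant negative cluster covering the planted band."""
        rng = np.random.default_rng(2)
        n = 20
        low = rng.normal(size=(n, len(self.FREQS)))
        high = rng.normal(size=(n, len(self.FREQS)))
        band = (self.FREQS >= 8) & (self.FREQS <= 13)
        high[:, band] -= 1.0
        res = cluster_permutation_freq(high, low, self.FREQS, n_perm=1000, seed=3)
        sig = res.significant(0.05)
        assert sig
        covering = [c for c in sig if c["freq_lo"] <= 8 and c["freq_hi"] >= 13]
        assert covering and covering[0]["mass"] < 0

    def test_reproducible_under_fixed_seed(self):
        low = self._null_curves(4)
        high = self._null_curves(5)
        r1 = cluster_permutation_freq(high, low, self.FREQS, n_perm=500, seed=9)
        r2 = cluster_permutation_freq(high, low, self.FREQS, n_perm=500, seed=9)
        assert r1.clusters == r2.clusters

    def test_subject_order_does_not_change_clusters(self):
        rng = np.random.default_rng(12)
        low = self._null_curves(6)
        high = low + np.linspace(-0.8, 0.8, len(self.FREQS)) \
            + rng.normal(0, 0.5, low.shape)
        r1 = cluster_permutation_freq(high, low, self.FREQS, n_perm=2000, seed=1)
        perm = np.random.default_rng(0).permutation(len(low))
        r2 = cluster_permutation_freq(high[perm], low[perm], self.FREQS,
                                      n_perm=2000, seed=1)
        b1 = [(c["freq_lo"], c["freq_hi"], round(c["mass"], 9)) for c in r1.clusters]
        b2 = [(c["freq_lo"], c["freq_hi"], round(c["mass"], 9)) for c in r2.clusters]
        assert b1 == b2
        for c1, c2 in zip(r1.clusters, r2.clusters):
            assert c2["p"] == pytest.approx(c1["p"], abs=0.03)

    def test_matches_mne_reference_implementation(self):
        """Same cluster boundaries and compatible p-values as MNE's
        permutation_cluster_1samp_test on identical difference curves."""
        from mne.stats import permutation_cluster_1samp_test

        rng = np.random.default_rng(7)
        n = 15
        low = rng.normal(size=(n, len(self.FREQS)))
        high = rng.normal(size=(n, len(self.FREQS)))
        high[:, (self.FREQS >= 5) & (self.FREQS <= 12)] += 0.9
        ours = cluster_permutation_freq(high, low, self.FREQS, n_perm=4000, seed=1)
        _, mne_clusters, mne_p, _ = permutation_cluster_1samp_test(
            high - low, n_permutations=4000, tail=0, seed=2, out_type="indices",
            verbose="error")
        def bounds(cl):
            idx = np.asarray(cl[0] if isinstance(cl, tuple) else cl)
            return int(idx.min()), int(idx.max())
        mne_bounds = sorted(bounds(m) for m in mne_clusters)
        our_bounds = sorted((c["idx_lo"], c["idx_hi"]) for c in ours.clusters)
        assert our_bounds == mne_bounds
        mne_by_bounds = {bounds(m): p for m, p in zip(mne_clusters, mne_p)}
        for c in ours.clusters:
            assert c["p"] == pytest.approx(
                mne_by_bounds[(c["idx_lo"], c["idx_hi"])], abs=0.02)

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation_freq(np.zeros((1, 79)), np.zeros((1, 79)),
                                     self.FREQS)


class TestReport:
    def _table(self):
        rows = []
        rng = np.random.default_rng(3)
        for s in range(10):
            base = rng.normal(100, 10)
            rows.append({"subject": s, "condition": "LOW", "metric": "ds",
                         "value": base})
            rows.append({"subject": s, "condition": "HIGH", "metric": "ds",
                         "value": base - 12 + rng.normal(0, 2)})
        return pd.DataFrame(rows)

    def test_detects_planted_reduction_with_direction(self):
        rep = condition_compare_report(self._table())
        row = rep.set_index("metric").loc["ds"]
        assert row["p"] < 0.05 and row["direction"] == "HIGH<LOW"

    def test_subject_in_single_condition_dropped(self):
        df = self._table()
        extra = pd.DataFrame([{"subject": 99, "condition": "LOW",
                               "metric": "ds", "value": 50.0}])
        rep = condition_compare_report(pd.concat([df, extra]))
        assert rep.loc[0, "n_pairs"] == 10

    def test_fdr_applied_within_group_only(self):
        df = self._table()
        df2 = df.copy()
        df2["metric"] = "other"
        rep = condition_compare_report(pd.concat([df, df2]),
                                       fdr_groups=[["ds", "other"]])
        assert rep["p_fdr"].notna().all()
        rep2 = condition_compare_report(pd.concat([df, df2]))
        assert rep2["p_fdr"].isna().all()
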