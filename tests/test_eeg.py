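"""EEG preprocessing, multitaper spectra, band power, envelope LZc."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saligaze.eeg import (BANDS, EpochedEEG, Spectrum, band_aggregate,
                          binarize_envelope, lz76_complexity, lzc,
                          multitaper_psd, preprocess)

RATE = 500.0


def lz76_pointer_oracle(s: str) -> int:
    """Kaspar-Schuster pointer implementation, written independently of the
    substring-search parser in the package."""
    n = len(s)
    c, l, i, k, k_max = 1, 1, 0, 1, 1
    if n == 1:
        return 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def sine(freq, dur, amp=1.0, rate=RATE):
    t = np.arange(int(dur * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


class TestPreprocess:
    def test_sixty_seconds_gives_thirty_epochs(self):
        rng = np.random.default_rng(0)
        ep = preprocess(rng.standard_normal((2, 30000)), RATE)
        assert ep.n_epochs == 30 and ep.n_channels == 2

    def test_notch_attenuates_50hz_by_20db(self):
        x = sine(50.0, 20.0)[None, :]
        ep = preprocess(x, RATE, reject_ptp=None)
        core = ep.epochs[2:-2].ravel()    # avoid filter edge transients
        atten_db = 20 * np.log10(np.std(sine(50.0, 20.0)) / (np.std(core) + 1e-30))
        assert atten_db >= 20.0

    def test_spike_epoch_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((1, 10000)) * 10
        x[0, 5500] += 1000.0              # 10x amplitude spike mid-epoch 5
        ep = preprocess(x, RATE, reject_ptp=150.0)
        assert ep.n_rejected == 1 and ep.n_epochs == 9

    def test_rate_too_low_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((1, 1000)), rate=100.0)

    def test_subject_exclusion_flag(self):
        rng = np.random.default_rng(2)
        ep = preprocess(rng.standard_normal((1, 20000)), RATE)  # 20 epochs
        assert not ep.enough_epochs


class TestSpectrum:
    def _epochs(self, x, n_ep=10):
        n_per = 1000
        return EpochedEEG(x[: n_ep * n_per].reshape(n_ep, 1, n_per), RATE, 2.0,
                          ("ch00",))

    def test_pure_tone_peaks_at_its_bin(self):
        spec = multitaper_psd(self._epochs(sine(10.0, 20.0)))
        assert spec.freqs[np.argmax(spec.avg_log_power)] == pytest.approx(10.0)

    def test_amplitude_doubling_raises_log_power_by_log10_4(self):
        p1 = multitaper_psd(self._epochs(sine(10.0, 20.0, amp=1.0)))
        p2 = multitaper_psd(self._epochs(sine(10.0, 20.0, amp=2.0)))
        i = np.argmax(p1.avg_log_power)
        assert (p2.avg_log_power[i] - p1.avg_log_power[i]
                ) == pytest.approx(np.log10(4.0), abs=0.01)

    def test_white_noise_flat_against_periodogram_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200 * 1000)
        ep = self._epochs(x, n_ep=200)
        spec = multitaper_psd(ep)
        # averaged-periodogram oracle on the same epochs, same freq grid
        seg = ep.epochs[:, 0, :]
        pg = (np.abs(np.fft.rfft(seg, axis=1)) ** 2).mean(axis=0) / (1000 * RATE)
        pg *= 2.0                                   # one-sided
        f = np.fft.rfftfreq(1000, 1 / RATE)
        sel = (f >= 1.0) & (f <= 40.0)
        # compare 5 Hz band means: the single-bin periodogram oracle has
        # ~7 % sampling noise per bin, the band mean ~2 %.  Skip the first
        # band, which sits within one taper bandwidth of DC where the
        # multitaper estimate is edge-biased.
        for lo in np.arange(5.0, 40.0, 5.0):
            band = (spec.freqs >= lo) & (spec.freqs < lo + 5.0)
            obs = spec.avg_log_power[band].mean()
            exp = np.log10(pg[sel][band]).mean()
            assert obs == pytest.approx(exp, abs=0.03)
        assert np.ptp(spec.avg_log_power) < 0.15    # flat in log10

    def test_variance_conservation_broadband(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100 * 1000)
        ep = self._epochs(x, n_ep=100)
        spec = multitaper_psd(ep, fmin=0.0, fmax=250.0)
        df = spec.freqs[1] - spec.freqs[0]
        total = spec.psd.sum() * df
        assert total == pytest.approx(x.var(), rel=0.1)

    def test_epoch_order_irrelevant(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(20000)
        ep = self._epochs(x, n_ep=20)
        perm = rng.permutation(20)
        ep2 = EpochedEEG(ep.epochs[perm], RATE, 2.0, ("ch00",))
        np.testing.assert_allclose(multitaper_psd(ep).avg_log_power,
                                   multitaper_psd(ep2).avg_log_power)
        assert lzc(ep).per_channel == pytest.approx(lzc(ep2).per_channel)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            multitaper_psd(EpochedEEG(np.empty((0, 1, 1000)), RATE, 2.0, ("a",)))


class TestBandPower:
    def test_tone_maximizes_its_band(self):
        spec = multitaper_psd(EpochedEEG(
            sine(10.0, 20.0)[: 10000].reshape(10, 1, 1000), RATE, 2.0, ("c",)))
        bp = band_aggregate(spec)
        assert bp.channel_avg.idxmax() == "alpha"

    def test_flat_spectrum_equal_band_means(self):
        freqs = np.arange(1.0, 40.5, 0.5)
        flat = Spectrum(freqs=freqs, psd=np.ones((1, len(freqs))),
                        log_power=np.zeros((1, len(freqs))),
                        avg_log_power=np.zeros(len(freqs)), ch_names=("c",))
        bp = band_aggregate(flat)
        assert np.allclose(bp.channel_avg.to_numpy(), 0.0)

    def test_matches_brute_force_bin_averaging(self):
        rng = np.random.default_rng(6)
        freqs = np.arange(1.0, 40.5, 0.5)
        lp = rng.standard_normal(len(freqs))
        spec = Spectrum(freqs=freqs, psd=10.0**lp[None, :], log_power=lp[None, :],
                        avg_log_power=lp, ch_names=("c",))
        bp = band_aggregate(spec)
        for name, (lo, hi) in BANDS.items():
            if name == "gamma":
                expect = np.mean([v for f, v in zip(freqs, lp) if lo <= f <= hi])
            else:
                expect = np.mean([v for f, v in zip(freqs, lp) if lo <= f < hi])
            assert bp.channel_avg[name] == pytest.approx(expect)


class TestBinarization:
    def test_ramped_envelope_splits_in_half(self):
        t = np.arange(5000) / RATE
        x = (0.1 + t) * np.sin(2 * np.pi * 40.0 * t)   # linearly ramping envelope
        bits = binarize_envelope(x)
        n = len(bits)
        assert bits[: n // 2].mean() < 0.1
        assert bits[n // 2 :].mean() > 0.9

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 400))
    def test_even_length_gives_exactly_half_ones(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(2 * n)
        assert binarize_envelope(x).sum() == n

    def test_constant_signal_degenerates_with_warning(self):
        with pytest.warns(RuntimeWarning):
            bits = binarize_envelope(np.ones(100))
        assert not bits.any()

    def test_matches_sort_based_median_oracle(self):
        from scipy.signal import hilbert

        rng = np.random.default_rng(7)
        x = (1 + 0.5 * np.sin(2 * np.pi * 3 * np.arange(2000) / RATE)) \
            * np.sin(2 * np.pi * 37 * np.arange(2000) / RATE) \
            + 0.1 * rng.standard_normal(2000)
        env = np.abs(hilbert(x))
        z = (env - env.mean()) / env.std()
        med = np.sort(z)[999:1001].mean()
        np.testing.assert_array_equal(binarize_envelope(x), (z > med).astype(int))


class TestLZ76:
    def test_textbook_example_parses_into_six_phrases(self):
        assert lz76_complexity([int(c) for c in "0001101001000101"]) == 6

    def test_all_zeros_parses_into_two_phrases(self):
        assert lz76_complexity([0] * 16) == 2

    def test_matches_pointer_oracle_on_random_strings(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = rng.integers(1, 65)
            bits = rng.integers(0, 2, n)
            assert lz76_complexity(bits) == lz76_pointer_oracle(
                "".join(map(str, bits)))

    def test_random_exceeds_periodic_exceeds_constant(self):
        rng = np.random.default_rng(9)
        n = 1024
        rand = lz76_complexity(rng.integers(0, 2, n))
        periodic = lz76_complexity(np.tile([0, 1, 1, 0], n // 4))
        const = lz76_complexity(np.zeros(n, dtype=int))
        assert rand > periodic > const

    def test_random_count_near_asymptotic_normalizer(self):
        rng = np.random.default_rng(10)
        n = 10_000
        c = lz76_complexity(rng.integers(0, 2, n))
        assert 0.8 < c / (n / np.log2(n)) < 1.2

    def test_empty_and_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            lz76_complexity([])
        with pytest.raises(ValueError):
            lz76_complexity([0, 2, 1])


class TestLZc:
    def test_reduced_oscillation_amplitude_raises_complexity(self):
        """A strongly rhythmic signal has a regular envelope, hence lower
        LZc than the same background without the oscillation."""
        from saligaze.synth import ParamSet, simulate_eeg

        strong = ParamSet(eeg_osc_amp={"alpha": 4.0})
        weak = ParamSet(eeg_osc_amp={"alpha": 0.5})
        lz_s = lzc(preprocess(simulate_eeg(strong, 30.0, 11, n_channels=2), RATE,
                              reject_ptp=None))
        lz_w = lzc(preprocess(simulate_eeg(weak, 30.0, 11, n_channels=2), RATE,
                              reject_ptp=None))
        assert lz_w.mean > lz_s.mean

    def test_normalized_flag_divides_by_asymptote(self):
        rng = np.random.default_rng(12)
        ep = EpochedEEG(rng.standard_normal((4, 1, 1000)), RATE, 2.0, ("c",))
        raw = lzc(ep, normalized=False)
        norm = lzc(ep, normalized=True)
        assert norm.per_channel[0] == pytest.approx(
            raw.per_channel[0] / (1000 / np.log2(1000)))
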