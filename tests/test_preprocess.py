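import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from painquant import SynthConfig, generate_pulse_wave
from painquant.preprocess import (
    PeakList,
    SignalTooShortError,
    classify_stability,
    detect_peaks,
    mask_to_spans,
    remove_unstable,
    segment_pulses,
    split_samples,
)

import oracles
from conftest import NOISE_FREE_KW

FS = 66.67


def peaks_from_intervals(intervals_s, fs=FS, channel="temple"):
    times = np.concatenate(([0.0], np.cumsum(intervals_s)))
    idx = np.round(times * fs + 200).astype(np.int64)
    return PeakList(channel=channel, indices=idx, fs=fs)


class TestDetectPeaks:
    def test_constant_signal_yields_no_peaks(self):
        assert len(detect_peaks(np.full(2000, 0.7), FS)) == 0

    def test_too_short_signal_raises(self):
        with pytest.raises(SignalTooShortError):
            detect_peaks(np.zeros(99), FS)

    def test_single_triangular_bump_detected_at_apex(self):
        x = np.zeros(1200)
        apex = 600
        width = 8
        x[apex - width: apex + width + 1] = 1 - np.abs(np.arange(-width, width + 1)) / width
        peaks = detect_peaks(x, FS)
        expected = oracles.brute_force_peaks(x, FS)
        np.testing.assert_array_equal(peaks.indices, expected)
        assert len(peaks) == 1
        assert peaks.indices[0] == apex

    def test_clean_train_recovers_beat_count_and_timing(self):
        cfg = SynthConfig(duration_s=60.0, **NOISE_FREE_KW)
        x, beats = generate_pulse_wave(0, cfg, seed=8)
        peaks = detect_peaks(x, cfg.fs)
        true_apices = np.round(beats["t_peak"].to_numpy() * cfg.fs).astype(int)
        # apices that can be detected (enough surrounding signal)
        inside = true_apices[(true_apices > 100) & (true_apices < len(x) - 20)]
        assert abs(len(peaks) - len(inside)) <= 1
        for p in peaks.indices:
            assert np.min(np.abs(inside - p)) <= 2

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_on_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        kind = seed % 3
        if kind == 0:
            x = rng.normal(size=1500)
        elif kind == 1:
            x = np.convolve(rng.normal(size=1600), np.ones(25) / 25, mode="valid")
        else:
            cfg = SynthConfig(duration_s=1500 / FS, ibi_jitter_sd_s=0.08,
                              artifact_fraction=0.0, coupling={})
            x, _ = generate_pulse_wave(int(rng.integers(0, 11)), cfg, seed=seed)
            x = x[:1500] + rng.normal(0, 0.05, size=1500)
        peaks = detect_peaks(x, FS)
        np.testing.assert_array_equal(peaks.indices, oracles.brute_force_peaks(x, FS))


class TestClassifyStability:
    def test_regular_intervals_are_stable(self):
        pk = peaks_from_intervals([0.8] * 7)
        segs = classify_stability(pk, int(pk.indices[-1]) + 200)
        mask = segs.stable_mask(int(pk.indices[-1]) + 200)
        assert mask[pk.indices[0]: pk.indices[-1]].all()
        assert not mask[: pk.indices[0]].any()
        assert not mask[pk.indices[-1]:].any()

    def test_fast_intervals_are_unstable(self):
        pk = peaks_from_intervals([0.5] * 10)
        n = int(pk.indices[-1]) + 200
        assert not classify_stability(pk, n).stable_mask(n).any()

    def test_single_large_interval_breaks_the_ratio_rule(self):
        # I_ave = 0.832 s passes the range rule and d = 0.064 < 0.2,
        # but 0.96 / 0.832 = 1.154 > 1.1
        pk = peaks_from_intervals([0.8, 0.8, 0.8, 0.8, 0.96])
        n = int(pk.indices[-1]) + 200
        assert not classify_stability(pk, n).stable_mask(n).any()

    def test_fewer_than_six_peaks_is_all_unstable(self, caplog):
        pk = peaks_from_intervals([0.8] * 3)
        with caplog.at_level(logging.WARNING):
            segs = classify_stability(pk, 2000)
        assert not segs.stable_mask(2000).any()
        assert any("unstable" in r.message for r in caplog.records)

    @given(st.lists(st.floats(min_value=0.3, max_value=1.6), min_size=5, max_size=40),
           st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_run_recheck(self, intervals, offset):
        times = np.concatenate(([0.0], np.cumsum(intervals)))
        idx = np.unique(np.round(times * FS).astype(np.int64)) + offset
        pk = PeakList(channel="c", indices=idx, fs=FS)
        n = int(idx[-1]) + 150
        mask = classify_stability(pk, n).stable_mask(n)
        np.testing.assert_array_equal(mask, oracles.brute_force_stable_mask(idx, n, FS))

    def test_spans_partition_and_alternate(self):
        pk = peaks_from_intervals([0.8] * 6 + [0.3] * 4 + [0.8] * 6)
        n = int(pk.indices[-1]) + 300
        spans = classify_stability(pk, n).spans
        assert spans[0][0] == 0 and spans[-1][1] == n
        for (a0, b0, l0), (a1, b1, l1) in zip(spans[:-1], spans[1:]):
            assert b0 == a1 and l0 != l1


class TestRemoveUnstable:
    @staticmethod
    def _segs(channel, stable, n):
        mask = np.zeros(n, dtype=bool)
        for a, b in stable:
            mask[a:b] = True
        from painquant.preprocess import StabilitySegments
        return StabilitySegments(channel=channel, spans=mask_to_spans(mask))

    def test_self_intersection_is_identity(self):
        n = 3000
        segs = {"temple": self._segs("temple", [(100, 2000)], n)}
        assert remove_unstable(segs, ["temple"], n) == [(100, 2000)]

    def test_pairwise_interval_arithmetic(self):
        n = 5000
        segs = {"a": self._segs("a", [(0, 3000)], n),
                "b": self._segs("b", [(2000, 5000)], n)}
        assert remove_unstable(segs, ["a", "b"], n) == [(2000, 3000)]

    def test_disjoint_channels_yield_nothing(self):
        n = 3000
        segs = {"a": self._segs("a", [(0, 1000)], n),
                "b": self._segs("b", [(1000, 2000)], n),
                "c": self._segs("c", [(2000, 3000)], n)}
        assert remove_unstable(segs, ["a", "b", "c"], n) == []

    def test_empty_channel_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            remove_unstable({}, [], 100)


class TestSplitSamples:
    @pytest.mark.parametrize(
        "spans_s, expected",
        [([35.0], 3), ([9.9], 0), ([12.0, 21.0], 3)],
    )
    def test_window_counts(self, spans_s, expected):
        spans, pos = [], 0
        for dur in spans_s:
            spans.append((pos, pos + int(round(dur * FS))))
            pos += int(round(dur * FS)) + 500
        windows = split_samples(spans, FS)
        assert len(windows) == expected
        wlen = int(round(10 * FS))
        for w in windows:
            assert w.end - w.start == wlen
            assert any(a <= w.start and w.end <= b for a, b in spans)

    def test_windowing_conserves_duration(self):
        rng = np.random.default_rng(3)
        pos, spans = 0, []
        for _ in range(10):
            length = int(rng.integers(100, 4000))
            spans.append((pos, pos + length))
            pos += length + 50
        windows = split_samples(spans, FS)
        total_span = sum(b - a for a, b in spans)
        total_win = sum(w.end - w.start for w in windows)
        assert total_win <= total_span
        wlen = int(round(10 * FS))
        for a, b in spans:
            covered = sum(w.end - w.start for w in windows if a <= w.start and w.end <= b)
            assert (b - a) - covered < wlen


class TestSegmentPulses:
    def test_count_is_peaks_minus_two(self):
        cfg = SynthConfig(duration_s=30.0, **NOISE_FREE_KW)
        x, _ = generate_pulse_wave(0, cfg, seed=4)
        peaks = detect_peaks(x, cfg.fs).indices
        pulses = segment_pulses(x, peaks)
        assert len(pulses) == len(peaks) - 2
        for p in pulses:
            assert p.start < p.peak < p.end
            assert x[p.peak] >= x[p.start: p.end].max() - 1e-12

    def test_symmetric_beats_have_central_valleys(self):
        fs = 50.0
        kw = dict(NOISE_FREE_KW)
        kw.update(base_ibi_s=1.0, rise_fraction_base=0.5)
        cfg = SynthConfig(duration_s=20.0, fs=fs, **kw)
        x, _ = generate_pulse_wave(0, cfg, seed=0)
        peaks = detect_peaks(x, fs).indices
        for p in segment_pulses(x, peaks):
            prev_peak = peaks[np.searchsorted(peaks, p.start) - 1]
            assert abs(p.start - (prev_peak + p.peak) / 2) <= 1

    def test_tie_breaks_to_earliest_minimum(self):
        x = np.ones(100)
        x[[20, 60, 90]] = 2.0    # peaks
        x[30:50] = 0.0           # flat valley plateau: earliest index wins
        x[70:80] = -1.0
        pulses = segment_pulses(x, [20, 60, 90])
        assert pulses[0].start == 30
        assert pulses[0].end == 70

    def test_fewer_than_two_peaks_gives_nothing(self):
        assert segment_pulses(np.zeros(50), [10]) == []
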