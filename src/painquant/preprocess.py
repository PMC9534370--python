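"""Artifact-robust pulse preprocessing.

The pipeline is: detect pulse peaks with a sliding moving-average rule,
classify the recording into stable/unstable spans from runs of six
consecutive peaks, intersect stable spans across the pulse sensors in use,
tile the surviving spans with contiguous 10-second sample windows, and
segment each window into individual pulses (valley-peak-valley triplets).

Peak detection rule
-------------------
A 100-sample window ``S1`` (1.5 s at 66.67 Hz) slides one sample at a time.
Let ``m`` be the mean of ``S1`` and ``S2`` its last 20 samples (0.3 s).  A
peak is declared when the first and last value of ``S2`` are below ``m``
and the maximum of ``S2`` is above ``m``; the peak position is the argmax
of ``S2``.  Overlapping windows re-detect the same apex, so detections
whose positions fall within 0.25 s of each other are merged, keeping the
highest-amplitude one (earliest on an exact tie).  0.25 s is less than half
the shortest physiological inter-beat interval accepted downstream
(0.6 s), so two genuine beats are never merged.

Stability rule
--------------
For every run of 6 consecutive detected peaks, the 5 inter-peak times
``I`` give a mean ``I_ave`` and population SD ``d``.  The run is stable iff
``0.6 <= I_ave <= 1.2`` seconds, ``d < 0.2`` seconds, and every single
interval lies within ``0.9*I_ave .. 1.1*I_ave``.  A sample tick is stable
iff it is covered by at least one stable run, where a run covers the
half-open span from its first to its last peak.  Ticks before the first
peak and after the last are unstable (no pulse evidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

# Detection / stability constants (seconds unless noted).  These are the
# device-analysis defaults; the pipeline config can override them.
S1_LEN = 100          # sliding window, samples (1.5 s at 66.67 Hz)
S2_LEN = 20           # trailing sub-window, samples (0.3 s)
MERGE_S = 0.25        # peak-deduplication radius
RUN_PEAKS = 6         # peaks per stability run
IAVE_MIN = 0.6        # accepted mean inter-peak time, lower bound
IAVE_MAX = 1.2        # upper bound
D_MAX = 0.2           # inter-peak-time SD bound (strict)
RATIO_LO = 0.9        # single-interval bounds, multiples of I_ave
RATIO_HI = 1.1
WINDOW_S = 10.0       # sample-window length


class SignalTooShortError(ValueError):
    """Signal shorter than one detection window."""


@dataclass
class PeakList:
    channel: str
    indices: np.ndarray  # sorted sample indices, strictly increasing
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(self.indices) > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class StabilitySegments:
    """Alternating (start, end, label) half-open spans partitioning a recording."""

    channel: str
    spans: list[tuple[int, int, str]]

    def stable_mask(self, n: int) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        for start, end, label in self.spans:
            if label == "stable":
                mask[start:end] = True
        return mask

    def stable_seconds(self, fs: float) -> float:
        return sum(end - start for start, end, lab in self.spans if lab == "stable") / fs


@dataclass
class SampleWindow:
    """A 10-second stable window; pain label filled by the features stage."""

    start: int
    end: int
    recording_id: str = ""
    subject_id: str = ""
    half: str = ""          # "first" | "second"
    label: int | None = None


@dataclass
class PulseSegment:
    """One pulse: bounding valleys and the peak between them (sample indices)."""

    start: int
    peak: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.peak < self.end:
            raise ValueError(f"pulse indices must satisfy start < peak < end, got {self}")


def detect_peaks(
    signal: Sequence[float],
    fs: float,
    *,
    s1_len: int = S1_LEN,
    s2_len: int = S2_LEN,
    merge_s: float = MERGE_S,
    channel: str = "",
) -> PeakList:
    """Detect pulse peaks with the sliding moving-average rule.

    The window slides by one sample (the densest scan); duplicate
    detections of one apex from overlapping windows are merged within
    ``merge_s`` seconds, keeping the largest amplitude.
    """
    x = np.asarray(signal, dtype=float)
    n = len(x)
    if n < s1_len:
        raise SignalTooShortError(f"signal has {n} samples; need at least {s1_len}")

    windows = sliding_window_view(x, s1_len)          # (n - s1_len + 1, s1_len)
    m = windows.mean(axis=-1)
    s2 = windows[:, s1_len - s2_len:]
    hit = (s2[:, 0] < m) & (s2[:, -1] < m) & (s2.max(axis=-1) > m)
    offsets = np.nonzero(hit)[0]
    if len(offsets) == 0:
        return PeakList(channel=channel, indices=np.empty(0, dtype=np.int64), fs=fs)
    apex = offsets + (s1_len - s2_len) + np.argmax(s2[offsets], axis=-1)

    merged = merge_detections(apex, x, fs, merge_s=merge_s)
    return PeakList(channel=channel, indices=merged, fs=fs)


def merge_detections(
    apex: np.ndarray, signal: np.ndarray, fs: float, *, merge_s: float = MERGE_S
) -> np.ndarray:
    """Collapse repeated detections of one apex into a single peak.

    Candidates are deduplicated, sorted, and chained into clusters: a
    candidate joins the current cluster while its gap to the cluster's
    previous member is <= ``merge_s * fs`` samples.  Each cluster keeps the
    candidate with the largest signal amplitude, earliest index on a tie.
    """
    if len(apex) == 0:
        return np.empty(0, dtype=np.int64)
    cand = np.unique(np.asarray(apex, dtype=np.int64))
    gap = merge_s * fs
    kept: list[int] = []
    best = cand[0]
    prev = cand[0]
    for a in cand[1:]:
        if a - prev <= gap:
            if signal[a] > signal[best]:
                best = a
        else:
            kept.append(best)
            best = a
        prev = a
    kept.append(best)
    return np.asarray(kept, dtype=np.int64)


def classify_stability(
    peaks: PeakList,
    n_samples: int,
    fs: float | None = None,
    *,
    run_peaks: int = RUN_PEAKS,
    iave_min: float = IAVE_MIN,
    iave_max: float = IAVE_MAX,
    d_max: float = D_MAX,
    ratio_lo: float = RATIO_LO,
    ratio_hi: float = RATIO_HI,
) -> StabilitySegments:
    """Label every sample tick stable/unstable from 6-peak runs.

    Runs advance one peak at a time (overlapping); a tick is stable iff
    covered by >= 1 run satisfying all three criteria.  With fewer than
    ``run_peaks`` peaks the whole recording is unstable.
    """
    fs = peaks.fs if fs is None else fs
    idx = peaks.indices
    mask = np.zeros(n_samples, dtype=bool)
    if len(idx) < run_peaks:
        logger.warning(
            "channel %s: only %d peaks (< %d); whole recording unstable",
            peaks.channel, len(idx), run_peaks,
        )
    else:
        t = idx / fs
        intervals = np.diff(t)                                  # (P-1,)
        runs = sliding_window_view(intervals, run_peaks - 1)    # (R, 5)
        iave = runs.mean(axis=-1)
        d = runs.std(axis=-1)                                   # population SD
        within = (runs >= ratio_lo * iave[:, None]) & (runs <= ratio_hi * iave[:, None])
        ok = (iave >= iave_min) & (iave <= iave_max) & (d < d_max) & within.all(axis=-1)
        for r in np.nonzero(ok)[0]:
            mask[idx[r]: idx[r + run_peaks - 1]] = True
    return StabilitySegments(channel=peaks.channel, spans=mask_to_spans(mask))


def mask_to_spans(mask: np.ndarray) -> list[tuple[int, int, str]]:
    """Convert a boolean stable-mask into alternating labelled half-open spans."""
    n = len(mask)
    if n == 0:
        return []
    change = np.nonzero(np.diff(mask))[0] + 1
    bounds = np.concatenate(([0], change, [n]))
    return [
        (int(a), int(b), "stable" if mask[a] else "unstable")
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def remove_unstable(
    segments: Mapping[str, StabilitySegments],
    channels: Iterable[str],
    n_samples: int,
) -> list[tuple[int, int]]:
    """Intersect stable spans across all requested pulse channels.

    A stretch of the recording is usable only if every sensor in the
    active combination is simultaneously stable there, so adding sensors
    can only shrink the result.
    """
    channels = list(channels)
    if not channels:
        raise ValueError("empty channel set")
    mask = np.ones(n_samples, dtype=bool)
    for ch in channels:
        mask &= segments[ch].stable_mask(n_samples)
    return [(a, b) for a, b, lab in mask_to_spans(mask) if lab == "stable"]


def split_samples(
    spans: Sequence[tuple[int, int]], fs: float, *, window_s: float = WINDOW_S
) -> list[SampleWindow]:
    """Tile stable spans left-to-right with contiguous 10-s windows.

    Each span contributes ``floor(span_length / window_length)`` windows;
    the remainder is discarded.  Windows never straddle an unstable gap.
    """
    wlen = int(round(window_s * fs))
    windows: list[SampleWindow] = []
    for a, b in spans:
        k = (b - a) // wlen
        for j in range(k):
            windows.append(SampleWindow(start=a + j * wlen, end=a + (j + 1) * wlen))
    return windows


def segment_pulses(signal: Sequence[float], peaks: Sequence[int]) -> list[PulseSegment]:
    """Segment a window into individual pulses via inter-peak minima.

    The valley between adjacent peaks is the index of the minimum value
    strictly between them (earliest index on ties).  Each pulse is a
    (valley, next peak, next valley) triplet; the leading and trailing
    partial pulses, which lack a bounding valley, are dropped: ``n`` peaks
    yield ``n - 2`` pulses.
    """
    x = np.asarray(signal, dtype=float)
    pk = np.asarray(peaks, dtype=np.int64)
    if len(pk) < 2:
        return []
    valleys = []
    for a, b in zip(pk[:-1], pk[1:]):
        seg = x[a + 1: b]
        valleys.append(int(a + 1 + np.argmin(seg)))
    return [
        PulseSegment(start=valleys[i], peak=int(pk[i + 1]), end=valleys[i + 1])
        for i in range(len(valleys) - 1)
    ]
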