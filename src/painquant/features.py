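"""Height-invariant pulse-morphology and temperature features per 10-s window.

Per pulse (valley-peak-valley triplet) the widths are

* ``L_R`` — rise width, valley to peak, seconds;
* ``L_F`` — fall width, peak to next valley, seconds;
* ``PPI_H`` — interval between two consecutive high peaks, seconds;
* ``PPI_L`` — interval between two consecutive low valleys, seconds.

All four depend only on peak/valley *timing*, never on amplitude, so they
are invariant to how tightly the device is worn.  The SD of ``PPI_H``
within a window is the pulse-rate-variability feature.  Per window each
active pulse sensor contributes the mean and SD of each width, and the
five temperature channels contribute their window means plus four derived
quantities: T_temple/T_finger, T_temple - T_finger, T_forehead/T_finger,
T_forehead - T_finger.

Pain labels: the start score applies to windows whose midpoint falls in
the first half of the recording, the end score to the rest (a midpoint
exactly at the half-way mark counts as second half).

SD convention: population SD (divide by n) throughout feature extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import PULSE_SITES, TEMP_SITES, RawRecording
from . import preprocess
from .preprocess import PeakList, PulseSegment, SampleWindow

logger = logging.getLogger(__name__)

#: per-pulse width parameters, in extraction order
PULSE_PARAMS = ("LR", "LF", "PPIH", "PPIL")
#: aggregates computed per window for each pulse parameter
PULSE_AGGS = ("mean", "sd")

META_COLUMNS = ("recording_id", "subject_id", "half", "label")


class DegenerateWindowError(ValueError):
    """Window cannot contribute features (e.g. fewer than two pulses)."""


@dataclass
class NormalizationParams:
    """Feature-wise z-scoring parameters, fitted on a training fold only."""

    center: pd.Series
    scale: pd.Series
    dropped: list[str]
    population: str = "pooled"   # "pooled" | subject id


def pulse_feature_columns(sensors: Iterable[str]) -> list[str]:
    cols = []
    for s in sensors:
        for p in PULSE_PARAMS:
            for agg in PULSE_AGGS:
                cols.append(f"{s}_{p}_{agg}")
    return cols


def temperature_feature_columns(*, include_sd: bool = False) -> list[str]:
    cols = [f"temp_{s}_mean" for s in TEMP_SITES]
    if include_sd:
        cols += [f"temp_{s}_sd" for s in TEMP_SITES]
    cols += [
        "temp_ratio_temple_finger",
        "temp_diff_temple_finger",
        "temp_ratio_forehead_finger",
        "temp_diff_forehead_finger",
    ]
    return cols


def feature_columns(sensors: Iterable[str], *, include_temp_sd: bool = False) -> list[str]:
    """Canonical feature-column order for a sensor combination."""
    return pulse_feature_columns(sensors) + temperature_feature_columns(include_sd=include_temp_sd)


def compute_pulse_params(pulses: Sequence[PulseSegment], fs: float) -> pd.DataFrame:
    """Per-pulse width parameters for one window and one sensor.

    Returns a DataFrame with columns ``LR, LF, PPIH, PPIL`` (seconds), one
    row per pulse.  The inter-pulse intervals are defined between
    consecutive pulses, so their final row is NaN; aggregation is
    NaN-aware.  Fewer than two pulses raise, because the PPI features are
    then undefined and the window must be dropped.
    """
    if len(pulses) < 2:
        raise DegenerateWindowError(
            f"need >= 2 pulses for inter-pulse intervals, got {len(pulses)}"
        )
    peaks = np.array([p.peak for p in pulses], dtype=float)
    starts = np.array([p.start for p in pulses], dtype=float)
    ends = np.array([p.end for p in pulses], dtype=float)
    out = pd.DataFrame(
        {
            "LR": (peaks - starts) / fs,
            "LF": (ends - peaks) / fs,
            "PPIH": np.append(np.diff(peaks), np.nan) / fs,
            "PPIL": np.append(np.diff(starts), np.nan) / fs,
        }
    )
    return out


def _pop_sd(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    return float(np.sqrt(np.mean((x - x.mean()) ** 2))) if len(x) else float("nan")


def compute_window_features(
    window: SampleWindow,
    pulse_params: Mapping[str, pd.DataFrame],
    temperatures: Mapping[str, np.ndarray],
    *,
    include_temp_sd: bool = False,
) -> dict[str, float]:
    """Aggregate one window's pulse and temperature features into a flat row."""
    row: dict[str, float] = {}
    for sensor, params in pulse_params.items():
        for p in PULSE_PARAMS:
            vals = params[p].to_numpy(dtype=float)
            row[f"{sensor}_{p}_mean"] = float(np.nanmean(vals))
            row[f"{sensor}_{p}_sd"] = _pop_sd(vals)
    tmeans: dict[str, float] = {}
    for site in TEMP_SITES:
        seg = np.asarray(temperatures[site], dtype=float)
        tmeans[site] = float(seg.mean())
        row[f"temp_{site}_mean"] = tmeans[site]
        if include_temp_sd:
            row[f"temp_{site}_sd"] = _pop_sd(seg)
    if tmeans["finger"] == 0.0:
        raise DegenerateWindowError("finger temperature mean is 0; ratio features undefined")
    row["temp_ratio_temple_finger"] = tmeans["temple"] / tmeans["finger"]
    row["temp_diff_temple_finger"] = tmeans["temple"] - tmeans["finger"]
    row["temp_ratio_forehead_finger"] = tmeans["forehead"] / tmeans["finger"]
    row["temp_diff_forehead_finger"] = tmeans["forehead"] - tmeans["finger"]
    return row


def assign_pain_labels(windows: Sequence[SampleWindow], rec: RawRecording) -> list[SampleWindow]:
    """Assign each window the start or end pain score by recording half.

    A window belongs to the first half iff its midpoint is strictly before
    ``duration_s / 2``; the exact midpoint goes to the second half
    (half-open convention).
    """
    mid_t = rec.duration_s / 2.0
    for w in windows:
        midpoint_s = (w.start + w.end) / (2.0 * rec.fs)
        w.recording_id = rec.recording_id
        w.subject_id = rec.subject_id
        if midpoint_s < mid_t:
            w.half, w.label = "first", rec.pain_start
        else:
            w.half, w.label = "second", rec.pain_end
    return list(windows)


def extract_recording_features(
    rec: RawRecording,
    sensors: Sequence[str],
    *,
    include_temp_sd: bool = False,
    detect_kwargs: Mapping | None = None,
    stability_kwargs: Mapping | None = None,
    window_s: float = preprocess.WINDOW_S,
    peaks: Mapping[str, PeakList] | None = None,
) -> pd.DataFrame:
    """Full per-recording feature extraction for one sensor combination.

    Runs peak detection and stability classification on every requested
    pulse channel, intersects the stable spans, tiles them with 10-s
    windows, labels the windows by recording half, and aggregates pulse
    and temperature features.  Windows with fewer than two complete pulses
    on any sensor are dropped (logged).  Pre-computed ``peaks`` may be
    passed to avoid re-detection when several combinations share channels.
    """
    sensors = list(sensors)
    if not sensors:
        raise ValueError("empty sensor combination")
    unknown = [s for s in sensors if s not in PULSE_SITES]
    if unknown:
        raise ValueError(f"unknown pulse sensors: {unknown}")
    n = rec.n_samples
    detect_kwargs = dict(detect_kwargs or {})
    stability_kwargs = dict(stability_kwargs or {})

    if peaks is None:
        peaks = {
            ch: preprocess.detect_peaks(rec.pulse[ch], rec.fs, channel=ch, **detect_kwargs)
            for ch in sensors
        }
    segments = {
        ch: preprocess.classify_stability(peaks[ch], n, rec.fs, **stability_kwargs)
        for ch in sensors
    }
    spans = preprocess.remove_unstable(segments, sensors, n)
    windows = preprocess.split_samples(spans, rec.fs, window_s=window_s)
    assign_pain_labels(windows, rec)

    rows = []
    for w in windows:
        try:
            params = {}
            for ch in sensors:
                pk = peaks[ch].indices
                inside = pk[(pk >= w.start) & (pk < w.end)]
                pulses = preprocess.segment_pulses(rec.pulse[ch], inside)
                params[ch] = compute_pulse_params(pulses, rec.fs)
            temps = {site: rec.temperature[site][w.start: w.end] for site in TEMP_SITES}
            row = compute_window_features(w, params, temps, include_temp_sd=include_temp_sd)
        except DegenerateWindowError as exc:
            logger.info(
                "recording %s window [%d, %d): dropped (%s)",
                rec.recording_id, w.start, w.end, exc,
            )
            continue
        row.update(
            recording_id=w.recording_id,
            subject_id=w.subject_id,
            half=w.half,
            label=w.label,
            start=w.start,
            end=w.end,
        )
        rows.append(row)

    cols = list(META_COLUMNS) + ["start", "end"] + feature_columns(
        sensors, include_temp_sd=include_temp_sd
    )
    return pd.DataFrame(rows, columns=cols)


def extract_cohort_features(
    recordings: Iterable[RawRecording], sensors: Sequence[str], **kwargs
) -> pd.DataFrame:
    """Concatenate :func:`extract_recording_features` over a cohort."""
    frames = [extract_recording_features(rec, sensors, **kwargs) for rec in recordings]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def fit_apply_zscore(
    train: pd.DataFrame,
    test: pd.DataFrame | None = None,
    feature_cols: Sequence[str] | None = None,
    *,
    population: str = "pooled",
) -> tuple[pd.DataFrame, pd.DataFrame | None, NormalizationParams]:
    """Z-score features using statistics estimated on the training rows only.

    Features with zero variance on the training rows are dropped from both
    outputs (logged).  The test frame, if given, is transformed with the
    training center/scale, so no test statistics leak into training.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    if feature_cols is None:
        feature_cols = [c for c in train.columns if c not in META_COLUMNS + ("start", "end")]
    X = train[list(feature_cols)].to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = np.sqrt(np.mean((X - center) ** 2, axis=0))   # population SD
    keep = scale > 0
    dropped = [c for c, k in zip(feature_cols, keep) if not k]
    if dropped:
        logger.info("dropping zero-variance features: %s", dropped)
    kept_cols = [c for c, k in zip(feature_cols, keep) if k]
    params = NormalizationParams(
        center=pd.Series(center[keep], index=kept_cols),
        scale=pd.Series(scale[keep], index=kept_cols),
        dropped=dropped,
        population=population,
    )
    train_out = apply_zscore(train, params)
    test_out = apply_zscore(test, params) if test is not None else None
    return train_out, test_out, params


def apply_zscore(df: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    out = df.drop(columns=params.dropped, errors="ignore").copy()
    cols = list(params.center.index)
    out[cols] = (df[cols] - params.center) / params.scale
    return out
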