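"""Synthetic pain-meter cohorts with known pain -> physiology coupling.

The generator emulates home sessions on the device: three pulse channels
sharing one beat train (channel-specific amplitude and noise), five skin
temperature channels (site-specific baselines in deg C), a start and end
self-reported pain score per recording, and motion-artifact epochs that
violate the downstream stability rules.  The latent pain level switches
exactly at the recording midpoint, so the half-recording label assignment
used by the analysis is exactly correct on synthetic data.

Each beat is a pair of sharpened raised-cosine arcs: the waveform rises
from a valley to the peak over ``rise_fraction`` of the beat interval and
falls for the remainder, giving the asymmetric quasi-periodic shape whose
valley/peak timing carries all the information the width features use (see
``PULSE_SHAPE_EXP`` for why the arcs are sharpened).  Beat intervals
are drawn per beat around ``base_ibi_s + coupling['ibi'] * pain`` with SD
``ibi_jitter_sd_s + coupling['ibi_jitter_sd'] * pain``.

Every knob that couples pain to physiology lives in ``SynthConfig.coupling``
(units per pain point); ground truth sufficient to compute the expected
features analytically is returned alongside every recording.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    FS_DEFAULT,
    PULSE_SITES,
    TEMP_SITES,
    CohortManifest,
    RawRecording,
    write_manifest,
    write_recording,
)

logger = logging.getLogger(__name__)

#: site-specific skin-temperature baselines, deg C
TEMP_BASELINES = {
    "forehead": 33.0,
    "temple": 32.5,
    "wrist_top": 31.0,
    "wrist_bottom": 30.7,
    "finger": 30.0,
}

#: default pain -> physiology slopes (per pain point).  Signs follow a
#: sympathetic-arousal pattern (faster pulse, cooler extremities, more
#: beat-interval variability with rising pain); magnitudes are free
#: parameters of the simulation chosen to give a clearly learnable but
#: noisy population-level signal.
DEFAULT_COUPLING = {
    "rise_fraction": 0.004,      # fraction of beat / point
    "ibi": -0.008,               # s / point
    "ibi_jitter_sd": 0.0015,     # s / point
    "temp_forehead": -0.04,      # degC / point
    "temp_temple": -0.03,
    "temp_wrist_top": -0.015,
    "temp_wrist_bottom": -0.015,
    "temp_finger": -0.08,
}

ARTIFACT_MODES = ("noise-burst", "dropout", "irregular-beats")


class ConfigError(ValueError):
    """Invalid synthesis configuration."""


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort; defaults emulate the study protocol
    (12 subjects, ~15 ten-minute recordings each, 66.67 Hz)."""

    n_subjects: int = 12
    recordings_per_subject: int = 15
    duration_s: float = 600.0
    fs: float = FS_DEFAULT
    base_ibi_s: float = 0.85
    ibi_jitter_sd_s: float = 0.02
    rise_fraction_base: float = 0.35
    coupling: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUPLING))
    artifact_fraction: float = 0.10
    pain_score_process: str = "subject_gaussian"   # or "fixed:<k>", "uniform"
    seed: int = 0
    # secondary noise/variation knobs
    subject_ibi_sd: float = 0.05          # between-subject baseline IBI SD, s
    subject_temp_sd: float = 0.50         # between-subject temperature offset SD, degC
    pulse_noise_sd: float = 0.01          # additive white noise on unit-amplitude pulse
    temp_noise_sd: float = 0.05           # white noise on temperature, degC
    temp_drift_sd: float = 0.25           # slow within-recording drift amplitude, degC
    pain_subject_mean_range: tuple[float, float] = (1.5, 8.5)
    pain_within_subject_sd: float = 2.2
    pain_end_shift_sd: float = 1.0

    def validate(self) -> None:
        if not 0.0 < self.rise_fraction_base < 1.0:
            raise ConfigError(f"rise_fraction_base must be in (0, 1), got {self.rise_fraction_base}")
        if not 0.0 <= self.artifact_fraction < 1.0:
            raise ConfigError(f"artifact_fraction must be in [0, 1), got {self.artifact_fraction}")
        if self.duration_s * self.fs < round(10 * self.fs):
            raise ConfigError("duration_s too short for a single 10-s window")
        for pain in (0, 10):
            ibi = self.base_ibi_s + self.coupling.get("ibi", 0.0) * pain
            if not 0.0 < ibi < self.duration_s:
                raise ConfigError(f"coupling drives inter-beat interval to {ibi} s at pain {pain}")


@dataclass
class GroundTruth:
    """Everything needed to compute expected features analytically."""

    recording_id: str
    subject_id: str
    pain_start: int
    pain_end: int
    beats: pd.DataFrame          # t_start, interval, rise_fraction, t_peak (seconds)
    artifact_spans: dict[str, list[tuple[int, int]]]   # per pulse channel, sample indices
    coupling: dict[str, float]
    subject_effects: dict[str, float]


@dataclass
class SubjectEffects:
    """Per-subject random effects, drawn once per subject."""

    subject_id: str
    ibi_offset: float
    temp_offsets: dict[str, float]
    pain_mean: float


# ---------------------------------------------------------------------------
# beat trains and waveform rendering

def _draw_beats(
    rng: np.random.Generator,
    cfg: SynthConfig,
    duration_s: float,
    pain_at: Callable[[float], float],
    ibi_offset: float = 0.0,
) -> pd.DataFrame:
    """Draw valley-to-valley beats sequentially until the recording ends."""
    rows = []
    t = 0.0
    while t < duration_s:
        pain = pain_at(t)
        mean_ibi = cfg.base_ibi_s + ibi_offset + cfg.coupling.get("ibi", 0.0) * pain
        sd = cfg.ibi_jitter_sd_s + cfg.coupling.get("ibi_jitter_sd", 0.0) * pain
        interval = mean_ibi + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        interval = max(interval, 0.25)
        rise = cfg.rise_fraction_base + cfg.coupling.get("rise_fraction", 0.0) * pain
        rise = float(np.clip(rise, 0.05, 0.95))
        rows.append((t, interval, rise, t + rise * interval))
        t += interval
    return pd.DataFrame(rows, columns=["t_start", "interval", "rise_fraction", "t_peak"])


#: systolic sharpening of the rendered arcs.  The raised-cosine profile is
#: taken to this power so the pulse hugs the diastolic baseline and the
#: above-mean excursion stays narrower than the detector's 0.3-s trailing
#: window even at the slowest accepted beats (1.2 s); a small linear
#: admixture keeps the valley a strict, well-localized minimum.
PULSE_SHAPE_EXP = 16
PULSE_SHAPE_LINEAR = 0.06


def _render_beats(
    beats: pd.DataFrame,
    n_samples: int,
    fs: float,
    *,
    amplitude: float = 1.0,
    low: float = 0.1,
) -> np.ndarray:
    """Render a beat train as concatenated sharpened rise/fall cosine arcs.

    Within each beat the waveform rises from the valley to the peak over
    ``rise_fraction`` of the interval and falls for the remainder; valley
    and peak *timing* is exact, which is all the width features consume.
    """
    x = np.full(n_samples, low, dtype=float)
    t = np.arange(n_samples) / fs
    k, w = PULSE_SHAPE_EXP, PULSE_SHAPE_LINEAR
    for t0, interval, rise, _ in beats.itertuples(index=False):
        a = int(np.ceil(t0 * fs))
        b = min(int(np.ceil((t0 + interval) * fs)), n_samples)
        if a >= b:
            continue
        u = (t[a:b] - t0) / interval
        up = u < rise
        s = np.empty(b - a)
        s[up] = 0.5 * (1 - np.cos(np.pi * u[up] / rise))
        s[~up] = 0.5 * (1 + np.cos(np.pi * (u[~up] - rise) / (1 - rise)))
        x[a:b] = low + amplitude * ((1 - w) * s**k + w * s)
    return x


def generate_pulse_wave(
    pain: float,
    cfg: SynthConfig,
    duration_s: float | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate one constant-pain pulse channel and its per-beat ground truth.

    Deterministic given the seed.  The returned beat table holds the true
    valley times, intervals, rise fractions and apex times in seconds.
    """
    cfg.validate()
    duration_s = cfg.duration_s if duration_s is None else duration_s
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beats = _draw_beats(rng, cfg, duration_s, lambda t: pain)
    n = int(round(cfg.fs * duration_s))
    signal = _render_beats(beats, n, cfg.fs)
    if cfg.pulse_noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.pulse_noise_sd, size=n)
    return signal, beats


# ---------------------------------------------------------------------------
# artifacts

def _merge_spans(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    if not spans:
        return []
    ordered = sorted(spans)
    merged = [list(ordered[0])]
    overlap = False
    for a, b in ordered[1:]:
        if a <= merged[-1][1]:
            overlap = True
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    if overlap:
        warnings.warn("overlapping artifact spans merged", stacklevel=3)
    return [(a, b) for a, b in merged]


def inject_artifacts(
    signal: Sequence[float],
    spans: Sequence[tuple[int, int]],
    mode: str,
    seed: int | np.random.Generator = 0,
    *,
    fs: float = FS_DEFAULT,
) -> np.ndarray:
    """Corrupt ``signal`` inside ``spans`` (sample indices) so the stability
    classifier rejects those epochs; the signal outside spans is untouched.

    Modes: ``noise-burst`` (aperiodic white noise), ``dropout`` (flat
    signal, no peaks at all), ``irregular-beats`` (beat train with wildly
    jittered intervals violating the 0.9-1.1 x local-mean rule).
    """
    x = np.asarray(signal, dtype=float).copy()
    if mode not in ARTIFACT_MODES:
        raise ValueError(f"unknown artifact mode {mode!r}; choose from {ARTIFACT_MODES}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for a, b in _merge_spans([(int(a), int(b)) for a, b in spans]):
        if a < 0 or b > len(x):
            raise ValueError(f"artifact span ({a}, {b}) outside signal extent {len(x)}")
        width = b - a
        if width <= 0:
            continue
        if mode == "noise-burst":
            scale = 3.0 * max(float(np.std(x)), 0.1)
            x[a:b] = float(np.mean(x[a:b])) + rng.normal(0.0, scale, size=width)
        elif mode == "dropout":
            x[a:b] = x[a]
        else:  # irregular-beats: intervals far outside 0.9-1.1 x any local mean
            rows, t = [], 0.0
            while t < width / fs:
                interval = float(rng.uniform(0.25, 2.2))
                rise = float(rng.uniform(0.15, 0.6))
                rows.append((t, interval, rise, t + rise * interval))
                t += interval
            beats = pd.DataFrame(rows, columns=["t_start", "interval", "rise_fraction", "t_peak"])
            x[a:b] = _render_beats(beats, width, fs)
    return x


def _draw_artifact_spans(
    rng: np.random.Generator, cfg: SynthConfig, n_samples: int
) -> list[tuple[int, int]]:
    """Random artifact epochs totalling ~artifact_fraction of the recording."""
    total = cfg.artifact_fraction * n_samples
    if total < 1:
        return []
    mean_len = 18.0 * cfg.fs                      # ~18-s motion epochs
    n_spans = max(1, int(round(total / mean_len)))
    lengths = rng.uniform(0.5, 1.5, size=n_spans)
    lengths *= total / lengths.sum()
    spans = []
    for length in lengths:
        length = int(min(length, n_samples - 1))
        start = int(rng.integers(0, n_samples - length))
        spans.append((start, start + length))
    return _merge_spans(spans)


# ---------------------------------------------------------------------------
# recordings and cohorts

def _smooth_noise(rng: np.random.Generator, n: int, sd: float, fs: float) -> np.ndarray:
    """Slowly varying drift: sparse control points, linear interpolation."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    knots = max(int(n / fs / 60.0) + 2, 2)        # one control point per minute
    values = rng.normal(0.0, sd, size=knots)
    return np.interp(np.arange(n), np.linspace(0, n - 1, knots), values)


def generate_recording(
    effects: SubjectEffects,
    pains: tuple[int, int],
    cfg: SynthConfig,
    seed: int | np.random.Generator,
    recording_id: str = "rec",
) -> tuple[RawRecording, GroundTruth]:
    """Generate one session: shared beat train, three pulse channels, five
    temperature channels, artifacts, and full ground truth.

    ``pains[0]`` drives the latent pain in the first half of the recording
    and ``pains[1]`` in the second (switch exactly at the midpoint).
    """
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pain_start, pain_end = int(pains[0]), int(pains[1])
    mid = cfg.duration_s / 2.0
    pain_at = lambda t: pain_start if t < mid else pain_end  # noqa: E731
    n = int(round(cfg.fs * cfg.duration_s))

    beats = _draw_beats(rng, cfg, cfg.duration_s, pain_at, ibi_offset=effects.ibi_offset)

    pulse: dict[str, np.ndarray] = {}
    artifact_spans: dict[str, list[tuple[int, int]]] = {}
    for site in PULSE_SITES:
        amp = 1.0 * float(rng.uniform(0.85, 1.15))
        x = _render_beats(beats, n, cfg.fs, amplitude=amp)
        if cfg.pulse_noise_sd > 0:
            x = x + rng.normal(0.0, cfg.pulse_noise_sd * amp, size=n)
        spans = _draw_artifact_spans(rng, cfg, n)
        if spans:
            mode = ARTIFACT_MODES[int(rng.integers(0, len(ARTIFACT_MODES)))]
            x = inject_artifacts(x, spans, mode, rng, fs=cfg.fs)
        pulse[site] = x
        artifact_spans[site] = spans

    t_idx = np.arange(n) / cfg.fs
    pain_t = np.where(t_idx < mid, pain_start, pain_end).astype(float)
    temperature: dict[str, np.ndarray] = {}
    for site in TEMP_SITES:
        base = TEMP_BASELINES[site] + effects.temp_offsets[site]
        slope = cfg.coupling.get(f"temp_{site}", 0.0)
        x = base + slope * pain_t
        x = x + _smooth_noise(rng, n, cfg.temp_drift_sd, cfg.fs)
        if cfg.temp_noise_sd > 0:
            x = x + rng.normal(0.0, cfg.temp_noise_sd, size=n)
        temperature[site] = x

    rec = RawRecording(
        subject_id=effects.subject_id,
        recording_id=recording_id,
        fs=cfg.fs,
        pulse=pulse,
        temperature=temperature,
        pain_start=pain_start,
        pain_end=pain_end,
        duration_s=cfg.duration_s,
    )
    truth = GroundTruth(
        recording_id=recording_id,
        subject_id=effects.subject_id,
        pain_start=pain_start,
        pain_end=pain_end,
        beats=beats,
        artifact_spans=artifact_spans,
        coupling=dict(cfg.coupling),
        subject_effects={
            "ibi_offset": effects.ibi_offset,
            **{f"temp_{k}": v for k, v in effects.temp_offsets.items()},
        },
    )
    return rec, truth


def _draw_subject_effects(rng: np.random.Generator, cfg: SynthConfig, subject_id: str) -> SubjectEffects:
    lo, hi = cfg.pain_subject_mean_range
    return SubjectEffects(
        subject_id=subject_id,
        ibi_offset=float(rng.normal(0.0, cfg.subject_ibi_sd)),
        temp_offsets={s: float(rng.normal(0.0, cfg.subject_temp_sd)) for s in TEMP_SITES},
        pain_mean=float(rng.uniform(lo, hi)),
    )


def _draw_pain_pair(rng: np.random.Generator, cfg: SynthConfig, effects: SubjectEffects) -> tuple[int, int]:
    proc = cfg.pain_score_process
    if proc.startswith("fixed:"):
        k = int(proc.split(":", 1)[1])
        return k, k
    if proc == "uniform":
        start = int(rng.integers(0, 11))
    elif proc == "subject_gaussian":
        start = int(np.clip(round(rng.normal(effects.pain_mean, cfg.pain_within_subject_sd)), 0, 10))
    else:
        raise ConfigError(f"unknown pain_score_process {proc!r}")
    end = int(np.clip(start + round(rng.normal(0.0, cfg.pain_end_shift_sd)), 0, 10))
    return start, end


def simulate_cohort(cfg: SynthConfig) -> list[tuple[RawRecording, GroundTruth]]:
    """Generate the whole cohort in memory; deterministic given ``cfg.seed``.

    Subject-level random effects are drawn once per subject; each
    recording uses an independent child stream of the seed, so recordings
    are statistically independent.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    subject_seeds = root.spawn(cfg.n_subjects)
    out = []
    for i, sseq in enumerate(subject_seeds):
        subject_id = f"S{i + 1:02d}"
        streams = sseq.spawn(cfg.recordings_per_subject + 1)
        effects = _draw_subject_effects(np.random.default_rng(streams[0]), cfg, subject_id)
        for j in range(cfg.recordings_per_subject):
            rng = np.random.default_rng(streams[j + 1])
            pains = _draw_pain_pair(rng, cfg, effects)
            rid = f"{subject_id}R{j + 1:02d}"
            out.append(generate_recording(effects, pains, cfg, rng, recording_id=rid))
    return out


def generate_cohort(cfg: SynthConfig, out_dir: str | Path) -> tuple[CohortManifest, list[GroundTruth]]:
    """Simulate a cohort and write it to ``out_dir`` via the recording format.

    Writes one recording file and one ground-truth sidecar TSV (true beat
    table) per session, a cohort manifest, and a cohort-level truth table
    (one row per recording: scores, artifact seconds per channel).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = CohortManifest(note=f"synthetic cohort, seed={cfg.seed}")
    truths = []
    summary_rows = []
    for rec, truth in simulate_cohort(cfg):
        path = out_dir / f"{rec.recording_id}.tsv"
        write_recording(rec, path)
        truth.beats.to_csv(out_dir / f"{rec.recording_id}.truth.tsv", sep="\t", index=False,
                           lineterminator="\n")
        manifest.entries.append((rec.subject_id, rec.recording_id, path))
        truths.append(truth)
        summary_rows.append({
            "subject_id": rec.subject_id,
            "recording_id": rec.recording_id,
            "pain_start": rec.pain_start,
            "pain_end": rec.pain_end,
            **{f"artifact_s_{ch}": sum(b - a for a, b in truth.artifact_spans[ch]) / cfg.fs
               for ch in PULSE_SITES},
        })
    write_manifest(manifest, out_dir / "manifest.tsv")
    pd.DataFrame(summary_rows).to_csv(out_dir / "cohort_truth.tsv", sep="\t", index=False,
                                      lineterminator="\n")
    return manifest, truths
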