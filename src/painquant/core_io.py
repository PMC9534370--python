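"""Recording data model and plain-text on-disk formats.

A *recording* is one ten-minute home session on the pain meter: three
photoplethysmographic pulse channels (temple, carotid, pointer finger) and
five skin-temperature channels (forehead, temple, top/bottom of wrist,
finger), all sampled on a common clock, plus a self-reported pain score
(integer visual-analogue scale, 0-10) taken at the start and at the end of
the session.

Recordings are stored as UTF-8 text: ``#key<TAB>value`` metadata header
lines followed by a TSV body with one column per channel.  A cohort is
described by a manifest TSV (subject_id, recording_id, path).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

#: canonical pulse-sensor sites, in the fixed order used everywhere
PULSE_SITES: tuple[str, ...] = ("temple", "carotid", "finger")
#: canonical temperature sites
TEMP_SITES: tuple[str, ...] = ("forehead", "temple", "wrist_top", "wrist_bottom", "finger")

#: default sampling rate of the acquisition hardware, Hz
FS_DEFAULT: float = 66.67

PULSE_COLUMNS = tuple(f"pulse_{s}" for s in PULSE_SITES)
TEMP_COLUMNS = tuple(f"temp_{s}" for s in TEMP_SITES)
_HEADER_KEYS = ("subject_id", "recording_id", "fs", "pain_start", "pain_end", "duration_s")


class RecordingFormatError(ValueError):
    """Raised when a recording file does not conform to the expected layout."""


class RecordingValidationError(ValueError):
    """Raised when a recording violates its invariants."""


@dataclass
class RawRecording:
    """One session's multichannel signals plus metadata."""

    subject_id: str
    recording_id: str
    fs: float
    pulse: dict[str, np.ndarray]
    temperature: dict[str, np.ndarray]
    pain_start: int
    pain_end: int
    duration_s: float

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def channel(self, name: str) -> np.ndarray:
        """Return a channel by its column name (``pulse_temple``, ``temp_finger``...)."""
        kind, _, site = name.partition("_")
        if kind == "pulse" and site in self.pulse:
            return self.pulse[site]
        if kind == "temp" and site in self.temperature:
            return self.temperature[site]
        raise KeyError(name)


@dataclass
class CohortManifest:
    """Index of a cohort on disk: one (subject, recording, path) row per session."""

    entries: list[tuple[str, str, Path]] = field(default_factory=list)
    note: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def recording_ids(self) -> list[str]:
        return [rid for _, rid, _ in self.entries]


def validate_recording(rec: RawRecording) -> list[str]:
    """Check every invariant of a :class:`RawRecording`.

    Returns a list of human-readable issue descriptions, empty iff the
    recording is well formed.  Never raises.
    """
    issues: list[str] = []
    if not rec.fs > 0:
        issues.append(f"fs: must be positive, got {rec.fs}")
    for name, score in (("pain_start", rec.pain_start), ("pain_end", rec.pain_end)):
        if not isinstance(score, (int, np.integer)):
            issues.append(f"{name}: must be an integer, got {score!r}")
        elif not 0 <= int(score) <= 10:
            issues.append(f"{name}: must be in [0, 10], got {score}")
    expected = int(round(rec.fs * rec.duration_s)) if rec.fs > 0 else None
    for site in PULSE_SITES:
        if site not in rec.pulse:
            issues.append(f"pulse_{site}: channel missing")
    for site in TEMP_SITES:
        if site not in rec.temperature:
            issues.append(f"temp_{site}: channel missing")
    if expected is not None:
        for prefix, group in (("pulse", rec.pulse), ("temp", rec.temperature)):
            for site, sig in group.items():
                if len(sig) != expected:
                    issues.append(
                        f"{prefix}_{site}: length {len(sig)} != round(fs*duration_s) = {expected}"
                    )
    return issues


def write_recording(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording to ``path`` in the text format read by :func:`read_recording`.

    Values survive a round trip exactly (floats are written with shortest
    round-trip repr); two writes of the same recording are byte-identical.
    """
    issues = validate_recording(rec)
    if issues:
        raise RecordingValidationError("; ".join(issues))
    path = Path(path)
    n = rec.n_samples
    cols: dict[str, np.ndarray] = {"t": np.arange(n) / rec.fs}
    for site in PULSE_SITES:
        cols[f"pulse_{site}"] = np.asarray(rec.pulse[site], dtype=float)
    for site in TEMP_SITES:
        cols[f"temp_{site}"] = np.asarray(rec.temperature[site], dtype=float)
    body = pd.DataFrame(cols)
    buf = io.StringIO()
    for key in _HEADER_KEYS:
        buf.write(f"#{key}\t{getattr(rec, key)}\n")
    # %.17g guarantees exact float round-trip through text
    body.to_csv(buf, sep="\t", index=False, float_format="%.17g", lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_recording(path: str | Path) -> RawRecording:
    """Read one recording file; see the module docstring for the format."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].rstrip("\n").partition("\t")
            meta[key] = value
            pos = fh.tell()
        body = pd.read_csv(fh, sep="\t", float_precision="round_trip")

    missing_meta = [k for k in _HEADER_KEYS if k not in meta]
    if missing_meta:
        raise RecordingFormatError(f"{path}: missing header keys: {', '.join(missing_meta)}")
    for col in PULSE_COLUMNS + TEMP_COLUMNS:
        if col not in body.columns:
            raise RecordingFormatError(f"{path}: missing channel column {col}")
    if body.isna().any().any():
        raise RecordingValidationError(f"{path}: ragged or non-numeric channel columns")

    def _int_score(key: str) -> int:
        raw = meta[key]
        try:
            value = int(raw)
        except ValueError:
            raise RecordingValidationError(f"{path}: {key} must be an integer, got {raw!r}") from None
        if not 0 <= value <= 10:
            raise RecordingValidationError(f"{path}: {key} out of range [0, 10]: {value}")
        return value

    rec = RawRecording(
        subject_id=meta["subject_id"],
        recording_id=meta["recording_id"],
        fs=float(meta["fs"]),
        pulse={s: body[f"pulse_{s}"].to_numpy(dtype=float) for s in PULSE_SITES},
        temperature={s: body[f"temp_{s}"].to_numpy(dtype=float) for s in TEMP_SITES},
        pain_start=_int_score("pain_start"),
        pain_end=_int_score("pain_end"),
        duration_s=float(meta["duration_s"]),
    )
    issues = validate_recording(rec)
    if issues:
        raise RecordingValidationError(f"{path}: " + "; ".join(issues))
    return rec


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    rows = [{"subject_id": s, "recording_id": r, "path": str(p)} for s, r, p in manifest.entries]
    pd.DataFrame(rows, columns=["subject_id", "recording_id", "path"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        rid = row["recording_id"]
        if rid in seen:
            raise RecordingValidationError(f"{path}: duplicate recording_id {rid}")
        seen.add(rid)
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        entries.append((row["subject_id"], rid, p))
    return CohortManifest(entries=entries)


def iter_recordings(manifest: CohortManifest):
    """Yield ``RawRecording`` objects for every manifest entry, in order."""
    for _, rid, p in manifest.entries:
        if not Path(p).exists():
            raise FileNotFoundError(f"manifest entry {rid}: file not found: {p}")
        yield read_recording(p)
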