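"""Recording containers, on-disk formats and validity rules.

Accelerometry travels as CSV with a ``t,ax,ay,az`` header: ``t`` in seconds
since acquisition start, the three axes in g.  The body-frame convention is
the one the angle pipeline assumes: +X right→left, +Y toe→head, +Z
front→back, so gravity points along +Z when the wearer lies supine.

A flat output directory plus a JSON-lines registry file stand in for the
acquisition app's folder hierarchy: one registry entry per recording with
subject id, start time, duration and whether the raw file is still present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

G_PER_MS2 = 1.0 / 9.80665

MIN_RECORDING_SECONDS = 120.0  # acquisitions shorter than 2 min are discarded
LOW_RES_RATE_HZ = 0.2

__all__ = [
    "AccelRecording",
    "RecordingRegistry",
    "read_accel",
    "write_accel",
    "validate_recording",
    "write_low_res",
    "MIN_RECORDING_SECONDS",
    "LOW_RES_RATE_HZ",
]


@dataclass
class AccelRecording:
    """Timestamped triaxial acceleration, possibly non-uniformly sampled.

    ``t`` is strictly increasing, seconds from acquisition start; ``acc`` is
    an (n, 3) array of (ax, ay, az) in g.
    """

    t: np.ndarray
    acc: np.ndarray
    subject_id: str = ""
    start_datetime: datetime | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must have shape (n, 3)")
        if self.t.shape[0] != self.acc.shape[0]:
            raise ValueError("t and acc length mismatch")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.acc))):
            raise ValueError("non-finite sample values")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Seconds between first and last sample (0 for <2 samples)."""
        return float(self.t[-1] - self.t[0]) if self.t.size >= 2 else 0.0

    @property
    def ax(self) -> np.ndarray:
        return self.acc[:, 0]

    @property
    def ay(self) -> np.ndarray:
        return self.acc[:, 1]

    @property
    def az(self) -> np.ndarray:
        return self.acc[:, 2]

    def sampling_interval(self) -> float | None:
        """The uniform sampling interval, or None if not uniform."""
        if self.t.size < 2:
            return None
        dt = np.diff(self.t)
        return float(dt[0]) if np.allclose(dt, dt[0], rtol=0, atol=1e-6) else None

    def scaled(self, k: float) -> "AccelRecording":
        return replace(self, acc=self.acc * float(k))


def read_accel(path, units: str = "g", subject_id: str | None = None) -> AccelRecording:
    """Read an accelerometry CSV (``t,ax,ay,az`` header).

    Samples are returned sorted by ``t``; duplicate timestamps are collapsed
    keeping the last occurrence.  ``units="ms2"`` divides by 9.80665 — the
    downstream angle formula is scale invariant, so this only matters for
    magnitude-based checks.

    Raises ``ValueError`` naming the offending line for malformed rows, and
    for an empty file.
    """
    path = Path(path)
    if units not in ("g", "ms2"):
        raise ValueError(f"units must be 'g' or 'ms2', got {units!r}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        raise ValueError(f"{path}: empty accelerometry file")
    header = [c.strip().lower() for c in rows[0][1].split(",")]
    if header[:4] != ["t", "ax", "ay", "az"]:
        raise ValueError(f"{path}: line 1: expected header 't,ax,ay,az', got {rows[0][1]!r}")
    data = np.empty((len(rows) - 1, 4), dtype=float)
    for k, (lineno, ln) in enumerate(rows[1:]):
        cells = ln.split(",")
        if len(cells) < 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 fields, got {len(cells)}")
        try:
            data[k] = [float(c) for c in cells[:4]]
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
    if data.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    # collapse duplicate timestamps, keeping the last occurrence
    keep = np.ones(data.shape[0], dtype=bool)
    keep[:-1] = np.diff(data[:, 0]) > 0
    data = data[keep]
    acc = data[:, 1:4] * (G_PER_MS2 if units == "ms2" else 1.0)
    return AccelRecording(t=data[:, 0], acc=acc, subject_id=subject_id or path.stem)


def write_accel(rec: AccelRecording, path) -> Path:
    """Write a recording in the ``t,ax,ay,az`` CSV dialect (round-trips with
    :func:`read_accel` to well below 1e-6 g / 1e-3 s)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"t": rec.t, "ax": rec.ax, "ay": rec.ay, "az": rec.az})
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def validate_recording(rec: AccelRecording) -> bool:
    """Acceptance rule for a recording: at least 2 min of data (inclusive)."""
    return rec.duration >= MIN_RECORDING_SECONDS


def write_low_res(rec: AccelRecording, out) -> Path:
    """Down-sample a uniform recording to 0.2 Hz and write it as CSV.

    Takes the sample nearest each 5-s grid point t = 0, 5, ... up to the
    recording's end; intended for visualisation, so no anti-alias filter is
    applied (the series is already 60-s median filtered upstream).
    """
    if rec.n_samples == 0:
        raise ValueError("cannot down-sample an empty recording")
    if rec.n_samples > 1 and rec.sampling_interval() is None:
        raise ValueError("write_low_res requires a uniformly sampled recording")
    step = 1.0 / LOW_RES_RATE_HZ
    grid = np.arange(0.0, rec.t[-1] + 1e-9, step)
    idx = np.clip(np.searchsorted(rec.t, grid), 0, rec.n_samples - 1)
    idx_prev = np.clip(idx - 1, 0, rec.n_samples - 1)
    nearer_prev = np.abs(rec.t[idx_prev] - grid) <= np.abs(rec.t[idx] - grid)
    idx = np.where(nearer_prev, idx_prev, idx)
    sub = AccelRecording(t=grid, acc=rec.acc[idx], subject_id=rec.subject_id,
                         start_datetime=rec.start_datetime)
    return write_accel(sub, out)


@dataclass
class RegistryEntry:
    subject_id: str
    start_datetime: str
    duration_minutes: float
    raw_available: bool


@dataclass
class RecordingRegistry:
    """Register of performed recordings, persisted as JSON lines."""

    entries: list[RegistryEntry] = field(default_factory=list)

    def add(self, rec: AccelRecording, raw_available: bool = True) -> None:
        start = rec.start_datetime.isoformat() if rec.start_datetime else ""
        self.entries.append(
            RegistryEntry(rec.subject_id, start, rec.duration / 60.0, raw_available)
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(vars(e)) + "\n")
        return path

    @classmethod
    def load(cls, path) -> "RecordingRegistry":
        entries = []
        with open(path) as fh:
            for ln in fh:
                if ln.strip():
                    entries.append(RegistryEntry(**json.loads(ln)))
        return cls(entries=entries)
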