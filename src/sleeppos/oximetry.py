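"""Pulse-oximetry handling: SpO2 series, desaturation events, ODI.

A desaturation event is a drop of at least 3 percentage points below the
local baseline, with the nadir reached within 120 s of leaving the baseline.
The baseline is the running maximum of SpO2 over the 30 s preceding the
start of the fall — standard scoring practice; the published definition
("the baseline prior to this drop") does not pin the window down, so it is
configurable.  An event ends when saturation recovers to within 1 point of
its baseline, or when a new qualifying fall begins.

ODI (oxygen desaturation index) is events per hour of sleep, graded with
the AASM severity bands applied to ODI: < 5 healthy, 5–15 mild, 15–30
moderate, ≥ 30 severe (lower edges inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MIN_DROP_PERCENT = 3.0
MAX_FALL_SECONDS = 120.0
BASELINE_WINDOW_SECONDS = 30.0
RECOVERY_MARGIN_PERCENT = 1.0
SPO2_RANGE = (50.0, 100.0)
GAP_FLAG_SECONDS = 10.0

SEVERITY_THRESHOLDS = (5.0, 15.0, 30.0)
SEVERITY_NAMES = ("Healthy", "Mild", "Moderate", "Severe")

__all__ = [
    "SpO2Series",
    "DesatEvent",
    "OdiResult",
    "read_spo2",
    "detect_desaturations",
    "compute_odi",
    "classify_severity",
    "write_events",
    "read_events",
]


@dataclass
class SpO2Series:
    """Timestamped SpO2 in percent; ~1 Hz, possibly with gaps.

    Values outside [50, 100] are clipped and flagged in ``suspect``;
    sampling gaps longer than 10 s are flagged on the sample after the gap.
    """

    t: np.ndarray
    spo2: np.ndarray
    suspect: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        raw = np.asarray(self.spo2, dtype=float)
        if self.t.size != raw.size:
            raise ValueError("t and spo2 length mismatch")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        out_of_range = (raw < SPO2_RANGE[0]) | (raw > SPO2_RANGE[1])
        gap = np.zeros(self.t.shape, dtype=bool)
        if self.t.size > 1:
            gap[1:] = np.diff(self.t) > GAP_FLAG_SECONDS
        self.spo2 = np.clip(raw, *SPO2_RANGE)
        if self.suspect is None:
            self.suspect = out_of_range | gap
        self.suspect = np.asarray(self.suspect, dtype=bool)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size >= 2 else 0.0


@dataclass
class DesatEvent:
    """One oxygen desaturation episode."""

    t_baseline: float
    t_nadir: float
    t_end: float
    baseline: float
    nadir: float
    assigned_angle: float | None = None

    @property
    def depth(self) -> float:
        return self.baseline - self.nadir

    def __post_init__(self) -> None:
        if not (self.t_baseline < self.t_nadir <= self.t_end):
            raise ValueError("event times must satisfy t_baseline < t_nadir <= t_end")


@dataclass
class OdiResult:
    event_count: int
    sleep_hours: float
    odi: float
    severity: str

    def to_dict(self) -> dict:
        return {"event_count": self.event_count, "sleep_hours": self.sleep_hours,
                "odi": self.odi, "severity": self.severity}


def read_spo2(path) -> SpO2Series:
    """Read an SpO2 CSV with header ``t,spo2`` (t seconds, spo2 percent)."""
    df = pd.read_csv(path)
    if not {"t", "spo2"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 't,spo2'")
    return SpO2Series(t=df["t"].to_numpy(float), spo2=df["spo2"].to_numpy(float))


def write_spo2(series: SpO2Series, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t": series.t, "spo2": series.spo2}).to_csv(
        path, index=False, float_format="%.3f")
    return path


def detect_desaturations(
    series: SpO2Series,
    min_drop: float = MIN_DROP_PERCENT,
    max_fall: float = MAX_FALL_SECONDS,
    baseline_window: float = BASELINE_WINDOW_SECONDS,
    recovery_margin: float = RECOVERY_MARGIN_PERCENT,
) -> list[DesatEvent]:
    """Scan an SpO2 series for desaturation events.

    A candidate starts at any sample where the signal begins to fall; its
    baseline is the running maximum over the preceding ``baseline_window``
    seconds.  The candidate qualifies if saturation reaches
    ``baseline - min_drop`` (inclusive) within ``max_fall`` seconds; the
    nadir is the minimum over that window, and the event runs until recovery
    to ``baseline - recovery_margin`` (or the end of the series).  Scanning
    resumes after the event, so returned events never overlap.
    """
    t, x = series.t, series.spo2
    n = t.size
    if n == 0:
        raise ValueError("empty SpO2 series")
    events: list[DesatEvent] = []
    # running max over the preceding baseline_window (inclusive of current sample)
    s = pd.Series(x, index=pd.to_timedelta(t, unit="s"))
    run_max = s.rolling(f"{baseline_window}s", min_periods=1).max().to_numpy()

    i = 0
    while i < n - 1:
        if x[i + 1] >= x[i]:  # not the start of a fall
            i += 1
            continue
        baseline = run_max[i]
        j_hi = int(np.searchsorted(t, t[i] + max_fall, side="right"))
        window = x[i + 1 : j_hi]
        qual = np.flatnonzero(baseline - window >= min_drop)
        if qual.size == 0:
            i += 1
            continue
        # the event runs from the first qualifying sample to recovery within
        # recovery_margin of baseline; its nadir is the minimum over that run,
        # so back-to-back fall/recovery cycles score as separate events
        qual_idx = i + 1 + int(qual[0])
        end_idx = qual_idx
        while end_idx + 1 < n and x[end_idx + 1] < baseline - recovery_margin:
            end_idx += 1
        end_idx = min(end_idx + 1, n - 1)
        nadir_idx = qual_idx + int(np.argmin(x[qual_idx : end_idx + 1]))
        # anchor the onset at the actual departure from baseline, not at the
        # first noise downtick that exposed the fall
        onset = qual_idx
        while onset - 1 >= i and x[onset - 1] < baseline - recovery_margin / 2.0:
            onset -= 1
        onset = max(onset - 1, i)
        events.append(
            DesatEvent(
                t_baseline=float(t[onset]),
                t_nadir=float(t[nadir_idx]),
                t_end=float(t[end_idx]),
                baseline=float(baseline),
                nadir=float(x[nadir_idx]),
            )
        )
        i = end_idx + 1
    return events


def classify_severity(odi: float) -> str:
    """AASM-derived severity band for an ODI value (events/hour)."""
    if odi < SEVERITY_THRESHOLDS[0]:
        return SEVERITY_NAMES[0]
    if odi < SEVERITY_THRESHOLDS[1]:
        return SEVERITY_NAMES[1]
    if odi < SEVERITY_THRESHOLDS[2]:
        return SEVERITY_NAMES[2]
    return SEVERITY_NAMES[3]


def compute_odi(events, sleep_hours: float) -> OdiResult:
    """ODI and severity from an event list (or count) and sleep hours."""
    if sleep_hours <= 0:
        raise ValueError("sleep_hours must be positive")
    count = events if isinstance(events, int) else len(events)
    odi = count / sleep_hours
    return OdiResult(event_count=count, sleep_hours=sleep_hours, odi=odi,
                     severity=classify_severity(odi))


_EVENT_COLS = ["t_baseline", "t_nadir", "t_end", "baseline", "nadir", "depth"]


def write_events(events: list[DesatEvent], path) -> Path:
    """Events CSV: ``t_baseline,t_nadir,t_end,baseline,nadir,depth``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [[e.t_baseline, e.t_nadir, e.t_end, e.baseline, e.nadir, e.depth] for e in events]
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, index=False, float_format="%.3f")
    return path


def read_events(path) -> list[DesatEvent]:
    """Ingest a pre-scored event CSV (e.g. an oximeter's native event list)."""
    df = pd.read_csv(path)
    missing = {"t_baseline", "t_nadir", "t_end", "baseline", "nadir"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DesatEvent(
            t_baseline=float(r.t_baseline), t_nadir=float(r.t_nadir), t_end=float(r.t_end),
            baseline=float(r.baseline), nadir=float(r.nadir),
        )
        for r in df.itertuples()
    ]
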