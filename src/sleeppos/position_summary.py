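"""Discrete sleep-position labels and per-night summary statistics.

The continuous sleep angle is quantised into the four clinical positions by
quadrants centred on the pure orientations (left 0°, supine 90°, right
±180°, prone −90°), i.e. boundaries at ±45° and ±135°, half-open towards
the next quadrant.  The stand angle separates laying (±90°) from upright
(±180°) postures at the midpoint |stand| = 135°; a headstand-like reading
(|stand| < 45°) cannot be a laying posture and is likewise binned as
standing (and logged — on real data it means the device is mounted wrong).

Per-position angle statistics use circular mean and circular standard
deviation: the right-lateral position straddles the ±180° wrap, where
arithmetic moments are meaningless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import circ_mean, circ_std
from .orientation import AngleSeries

logger = logging.getLogger(__name__)

STANDING_THRESHOLD_DEG = 135.0
HEADSTAND_THRESHOLD_DEG = 45.0
DEFAULT_MIN_DWELL_SECONDS = 30.0

__all__ = [
    "PositionLabel",
    "PositionStats",
    "classify_sample",
    "classify_series",
    "laying_mask",
    "summarize",
    "count_shifts",
    "percentages",
]


class PositionLabel(Enum):
    LEFT = "left"
    SUPINE = "supine"
    RIGHT = "right"
    PRONE = "prone"
    STANDING = "standing"
    INVALID = "invalid"


SLEEP_LABELS = (PositionLabel.LEFT, PositionLabel.SUPINE, PositionLabel.RIGHT, PositionLabel.PRONE)

# integer codes used in vectorised classification
_CODE = {lab: i for i, lab in enumerate(
    [PositionLabel.LEFT, PositionLabel.SUPINE, PositionLabel.RIGHT,
     PositionLabel.PRONE, PositionLabel.STANDING, PositionLabel.INVALID])}
_LABELS = list(_CODE)


def classify_codes(sleep: np.ndarray, stand: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Vectorised classification; returns integer codes indexing ``_LABELS``."""
    sleep = np.asarray(sleep, dtype=float)
    stand = np.asarray(stand, dtype=float)
    out = np.full(sleep.shape, _CODE[PositionLabel.INVALID], dtype=np.int8)
    ok = np.isfinite(sleep) & np.isfinite(stand)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    abs_stand = np.abs(stand)
    standing = ok & ((abs_stand >= STANDING_THRESHOLD_DEG) | (abs_stand < HEADSTAND_THRESHOLD_DEG))
    if np.any(ok & (abs_stand < HEADSTAND_THRESHOLD_DEG)):
        logger.warning("headstand-like stand angles found; binned as standing")
    laying = ok & ~standing
    out[standing] = _CODE[PositionLabel.STANDING]
    out[laying & (sleep >= -45.0) & (sleep < 45.0)] = _CODE[PositionLabel.LEFT]
    out[laying & (sleep >= 45.0) & (sleep < 135.0)] = _CODE[PositionLabel.SUPINE]
    out[laying & ((sleep >= 135.0) | (sleep < -135.0))] = _CODE[PositionLabel.RIGHT]
    out[laying & (sleep >= -135.0) & (sleep < -45.0)] = _CODE[PositionLabel.PRONE]
    return out


def classify_sample(sleep: float, stand: float) -> PositionLabel:
    """Label a single (sleep, stand) angle pair."""
    code = classify_codes(np.asarray([sleep]), np.asarray([stand]))[0]
    return _LABELS[code]


def classify_series(series: AngleSeries) -> np.ndarray:
    """Array of :class:`PositionLabel` codes for every sample of a series."""
    return classify_codes(series.sleep_angle, series.stand_angle, series.valid)


def laying_mask(series: AngleSeries) -> np.ndarray:
    """Boolean mask of valid laying samples (one of the four sleep labels)."""
    codes = classify_series(series)
    return codes <= _CODE[PositionLabel.PRONE]


@dataclass
class PositionStats:
    """Per-night discrete position summary (the clinical summary table).

    Minutes and percent-of-laying-time per sleep position, circular mean /
    SD of the sleep angle within each position, plus laying and standing
    totals.  Percentages are NaN when there is no laying time.
    """

    minutes: dict = field(default_factory=dict)
    percent: dict = field(default_factory=dict)
    mean_angle: dict = field(default_factory=dict)
    sd_angle: dict = field(default_factory=dict)
    laying_minutes: float = 0.0
    laying_percent: float = float("nan")
    standing_minutes: float = 0.0
    standing_percent: float = float("nan")
    invalid_minutes: float = 0.0
    total_minutes: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": lab.value,
                "minutes": self.minutes[lab.value],
                "percent": self.percent[lab.value],
                "mean_angle": self.mean_angle[lab.value],
                "sd_angle": self.sd_angle[lab.value],
            }
            for lab in SLEEP_LABELS
        ]
        rows.append({"position": "laying", "minutes": self.laying_minutes,
                     "percent": self.laying_percent, "mean_angle": np.nan, "sd_angle": np.nan})
        rows.append({"position": "standing", "minutes": self.standing_minutes,
                     "percent": self.standing_percent, "mean_angle": np.nan, "sd_angle": np.nan})
        return pd.DataFrame(rows)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "minutes": self.minutes,
            "percent": self.percent,
            "mean_angle": self.mean_angle,
            "sd_angle": self.sd_angle,
            "laying_minutes": self.laying_minutes,
            "laying_percent": self.laying_percent,
            "standing_minutes": self.standing_minutes,
            "standing_percent": self.standing_percent,
            "invalid_minutes": self.invalid_minutes,
            "total_minutes": self.total_minutes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
        return path


def percentages(minutes: dict[str, float]) -> dict[str, float]:
    """Percent of laying time for a mapping of per-position minutes.

    This is the arithmetic behind the summary table's ``%`` columns: each
    position's minutes over the summed laying minutes, × 100.
    """
    total = float(sum(minutes.values()))
    if total <= 0:
        return {k: float("nan") for k in minutes}
    return {k: 100.0 * v / total for k, v in minutes.items()}


def summarize(series: AngleSeries) -> PositionStats:
    """Discrete summary of a classified angle series.

    Minutes are sample counts × the sampling interval; position percentages
    are relative to laying time; X̄/σX are circular statistics of the sleep
    angles carrying each label.
    """
    codes = classify_series(series)
    dt_min = series.dt / 60.0
    stats = PositionStats()
    laying_min = 0.0
    for lab in SLEEP_LABELS:
        sel = codes == _CODE[lab]
        mins = float(np.sum(sel)) * dt_min
        stats.minutes[lab.value] = mins
        laying_min += mins
        angles = series.sleep_angle[sel]
        stats.mean_angle[lab.value] = circ_mean(angles) if angles.size else float("nan")
        stats.sd_angle[lab.value] = circ_std(angles) if angles.size else float("nan")
    stats.laying_minutes = laying_min
    stats.standing_minutes = float(np.sum(codes == _CODE[PositionLabel.STANDING])) * dt_min
    stats.invalid_minutes = float(np.sum(codes == _CODE[PositionLabel.INVALID])) * dt_min
    stats.total_minutes = series.n_samples * dt_min
    stats.percent = percentages(stats.minutes)
    worn = stats.laying_minutes + stats.standing_minutes
    if worn > 0:
        stats.laying_percent = 100.0 * stats.laying_minutes / worn
        stats.standing_percent = 100.0 * stats.standing_minutes / worn
    return stats


def count_shifts(series: AngleSeries, min_dwell: float = DEFAULT_MIN_DWELL_SECONDS) -> int:
    """Number of position changes between consecutive laying samples.

    Runs shorter than ``min_dwell`` seconds are treated as transition
    artifacts: they are dropped before counting, and surviving consecutive
    runs with equal labels are merged.  Standing/invalid stretches separate
    laying segments without themselves counting as shifts.
    """
    codes = classify_series(series)
    lay = codes <= _CODE[PositionLabel.PRONE]
    lay_codes = codes[lay]
    if lay_codes.size == 0:
        return 0
    # run-length encode
    change = np.flatnonzero(np.diff(lay_codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [lay_codes.size]))
    min_samples = max(1, int(round(min_dwell / series.dt)))
    labels = [lay_codes[s] for s, e in zip(starts, ends) if e - s >= min_samples]
    if not labels:
        return 0
    merged = [labels[0]]
    for lab in labels[1:]:
        if lab != merged[-1]:
            merged.append(lab)
    return len(merged) - 1
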