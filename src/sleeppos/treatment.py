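"""Supine-avoidance vibration scheduling.

While the wearer lies in the supine quadrant, the device emits a 300 ms
vibration pulse every 3 s, starting the moment the supine bout begins and
stopping when it ends.  Pulses are suppressed while standing (an upright
posture with a supine-like sleep angle is not a sleep position).  A grace
period can delay the first pulse after entering supine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .orientation import AngleSeries
from .position_summary import PositionLabel, _CODE, classify_series

PULSE_DURATION_SECONDS = 0.3
PULSE_PERIOD_SECONDS = 3.0

__all__ = ["VibrationPulse", "vibration_schedule", "write_schedule"]


@dataclass
class VibrationPulse:
    t_start: float
    duration: float = PULSE_DURATION_SECONDS


def supine_bouts(series: AngleSeries) -> list[tuple[float, float]]:
    """Maximal runs of SUPINE-labelled laying samples as (start, duration)."""
    codes = classify_series(series)
    sup = codes == _CODE[PositionLabel.SUPINE]
    if not np.any(sup):
        return []
    edges = np.flatnonzero(np.diff(sup.astype(int)))
    starts = list(edges[sup[edges + 1]] + 1)
    ends = list(edges[~sup[edges + 1]] + 1)
    if sup[0]:
        starts.insert(0, 0)
    if sup[-1]:
        ends.append(sup.size)
    dt = series.dt
    return [(float(series.t[s]), (e - s) * dt) for s, e in zip(starts, ends)]


def vibration_schedule(
    series: AngleSeries,
    period: float = PULSE_PERIOD_SECONDS,
    pulse_duration: float = PULSE_DURATION_SECONDS,
    grace: float = 0.0,
) -> list[VibrationPulse]:
    """Pulse train for every supine bout of a classified angle series.

    Within a bout of duration ``d`` starting at ``t0``, pulses fire at
    ``t0 + grace + k·period`` for every offset not exceeding ``d`` —
    ``floor((d - grace)/period) + 1`` pulses per bout with the default zero
    grace.  All-lateral nights yield an empty schedule.
    """
    pulses: list[VibrationPulse] = []
    for t0, d in supine_bouts(series):
        if d < grace:
            continue
        k = int(np.floor((d - grace) / period + 1e-9))
        pulses.extend(
            VibrationPulse(t_start=t0 + grace + i * period, duration=pulse_duration)
            for i in range(k + 1)
        )
    return pulses


def write_schedule(pulses: list[VibrationPulse], path) -> Path:
    """Schedule CSV ``t_start,duration``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([[p.t_start, p.duration] for p in pulses],
                 columns=["t_start", "duration"]).to_csv(path, index=False,
                                                         float_format="%.3f")
    return path
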