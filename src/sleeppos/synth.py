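"""Seeded generator of realistic nights with full ground truth.

The generator emulates the data a sternum-worn accelerometer plus a finger
pulse oximeter would produce over one night:

* **Posture** follows a semi-Markov chain over the four sleep positions
  (left / supine / right / prone) with log-normal dwell times and, per
  bout, a von-Mises draw of the actual trunk angle around the position's
  pure orientation, plus a slowly varying within-bout wobble.  Untreated
  nights open with a supine bout of at least 12 min at exactly 90° — the
  posture the calibration step assumes.  Optional standing bouts are
  inserted at bout boundaries.
* **Accelerometry** inverts the angle formula: a target sleep angle φ and
  stand angle ψ become the unit gravity vector ``(cos φ, Z·cotψ, sin φ)``
  (normalised), standing bouts become −Y-dominant vectors; Gaussian sensor
  noise is added per axis, and timestamps jitter uniformly ±20 ms around
  the 100 ms grid, emulating a non-uniform ~10 Hz sensor.
* **SpO2** is a 97 % baseline with AR(1) noise at 1 Hz.  Desaturation
  events arrive as a Poisson process whose rate depends on the current
  position label; each event is a trapezoidal dip (linear descent, plateau,
  linear recovery) of depth ≥ 4 points.  An arrival occurring before the
  previous dip has recovered is deferred until recovery — successive
  obstructive events cannot overlap physiologically — so at high rates the
  trace cycles continuously, as severe sleep apnea does.
* **Treatment** models vibro-tactile supine avoidance: during a treated
  supine bout the wearer responds with per-vibration-minute probability
  ``compliance`` and then leaves supine after a short log-normal latency,
  truncating the bout.

Identical ``(model, duration, seed, treated)`` inputs give byte-identical
outputs; the returned :class:`GroundTruth` records every planted interval,
event and vibration response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.signal import lfilter

from .circular import circ_mean, wrap_angle
from .io_core import AccelRecording, write_accel
from .oximetry import SpO2Series, write_spo2

LABELS = ("left", "supine", "right", "prone")
PURE_CENTERS = {"left": 0.0, "supine": 90.0, "right": 180.0, "prone": -90.0}
STANDING = "standing"

ACCEL_RATE_HZ = 10.0
SPO2_RATE_HZ = 1.0
CALIBRATION_BOUT_MIN_S = 720.0  # first supine bout covers the 10-min window
EVENT_GUARD_S = 5.0             # re-saturation hold between consecutive dips

__all__ = [
    "SubjectModel",
    "GroundTruth",
    "SimulationResult",
    "simulate_night",
    "cohort",
    "default_cohort",
    "severity_preset",
]


def _default_jitter() -> dict:
    return {"left": 12.0, "supine": 8.0, "right": 12.0, "prone": 10.0}


def _default_rates() -> dict:
    return {"left": 5.0, "supine": 20.0, "right": 5.0, "prone": 5.0}


@dataclass
class SubjectModel:
    """Everything that varies between simulated subjects.

    Angle jitter is the per-bout von-Mises spread (degrees) around each
    position's pure orientation; dwell times are log-normal in minutes;
    the transition matrix defaults to uniform over the other three
    positions; desaturation rates are events/hour while in each position.
    """

    subject_id: str = "synthetic"
    position_jitter: dict = field(default_factory=_default_jitter)
    dwell_median_minutes: float = 20.0
    dwell_log_sigma: float = 0.6
    transition: dict | None = None
    desat_rates: dict = field(default_factory=_default_rates)
    desat_depth_range: tuple = (4.0, 8.0)
    descent_range: tuple = (20.0, 90.0)
    plateau_range: tuple = (0.0, 20.0)
    recovery_range: tuple = (10.0, 60.0)
    noise_sigma: float = 0.02            # g per axis
    timestamp_jitter: float = 0.02       # s, uniform around the 100 ms grid
    wobble_sigma: float = 1.0            # degrees, slow within-bout wander
    stand_jitter: float = 4.0            # degrees, per-bout stand-angle offset
    spo2_baseline: float = 97.0
    spo2_sigma: float = 0.3
    spo2_ar: float = 0.9
    compliance: float = 0.9              # P(respond) per vibration minute
    response_latency_median_s: float = 10.0
    response_latency_log_sigma: float = 0.5
    standing_bouts: int = 2
    standing_duration_s: float = 120.0
    mount_roll_deg: float = 0.0          # device rotation about the body axis
    mount_pitch_deg: float = 0.0

    def transition_row(self, label: str) -> dict:
        if self.transition is not None:
            row = self.transition[label]
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"transition row for {label!r} does not sum to 1")
            return row
        others = [l for l in LABELS if l != label]
        return {l: 1.0 / len(others) for l in others}


@dataclass
class TruthInterval:
    t_start: float
    t_end: float
    label: str
    angle: float  # bout centre (sleep angle); NaN while standing


@dataclass
class TruthEvent:
    t_start: float
    t_nadir: float      # end of the descent ramp
    t_recover: float    # end of the nadir plateau / start of recovery
    t_end: float
    depth: float
    label: str
    angle: float  # circular mean planted sleep angle over the event


@dataclass
class VibrationResponse:
    bout_start: float
    planned_dwell: float
    actual_dwell: float
    responded: bool


@dataclass
class GroundTruth:
    """Complete description of what one simulated night planted."""

    duration_s: float
    intervals: list
    events: list
    vibration_log: list
    t: np.ndarray                # nominal 10 Hz grid
    sleep_angle: np.ndarray      # planted calibrated-frame sleep angle (NaN standing)
    stand_angle: np.ndarray
    labels: np.ndarray           # per-sample label strings
    seed: int = 0
    treated: bool = False

    def minutes_per_label(self) -> dict:
        out = {}
        for lab in LABELS + (STANDING,):
            out[lab] = sum(
                (iv.t_end - iv.t_start) for iv in self.intervals if iv.label == lab
            ) / 60.0
        return out

    def supine_percent(self) -> float:
        mins = self.minutes_per_label()
        laying = sum(mins[l] for l in LABELS)
        return 100.0 * mins["supine"] / laying if laying else float("nan")

    def manifest_entry(self) -> dict:
        return {
            "seed": self.seed,
            "treated": self.treated,
            "duration_hours": self.duration_s / 3600.0,
            "minutes_per_label": self.minutes_per_label(),
            "n_events": len(self.events),
            "event_times": [e.t_start for e in self.events],
        }


class SimulationResult(NamedTuple):
    accel: AccelRecording
    spo2: SpO2Series
    truth: GroundTruth


# ---------------------------------------------------------------------------
# posture sequence


def _draw_dwell(model: SubjectModel, rng) -> float:
    return float(
        60.0 * np.exp(np.log(model.dwell_median_minutes)
                      + model.dwell_log_sigma * rng.standard_normal())
    )


def _draw_bout_angle(model: SubjectModel, label: str, rng) -> float:
    sigma = model.position_jitter[label]
    kappa = (180.0 / (np.pi * sigma)) ** 2  # von Mises kappa ≈ 1/σ_rad²
    return wrap_angle(PURE_CENTERS[label] + np.degrees(rng.vonmises(0.0, kappa)))


def _next_label(model: SubjectModel, current: str, rng) -> str:
    row = model.transition_row(current)
    labels = sorted(row)
    return str(rng.choice(labels, p=[row[l] for l in labels]))


def _supine_leave_time(model: SubjectModel, rng) -> tuple[float, bool]:
    """Seconds until the wearer leaves supine under vibration."""
    minutes = int(rng.geometric(model.compliance))
    latency = float(
        np.exp(np.log(model.response_latency_median_s)
               + model.response_latency_log_sigma * rng.standard_normal())
    )
    return 60.0 * minutes + latency, True


def _build_intervals(model: SubjectModel, duration_s: float, treated: bool, rng):
    intervals: list[TruthInterval] = []
    vibration_log: list[VibrationResponse] = []
    t = 0.0
    label = "supine" if not treated else str(rng.choice(LABELS))
    first = True
    while t < duration_s:
        dwell = _draw_dwell(model, rng)
        if first and not treated:
            dwell = max(dwell, CALIBRATION_BOUT_MIN_S)
            angle = PURE_CENTERS["supine"]  # the instructed calibration posture
        else:
            angle = _draw_bout_angle(model, label, rng)
        if treated and label == "supine":
            leave, _ = _supine_leave_time(model, rng)
            actual = min(dwell, leave)
            vibration_log.append(VibrationResponse(t, dwell, actual, leave < dwell))
            dwell = actual
        intervals.append(TruthInterval(t, min(t + dwell, duration_s), label, angle))
        t += dwell
        label = _next_label(model, label, rng)
        first = False
    # standing bouts inserted at random bout boundaries (never before the
    # calibration bout); they push later intervals back and the tail is clipped
    if model.standing_bouts and len(intervals) > 1:
        cuts = rng.choice(np.arange(1, len(intervals)), size=min(model.standing_bouts,
                                                                 len(intervals) - 1),
                          replace=False)
        for ci in sorted(cuts, reverse=True):
            intervals.insert(int(ci), TruthInterval(0.0, model.standing_duration_s,
                                                    STANDING, float("nan")))
        t = 0.0
        rebuilt = []
        for iv in intervals:
            d = (iv.t_end - iv.t_start) if iv.label != STANDING else model.standing_duration_s
            if t >= duration_s:
                break
            rebuilt.append(TruthInterval(t, min(t + d, duration_s), iv.label, iv.angle))
            t += d
        intervals = rebuilt
    return intervals, vibration_log


# ---------------------------------------------------------------------------
# signal synthesis


def _ar1(n: int, phi: float, sigma: float, rng) -> np.ndarray:
    innov = rng.standard_normal(n) * sigma * np.sqrt(max(1.0 - phi**2, 1e-12))
    x = lfilter([1.0], [1.0, -phi], innov)
    return np.asarray(x)


def _angle_timeline(model: SubjectModel, intervals, duration_s: float, rng):
    n = int(round(duration_s * ACCEL_RATE_HZ))
    t = np.arange(n) / ACCEL_RATE_HZ
    starts = np.array([iv.t_start for iv in intervals])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(intervals) - 1)
    centres = np.array([iv.angle for iv in intervals])
    labels = np.array([iv.label for iv in intervals])
    lab = labels[idx]
    laying = lab != STANDING
    # slow within-bout wander, correlation time ~30 s
    phi = float(np.exp(-1.0 / (ACCEL_RATE_HZ * 30.0)))
    wobble = _ar1(n, phi, model.wobble_sigma, rng)
    sleep = np.where(laying, wrap_angle(centres[idx] + wobble), np.nan)
    # per-bout stand-angle offset around the laying (±90°) / standing (±177°) poses
    stand_off = rng.normal(0.0, model.stand_jitter, size=len(intervals))
    stand = np.empty(n)
    sign_z = np.where(np.sin(np.deg2rad(np.where(laying, sleep, 0.0))) < 0, -1.0, 1.0)
    stand[laying] = (sign_z * 90.0 + stand_off[idx])[laying]
    stand[~laying] = (177.0 + stand_off[idx])[~laying]
    stand = wrap_angle(stand)
    return t, sleep, stand, lab


def _rotation(model: SubjectModel) -> np.ndarray:
    roll = np.deg2rad(model.mount_roll_deg)   # about the body's Y (toe→head) axis
    pitch = np.deg2rad(model.mount_pitch_deg)  # about the X (right→left) axis
    ry = np.array([[np.cos(roll), 0, np.sin(roll)],
                   [0, 1, 0],
                   [-np.sin(roll), 0, np.cos(roll)]])
    rx = np.array([[1, 0, 0],
                   [0, np.cos(pitch), -np.sin(pitch)],
                   [0, np.sin(pitch), np.cos(pitch)]])
    return rx @ ry


def _accelerometry(model: SubjectModel, t, sleep, stand, lab, rng) -> AccelRecording:
    n = t.size
    laying = lab != STANDING
    phi = np.deg2rad(np.where(laying, sleep, 0.0))
    psi = np.deg2rad(stand)
    x = np.where(laying, np.cos(phi), 0.05)
    z = np.where(laying, np.sin(phi), np.sin(psi))
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(laying, z * np.cos(psi) / np.sin(psi), np.cos(psi))
    v = np.column_stack([x, y, z])
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if model.mount_roll_deg or model.mount_pitch_deg:
        v = v @ _rotation(model).T
    v += rng.normal(0.0, model.noise_sigma, size=(n, 3))
    tj = t + rng.uniform(-model.timestamp_jitter, model.timestamp_jitter, size=n)
    tj[0] = 0.0
    tj = np.maximum.accumulate(tj + np.arange(n) * 1e-9)  # guard monotonicity
    return AccelRecording(t=tj, acc=v, subject_id=model.subject_id)


def _mean_episode_s(model: SubjectModel) -> float:
    return (np.mean(model.descent_range) + np.mean(model.plateau_range)
            + np.mean(model.recovery_range)) + EVENT_GUARD_S


def _plant_events(model: SubjectModel, intervals, duration_s, sleep, lab, rng):
    """Non-overlapping desaturation episodes at the per-label planted rates.

    Episodes are a modulated renewal process: after each episode (plus a
    short re-saturation guard) the gap to the next onset is exponential
    with mean ``3600/rate − mean episode length``, so the realized onset
    rate per hour spent in a label matches the planted rate even when the
    trace cycles nearly continuously.  Episodes never overlap — a new
    obstruction cannot begin before the previous one has recovered.
    """
    events: list[TruthEvent] = []
    ep_mean = _mean_episode_s(model)
    bounds = [(iv.t_start, iv.t_end, iv.label) for iv in intervals]
    k = 0
    pos = 0.0
    while pos < duration_s - EVENT_GUARD_S and k < len(bounds):
        t0, t1, label = bounds[k]
        if pos >= t1:
            k += 1
            continue
        rate = model.desat_rates.get(label, 0.0) if label != STANDING else 0.0
        if rate <= 0:
            pos = t1
            k += 1
            continue
        mean_gap = max(3600.0 / rate - ep_mean, 1.0)
        start = max(pos, t0) + rng.exponential(mean_gap)
        if start >= t1:
            pos = t1  # exponential gaps are memoryless: redraw in the next bout
            k += 1
            continue
        descent = rng.uniform(*model.descent_range)
        plateau = rng.uniform(*model.plateau_range)
        recovery = rng.uniform(*model.recovery_range)
        depth = rng.uniform(*model.desat_depth_range)
        end = start + descent + plateau + recovery
        if end > duration_s - EVENT_GUARD_S:
            break
        i0, i1 = int(start * ACCEL_RATE_HZ), int(end * ACCEL_RATE_HZ)
        span = sleep[i0:i1]
        span = span[np.isfinite(span)]
        angle = circ_mean(span) if span.size else float("nan")
        events.append(TruthEvent(start, start + descent, start + descent + plateau,
                                 end, depth, str(lab[min(i0, lab.size - 1)]), angle))
        pos = end + EVENT_GUARD_S
    return events


def _spo2_trace(model: SubjectModel, events, duration_s, rng) -> SpO2Series:
    n = int(round(duration_s * SPO2_RATE_HZ))
    t = np.arange(n) / SPO2_RATE_HZ
    clean = np.full(n, model.spo2_baseline)
    for ev in events:
        down = np.clip((t - ev.t_start) / max(ev.t_nadir - ev.t_start, 1e-9), 0.0, 1.0)
        up = np.clip((t - ev.t_recover) / max(ev.t_end - ev.t_recover, 1e-9), 0.0, 1.0)
        profile = np.where(t < ev.t_recover, down, 1.0 - up)
        profile[(t < ev.t_start) | (t > ev.t_end)] = 0.0
        clean = np.minimum(clean, model.spo2_baseline - ev.depth * profile)
    noise = _ar1(n, model.spo2_ar, model.spo2_sigma, rng)
    return SpO2Series(t=t, spo2=np.clip(clean + noise, 50.0, 100.0))


def simulate_night(
    model: SubjectModel,
    duration_hours: float = 8.0,
    seed: int = 0,
    treated: bool = False,
) -> SimulationResult:
    """Simulate one night; returns (accelerometry, SpO2, ground truth)."""
    if duration_hours <= 0:
        raise ValueError("duration must be positive")
    if model.transition is not None:
        for lab in LABELS:
            model.transition_row(lab)  # validates row sums
    rng = np.random.default_rng(seed)
    duration_s = float(duration_hours * 3600.0)
    intervals, vib_log = _build_intervals(model, duration_s, treated, rng)
    t, sleep, stand, lab = _angle_timeline(model, intervals, duration_s, rng)
    accel = _accelerometry(model, t, sleep, stand, lab, rng)
    events = _plant_events(model, intervals, duration_s, sleep, lab, rng)
    spo2 = _spo2_trace(model, events, duration_s, rng)
    truth = GroundTruth(duration_s=duration_s, intervals=intervals, events=events,
                        vibration_log=vib_log, t=t, sleep_angle=sleep,
                        stand_angle=stand, labels=lab, seed=seed, treated=treated)
    return SimulationResult(accel=accel, spo2=spo2, truth=truth)


# ---------------------------------------------------------------------------
# cohorts


def severity_preset(band: str, subject_id: str | None = None) -> SubjectModel:
    """A subject model whose overall planted event rate sits inside one of
    the four severity bands (healthy / mild / moderate / severe).

    Severe disease also cycles faster — desaturation episodes are drawn
    from the short end of the duration ranges so that > 30 events/hour is
    physically sustainable.
    """
    presets = {
        "healthy": dict(rates={"supine": 3.0, "left": 1.0, "right": 1.0, "prone": 0.5}),
        "mild": dict(rates={"supine": 18.0, "left": 6.0, "right": 6.0, "prone": 4.0}),
        "moderate": dict(rates={"supine": 45.0, "left": 14.0, "right": 14.0, "prone": 10.0},
                         descent=(20.0, 60.0), plateau=(0.0, 10.0), recovery=(10.0, 40.0)),
        "severe": dict(rates={"supine": 55.0, "left": 35.0, "right": 35.0, "prone": 25.0},
                       descent=(20.0, 40.0), plateau=(0.0, 5.0), recovery=(10.0, 20.0)),
    }
    if band not in presets:
        raise ValueError(f"unknown severity band {band!r}")
    p = presets[band]
    model = SubjectModel(subject_id=subject_id or band, desat_rates=p["rates"])
    if "descent" in p:
        model = replace(model, descent_range=p["descent"], plateau_range=p["plateau"],
                        recovery_range=p["recovery"])
    return model


def posa_scenario(
    supine_rate: float = 40.0,
    lateral_rate: float = 5.0,
    subject_id: str = "posa",
) -> SubjectModel:
    """A strongly positional-OSA subject: a high supine desaturation rate
    against a low rate in every other posture.

    Episode durations are drawn from the fast end of their supports: a
    40/h rate leaves at most 90 s per obstruction cycle, so the default
    ~100 s mean trapezoid would be physically unsustainable.
    """
    return SubjectModel(
        subject_id=subject_id,
        desat_rates={"supine": supine_rate, "left": lateral_rate,
                     "right": lateral_rate, "prone": lateral_rate},
        descent_range=(20.0, 40.0), plateau_range=(0.0, 5.0),
        recovery_range=(10.0, 20.0),
    )


def default_cohort() -> list[SubjectModel]:
    """Four subjects, one per severity band."""
    return [severity_preset(b, f"subject_{b}") for b in
            ("healthy", "mild", "moderate", "severe")]


def cohort(
    models: list[SubjectModel],
    seed: int = 0,
    out_dir=None,
    duration_hours: float = 8.0,
    treated: bool = False,
) -> dict:
    """Simulate one night per model; optionally write recordings + manifest.

    Returns ``{subject_id: SimulationResult}``.  With ``out_dir`` set, each
    subject gets ``<id>_accel.csv`` and ``<id>_spo2.csv`` plus a single
    ``manifest.json`` describing the planted ground truth.
    """
    if not models:
        raise ValueError("need at least one model")
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=len(models))
    results: dict[str, SimulationResult] = {}
    manifest = {}
    for model, sub_seed in zip(models, seeds):
        res = simulate_night(model, duration_hours, int(sub_seed), treated)
        results[model.subject_id] = res
        manifest[model.subject_id] = res.truth.manifest_entry()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, res in results.items():
            write_accel(res.accel, out_dir / f"{sid}_accel.csv")
            write_spo2(res.spo2, out_dir / f"{sid}_spo2.csv")
            manifest[sid]["accel_file"] = f"{sid}_accel.csv"
            manifest[sid]["spo2_file"] = f"{sid}_spo2.csv"
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return results
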