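"""From raw accelerometry to calibrated sleep and stand angles.

The pipeline mirrors the acquisition chain of a sternum-worn device:

1. linear interpolation of each axis onto a uniform 10 Hz grid;
2. a 60-s sliding median per axis to strip high-frequency (non-gravity)
   acceleration;
3. the planar angle formula

       angle = (180/pi) * acos(a.b / (|a||b|)) * sign(c) + theta_initial

   with ``a = (X, Z)``, ``b = (1, 0)``, ``c = Z`` for the sleep angle and
   ``a = (Y, Z)``, ``b = (1, 0)``, ``c = Z`` for the stand angle.  In the
   body frame this puts a pure left-lateral posture at 0°, supine at 90°,
   right at ±180° and prone at −90°; the stand angle is ±90° when laying
   and ±180° when upright;
4. an additive per-recording calibration offset (one per angle) chosen so
   that the wearer's own supine posture — assumed during the first 10 min
   of acquisition — reads exactly 90° on both angles.

All angles are wrapped to ``(-180, 180]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import circ_mean, wrap_angle
from .io_core import AccelRecording

logger = logging.getLogger(__name__)

TARGET_RATE_HZ = 10.0
MEDIAN_WINDOW_SECONDS = 60.0
CALIBRATION_WINDOW_SECONDS = 600.0
SUPINE_REFERENCE_DEG = 90.0

__all__ = [
    "CalibrationParams",
    "AngleSeries",
    "resample_uniform",
    "median_filter",
    "raw_angle",
    "calibrate",
    "compute_angles",
    "process_recording",
]


@dataclass
class CalibrationParams:
    """Additive offsets (degrees) mapping the wearer's supine posture to 90°."""

    theta_initial_sleep: float = 0.0
    theta_initial_stand: float = 0.0
    calibration_window: float = CALIBRATION_WINDOW_SECONDS


@dataclass
class AngleSeries:
    """Uniformly sampled calibrated sleep and stand angles.

    ``t`` is a uniform grid in seconds (0.1 s spacing at the default rate);
    angles are degrees on ``(-180, 180]``; ``valid`` flags samples whose
    in-plane acceleration vector was non-degenerate.
    """

    t: np.ndarray
    sleep_angle: np.ndarray
    stand_angle: np.ndarray
    valid: np.ndarray | None = None
    calibration: CalibrationParams = field(default_factory=CalibrationParams)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.sleep_angle = np.asarray(self.sleep_angle, dtype=float)
        self.stand_angle = np.asarray(self.stand_angle, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size >= 2 else 1.0 / TARGET_RATE_HZ

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "sleep_angle": self.sleep_angle,
                "stand_angle": self.stand_angle,
                "valid": self.valid.astype(int),
            }
        )

    def to_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False, float_format="%.6f")
        return path

    @classmethod
    def from_csv(cls, path) -> "AngleSeries":
        df = pd.read_csv(path)
        return cls(
            t=df["t"].to_numpy(float),
            sleep_angle=df["sleep_angle"].to_numpy(float),
            stand_angle=df["stand_angle"].to_numpy(float),
            valid=df["valid"].to_numpy(bool) if "valid" in df else None,
        )


def resample_uniform(rec: AccelRecording, rate: float = TARGET_RATE_HZ) -> AccelRecording:
    """Linearly interpolate each axis onto the uniform grid t = 0, 1/rate, ...

    The grid never extends past the last raw sample (no extrapolation).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if rec.n_samples < 2:
        raise ValueError("resampling needs at least 2 samples")
    dt = 1.0 / rate
    grid = np.arange(0.0, rec.t[-1] - rec.t[0] + 1e-9, dt) + rec.t[0]
    acc = np.column_stack([np.interp(grid, rec.t, rec.acc[:, i]) for i in range(3)])
    return AccelRecording(t=grid - rec.t[0], acc=acc, subject_id=rec.subject_id,
                          start_datetime=rec.start_datetime)


def median_filter(rec: AccelRecording, window: float = MEDIAN_WINDOW_SECONDS) -> AccelRecording:
    """Sliding median per axis over ``±window/2`` around each sample.

    The window shrinks at the edges (no padding).  Requires uniform sampling.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    dt = rec.sampling_interval()
    if dt is None:
        raise ValueError("median_filter requires a uniformly sampled recording")
    half = int(round(window / 2.0 / dt))
    size = 2 * half + 1
    df = pd.DataFrame(rec.acc)
    smoothed = df.rolling(window=size, center=True, min_periods=1).median().to_numpy()
    return AccelRecording(t=rec.t, acc=smoothed, subject_id=rec.subject_id,
                          start_datetime=rec.start_datetime)


def raw_angle(x, z, c, theta_initial: float = 0.0):
    """Planar orientation angle in degrees on ``(-180, 180]``.

    ``angle = (180/pi) * acos(x / sqrt(x² + z²)) * sign(c) + theta_initial``,
    with ``sign(0)`` taken as +1.  Scalar or array inputs.  A zero in-plane
    vector has no orientation: scalars raise ``ValueError``; in arrays such
    samples come back NaN (callers flag them invalid).
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    c = np.asarray(c, dtype=float)
    norm = np.hypot(x, z)
    scalar = norm.ndim == 0
    if scalar and norm == 0.0:
        raise ValueError("zero in-plane vector: orientation undefined")
    ratio = np.where(norm > 0, x / np.where(norm > 0, norm, 1.0), 1.0)
    base = np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))
    sign = np.where(c < 0, -1.0, 1.0)  # sign(0) := +1
    angle = wrap_angle(base * sign + theta_initial)
    if not scalar:
        angle = np.where(norm > 0, angle, np.nan)
    return float(angle) if scalar else angle


def _uncalibrated_angles(rec: AccelRecording) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sleep = raw_angle(rec.ax, rec.az, rec.az)
    stand = raw_angle(rec.ay, rec.az, rec.az)
    valid = ~(np.isnan(sleep) | np.isnan(stand))
    return sleep, stand, valid


def calibrate(
    t: np.ndarray,
    sleep_raw: np.ndarray,
    stand_raw: np.ndarray,
    window: float = CALIBRATION_WINDOW_SECONDS,
) -> CalibrationParams:
    """Derive per-recording offsets from the first ``window`` seconds.

    Assumes the wearer lies supine over that window; each offset is the
    wrapped difference between 90° and the circular mean of the raw angle,
    so that adding it re-centres the calibration window on 90°.  If the
    recording is shorter than the window the offsets fall back to zero with
    a warning.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0 or t[-1] - t[0] < window:
        logger.warning(
            "recording shorter than the %.0f s calibration window; using zero offsets", window
        )
        return CalibrationParams(0.0, 0.0, window)
    sel = t - t[0] <= window
    sleep_sel = np.asarray(sleep_raw, float)[sel]
    stand_sel = np.asarray(stand_raw, float)[sel]
    sleep_sel = sleep_sel[~np.isnan(sleep_sel)]
    stand_sel = stand_sel[~np.isnan(stand_sel)]
    off_sleep = wrap_angle(SUPINE_REFERENCE_DEG - circ_mean(sleep_sel))
    off_stand = wrap_angle(SUPINE_REFERENCE_DEG - circ_mean(stand_sel))
    return CalibrationParams(off_sleep, off_stand, window)


def compute_angles(
    rec: AccelRecording,
    calibration: CalibrationParams | None = None,
    autocalibrate: bool = True,
) -> AngleSeries:
    """Sleep and stand angles of a resampled, filtered recording.

    Sleep angle from (X, Z), stand angle from (Y, Z), both with sign carrier
    ``c = Z``; calibration offsets added then re-wrapped.  With
    ``calibration=None`` and ``autocalibrate=True`` the offsets are derived
    from the first 10 min (supine assumption); ``autocalibrate=False`` uses
    zero offsets.  Degenerate samples (zero in-plane vector) are NaN and
    flagged invalid.
    """
    sleep_raw, stand_raw, valid = _uncalibrated_angles(rec)
    if calibration is None:
        if autocalibrate:
            calibration = calibrate(rec.t, sleep_raw, stand_raw)
        else:
            calibration = CalibrationParams(0.0, 0.0)
    sleep = np.where(valid, wrap_angle(sleep_raw + calibration.theta_initial_sleep), np.nan)
    stand = np.where(valid, wrap_angle(stand_raw + calibration.theta_initial_stand), np.nan)
    return AngleSeries(t=rec.t, sleep_angle=sleep, stand_angle=stand, valid=valid,
                       calibration=calibration)


def process_recording(
    rec: AccelRecording,
    rate: float = TARGET_RATE_HZ,
    median_window: float = MEDIAN_WINDOW_SECONDS,
    calibration: CalibrationParams | None = None,
    autocalibrate: bool = True,
) -> AngleSeries:
    """Full preprocessing chain: resample → median filter → angles."""
    uniform = resample_uniform(rec, rate)
    filtered = median_filter(uniform, median_window)
    return compute_angles(filtered, calibration=calibration, autocalibrate=autocalibrate)
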