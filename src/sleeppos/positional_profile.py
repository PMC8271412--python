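"""Angle-resolved positional statistics: %Position, %DE, local ODI, ratio.

Every statistic is evaluated on an integer grid of sleep angles
θ = −180 … 179° (360 points; +180 is identified with −180) using a circular
window of ±7.5° around each θ, so each sample or event contributes to
exactly 15 one-degree windows:

* ``%Position(θ)`` — percent of laying samples whose sleep angle falls in
  the window;
* ``%DE(θ)`` — percent of desaturation events whose assigned angle (the
  circular mean of the sleep angle over the event) falls in the window;
* ``local ODI(θ)`` — events in the window per hour spent in the window,
  with the time denominator floored at 10 min to suppress artifacts, then
  smoothed with a circular 5-point moving average; masked where no time was
  spent at θ;
* ``ratio %DE/%Position(θ)`` — event over-representation, with the
  denominator floored at 1 %; masked where %Position is zero.

Counting is implemented by binning angles into 1° bins (edges on the
half-degree) and circularly convolving with a 15-bin boxcar, which is exact
for the half-open window [θ−7.5°, θ+7.5°) and makes the window-sum
conservation Σ_θ %Position(θ) = 1500 hold to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import circ_mean, circ_median
from .orientation import AngleSeries
from .oximetry import DesatEvent
from .position_summary import laying_mask

__all__ = [
    "AnalysisConfig",
    "PositionalProfile",
    "grid_angles",
    "pct_position",
    "assign_event_angles",
    "pct_de",
    "local_odi",
    "ratio_de_position",
    "compute_profile",
    "profile_heatmap",
]


@dataclass
class AnalysisConfig:
    """Knobs of the angle-resolved analysis (defaults are the study's)."""

    half_window: float = 7.5          # degrees to either side of θ
    min_position_minutes: float = 10.0  # local-ODI denominator floor
    min_position_percent: float = 1.0   # ratio denominator floor
    smooth_radius: int = 2              # 5-point moving average
    samples_per_hour: float = 36000.0   # 10 Hz × 3600 s
    event_angle: str = "mean"           # 'mean' or 'median' event statistic


def grid_angles() -> np.ndarray:
    """The evaluation grid θ = −180 … 179 (integer degrees, 360 points)."""
    return np.arange(-180, 180)


def _window_counts(angles_deg: np.ndarray, cfg: AnalysisConfig) -> np.ndarray:
    """Per-grid-angle counts of values within ±half_window (circular).

    Bin into 1° bins with edges on half degrees, then circular boxcar sum.
    """
    a = np.mod(np.asarray(angles_deg, dtype=float) + 180.5, 360.0)  # bin index space
    bins = np.bincount(a.astype(int) % 360, minlength=360).astype(float)
    w = int(round(cfg.half_window - 0.5))  # 7 bins each side + centre = 15
    kernel_idx = np.arange(-w, w + 1)
    counts = np.zeros(360)
    for k in kernel_idx:
        counts += np.roll(bins, -k)
    return counts


def pct_position(series: AngleSeries, cfg: AnalysisConfig | None = None) -> np.ndarray:
    """Percent of laying time spent within ±7.5° of each grid angle."""
    cfg = cfg or AnalysisConfig()
    lay = laying_mask(series)
    angles = series.sleep_angle[lay]
    if angles.size == 0:
        raise ValueError("no laying samples: %Position undefined")
    return 100.0 * _window_counts(angles, cfg) / angles.size


def assign_event_angles(
    events: list[DesatEvent], series: AngleSeries, cfg: AnalysisConfig | None = None
) -> list[DesatEvent]:
    """Attach to each event the circular mean (or median) sleep angle over
    [t_baseline, t_end]; events overlapping no samples are dropped with a
    warning."""
    cfg = cfg or AnalysisConfig()
    stat = circ_mean if cfg.event_angle == "mean" else circ_median
    out: list[DesatEvent] = []
    dropped = 0
    for ev in events:
        sel = (series.t >= ev.t_baseline) & (series.t <= ev.t_end) & series.valid
        angles = series.sleep_angle[sel]
        angles = angles[np.isfinite(angles)]
        if angles.size == 0:
            dropped += 1
            continue
        ev.assigned_angle = stat(angles)
        out.append(ev)
    if dropped:
        warnings.warn(f"{dropped} event(s) overlap no angle samples; dropped")
    return out


def pct_de(events: list[DesatEvent], cfg: AnalysisConfig | None = None) -> np.ndarray:
    """Percent of desaturation events assigned within ±7.5° of each angle."""
    cfg = cfg or AnalysisConfig()
    angles = np.asarray([e.assigned_angle for e in events if e.assigned_angle is not None])
    if angles.size == 0:
        warnings.warn("no assigned events: %DE profile is all zero")
        return np.zeros(360)
    return 100.0 * _window_counts(angles, cfg) / angles.size


def _circular_masked_smooth(values: np.ndarray, valid: np.ndarray, radius: int) -> np.ndarray:
    """Circular moving average over ±radius cells, skipping masked cells."""
    out = np.full_like(values, np.nan)
    acc = np.zeros_like(values)
    cnt = np.zeros_like(values)
    v = np.where(valid, values, 0.0)
    for k in range(-radius, radius + 1):
        acc += np.roll(v, -k)
        cnt += np.roll(valid.astype(float), -k)
    ok = valid & (cnt > 0)
    out[ok] = acc[ok] / cnt[ok]
    return out


def local_odi(
    events: list[DesatEvent],
    series: AngleSeries,
    cfg: AnalysisConfig | None = None,
    smooth: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-angle desaturation rate (events/hour) with validity mask.

    hours(θ) = laying samples in the window / samples_per_hour, floored at
    ``min_position_minutes``; angles with zero laying samples are masked.
    With ``smooth=True`` the valid cells are passed through a circular
    5-point moving average (masked cells excluded from the neighbourhoods).
    Returns ``(odi, valid)``.
    """
    cfg = cfg or AnalysisConfig()
    lay = laying_mask(series)
    angles = series.sleep_angle[lay]
    if angles.size == 0:
        raise ValueError("no laying samples: local ODI undefined")
    sample_counts = _window_counts(angles, cfg)
    ev_angles = np.asarray([e.assigned_angle for e in events if e.assigned_angle is not None])
    event_counts = _window_counts(ev_angles, cfg) if ev_angles.size else np.zeros(360)
    hours = sample_counts / cfg.samples_per_hour
    floor_h = cfg.min_position_minutes / 60.0
    odi = event_counts / np.maximum(hours, floor_h)
    valid = sample_counts > 0
    odi[~valid] = np.nan
    if smooth:
        odi = _circular_masked_smooth(odi, valid, cfg.smooth_radius)
    return odi, valid


def ratio_de_position(
    pct_de_profile: np.ndarray,
    pct_position_profile: np.ndarray,
    cfg: AnalysisConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """%DE over %Position with the 1 % denominator floor; masked where
    %Position is zero.  Returns ``(ratio, valid)``."""
    cfg = cfg or AnalysisConfig()
    pct_de_profile = np.asarray(pct_de_profile, dtype=float)
    pct_position_profile = np.asarray(pct_position_profile, dtype=float)
    valid = pct_position_profile > 0
    ratio = pct_de_profile / np.maximum(pct_position_profile, cfg.min_position_percent)
    ratio[~valid] = np.nan
    return ratio, valid


@dataclass
class PositionalProfile:
    """All four angle-resolved statistics for one subject/night."""

    theta: np.ndarray
    pct_position: np.ndarray
    pct_de: np.ndarray
    local_odi: np.ndarray
    ratio: np.ndarray
    valid_odi: np.ndarray
    valid_ratio: np.ndarray
    subject_id: str = ""
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.theta,
                "pct_position": self.pct_position,
                "pct_de": self.pct_de,
                "local_odi": self.local_odi,
                "ratio": self.ratio,
                "valid_odi": self.valid_odi.astype(int),
                "valid_ratio": self.valid_ratio.astype(int),
            }
        )

    def to_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        # masked cells serialise as empty fields
        self.to_frame().to_csv(path, index=False, float_format="%.6f", na_rep="")
        return path

    @classmethod
    def from_csv(cls, path, subject_id: str = "") -> "PositionalProfile":
        df = pd.read_csv(path)
        return cls(
            theta=df["theta"].to_numpy(int),
            pct_position=df["pct_position"].to_numpy(float),
            pct_de=df["pct_de"].to_numpy(float),
            local_odi=df["local_odi"].to_numpy(float),
            ratio=df["ratio"].to_numpy(float),
            valid_odi=df["valid_odi"].to_numpy(bool),
            valid_ratio=df["valid_ratio"].to_numpy(bool),
            subject_id=subject_id or Path(path).stem,
        )


def compute_profile(
    series: AngleSeries,
    events: list[DesatEvent],
    cfg: AnalysisConfig | None = None,
    subject_id: str = "",
) -> PositionalProfile:
    """Assemble the full positional profile for one night."""
    cfg = cfg or AnalysisConfig()
    assigned = assign_event_angles(events, series, cfg)
    pos = pct_position(series, cfg)
    de = pct_de(assigned, cfg) if assigned else np.zeros(360)
    odi, valid_odi = local_odi(assigned, series, cfg, smooth=True)
    ratio, valid_ratio = ratio_de_position(de, pos, cfg)
    return PositionalProfile(
        theta=grid_angles(), pct_position=pos, pct_de=de, local_odi=odi, ratio=ratio,
        valid_odi=valid_odi, valid_ratio=valid_ratio, subject_id=subject_id, config=cfg,
    )


_MATRICES = ("pct_de", "pct_position", "ratio", "local_odi")


def profile_heatmap(profiles: list[PositionalProfile], out_dir, render: bool = True) -> dict:
    """Cohort heatmaps: one subjects × 360 matrix per statistic.

    Each matrix is written as CSV (masked cells as empty fields) and, when
    ``render`` is true, as a PNG with masked cells painted black.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = [p.subject_id or f"subject_{i+1}" for i, p in enumerate(profiles)]
    written = {}
    for name in _MATRICES:
        mat = np.vstack([getattr(p, name) for p in profiles])
        df = pd.DataFrame(mat, index=subjects, columns=grid_angles())
        csv_path = out_dir / f"heatmap_{name}.csv"
        df.to_csv(csv_path, float_format="%.6f", na_rep="")
        written[name] = {"csv": csv_path, "matrix": mat}
        if render:
            written[name]["png"] = _render_heatmap(mat, subjects, name,
                                                   out_dir / f"heatmap_{name}.png")
    return written


def _render_heatmap(mat: np.ndarray, subjects: list[str], name: str, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("black")
    fig, ax = plt.subplots(figsize=(10, max(2, 0.4 * len(subjects) + 1)))
    im = ax.imshow(np.ma.masked_invalid(mat), aspect="auto", cmap=cmap,
                   extent=[-180, 180, len(subjects), 0], interpolation="nearest")
    ax.set_xlabel("sleep angle (deg)")
    ax.set_yticks(np.arange(len(subjects)) + 0.5, subjects)
    ax.set_title(name)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
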