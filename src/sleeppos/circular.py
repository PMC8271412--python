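"""Circular statistics on orientation angles in degrees.

All angles in this package live on the circle ``(-180, 180]`` degrees; the
boundary value ``-180`` is always normalised to ``+180`` so that a pure
right-lateral posture has a single representation.  The helpers here are the
thin layer every module shares: wrapping, circular distance, circular mean /
standard deviation, and a rotation-based circular median.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "circ_dist",
    "circ_mean",
    "circ_std",
    "circ_median",
]


def wrap_angle(angle):
    """Wrap angles (degrees) onto ``(-180, 180]``.

    Accepts scalars or arrays; -180 maps to +180.
    """
    wrapped = 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)
    return wrapped if np.ndim(angle) else float(wrapped)


def circ_dist(a, b):
    """Absolute circular distance in degrees, in ``[0, 180]``."""
    d = np.abs(np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0))
    d = np.where(d > 180.0, 360.0 - d, d)
    return d if (np.ndim(a) or np.ndim(b)) else float(d)


def _resultant(angles_deg: np.ndarray) -> tuple[float, float]:
    """Mean direction (radians) and mean resultant length of a sample."""
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    s, c = np.mean(np.sin(rad)), np.mean(np.cos(rad))
    return float(np.arctan2(s, c)), float(np.hypot(s, c))


def circ_mean(angles_deg) -> float:
    """Circular mean direction in degrees on ``(-180, 180]``.

    Undefined (NaN) for an empty sample or a perfectly balanced one
    (zero resultant length).
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size == 0:
        return float("nan")
    mu, r = _resultant(angles_deg)
    if r < 1e-12:
        return float("nan")
    return wrap_angle(np.rad2deg(mu))


def circ_std(angles_deg) -> float:
    """Circular standard deviation in degrees, ``sqrt(-2 ln R)``.

    Zero for a degenerate (single-valued) sample; NaN for an empty one.
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size == 0:
        return float("nan")
    _, r = _resultant(angles_deg)
    r = min(max(r, 1e-12), 1.0)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))))


def circ_median(angles_deg) -> float:
    """Circular median: rotate the sample so its circular mean sits at 0,
    take the ordinary median, rotate back.

    Exact for unimodal samples spanning less than a half circle, which is the
    regime desaturation-event angles occupy (an event rarely straddles more
    than one position shift).
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size == 0:
        return float("nan")
    mu = circ_mean(angles_deg)
    if np.isnan(mu):
        return float("nan")
    centred = wrap_angle(angles_deg - mu)
    return wrap_angle(float(np.median(centred)) + mu)
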