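"""Small circular-statistics helpers used throughout the polarity stages.

All public functions work in degrees; angles are wrapped to [-180, 180).
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_angle", "circular_distance", "circular_mean"]


def wrap_angle(angle_deg):
    """Wrap angle(s) in degrees to the half-open interval [-180, 180)."""
    return (np.asarray(angle_deg, dtype=float) + 180.0) % 360.0 - 180.0


def circular_distance(a_deg, b_deg):
    """Shortest angular distance between two angles, in [0, 180]."""
    d = np.abs(wrap_angle(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)))
    return d


def circular_mean(angles_deg) -> float:
    """Circular mean of angles in degrees, wrapped to [-180, 180).

    Defined via the mean resultant vector; undefined (returns nan) for an
    empty input or a perfectly balanced antipodal set.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        return float("nan")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    if np.hypot(s, c) < 1e-12:
        return float("nan")
    return float(wrap_angle(np.degrees(np.arctan2(s, c))))


def resultant_length(angles_deg) -> float:
    """Mean resultant length R in [0, 1]; 1 = fully concentrated sample."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        return float("nan")
    return float(np.hypot(np.sin(a).mean(), np.cos(a).mean()))
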