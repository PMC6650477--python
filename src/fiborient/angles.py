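"""Axial (180°-periodic) angle arithmetic.

Fiber orientation is an axis, not a direction: θ and θ+180° describe the
same fiber. All angles are degrees; 0° points left→right in the image and
angles increase counter-clockwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fold180", "angular_difference", "axial_mean"]


def fold180(theta):
    """Fold angle(s) in degrees to the axial range [0, 180)."""
    r = np.mod(theta, 180.0)
    # np.mod can round to exactly 180.0 for tiny negative inputs
    return np.where(r >= 180.0, 0.0, r) if np.ndim(r) else (0.0 if r >= 180.0 else r)


def angular_difference(theta1, theta2):
    """Axial angular distance in degrees, in [0, 90].

    ``min(|Δ| mod 180, 180 − |Δ| mod 180)``; symmetric in its arguments.
    NaN inputs propagate to NaN (sentinel semantics).
    """
    d = np.mod(np.abs(np.asarray(theta1, dtype=float) - np.asarray(theta2, dtype=float)), 180.0)
    out = np.minimum(d, 180.0 - d)
    if np.ndim(out) == 0:
        return float(out)
    return out


def axial_mean(thetas_deg) -> float:
    """Mean of axial angles via the doubled-angle circular mean, in [0, 180).

    Raises ValueError on an empty input.
    """
    t = np.asarray(thetas_deg, dtype=float)
    if t.size == 0:
        raise ValueError("axial_mean of empty set")
    doubled = np.deg2rad(2.0 * t)
    m = np.arctan2(np.sin(doubled).mean(), np.cos(doubled).mean())
    return float(fold180(np.rad2deg(m) / 2.0))
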