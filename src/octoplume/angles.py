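"""Angle conventions used throughout the package.

All angles are in degrees, measured counter-clockwise in the arena frame.
Signed differences are reported in the half-open interval (-180, 180]: a
positive offset means the second direction lies counter-clockwise of the
first.
"""

from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Wrap angle(s) into (-180, 180] degrees."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(((-a + 180.0) % 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def signed_offset_deg(from_deg, to_deg):
    """Signed angle from ``from_deg`` to ``to_deg``, in (-180, 180].

    Positive when ``to_deg`` is counter-clockwise of ``from_deg``.
    """
    return wrap_deg(np.asarray(to_deg, dtype=float) - np.asarray(from_deg, dtype=float))


def unit_vector_deg(angle_deg):
    """Unit vector(s) (x, y) for angle(s) in degrees, CCW from +x."""
    rad = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return np.stack([np.cos(rad), np.sin(rad)], axis=-1)


def vector_angle_deg(vec):
    """Angle(s) in degrees of 2-D vector(s), CCW from +x, in (-180, 180]."""
    v = np.asarray(vec, dtype=float)
    ang = np.rad2deg(np.arctan2(v[..., 1], v[..., 0]))
    return wrap_deg(ang)
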