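"""Coordinate frame and sign conventions shared by every module.

All landmark coordinates are in millimetres, in a frontal-plane frame for a
**right** knee:

* ``x`` increases towards the **medial** side (body midline),
* ``y`` increases **superiorly** (towards the head).

Angles are in **degrees** at every public interface.

Alignment sign convention
-------------------------
The hip-knee-ankle (HKA) angle is the angle between the femoral mechanical
axis (femoral head centre -> intercondylar notch) and the tibial shaft axis
(tibial plateau centre -> talus centre), both taken as *distally pointing*
direction vectors.  In this frame a varus (bow-legged) limb has its tibial
axis adducted -- the talus sits medial (+x) of the knee -- which is a
*counter-clockwise* rotation of the tibial axis relative to the femoral axis.
Epidemiological convention reports varus as **negative** HKA (male cohorts,
which are more varus on average, have more negative means), so the signed HKA
is minus the counter-clockwise angle:

    hka = ALIGNMENT_SIGN * ccw_angle(femoral_axis, tibial_axis)

``ALIGNMENT_SIGN = -1`` is the single constant defining this; the synthetic
generator, the alignment module and all tests share it.
"""

from __future__ import annotations

import numpy as np

#: sign applied to the CCW angle from the femoral to the tibial distal axis so
#: that varus limbs get negative HKA/FTA values.
ALIGNMENT_SIGN: float = -1.0


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """2x2 counter-clockwise rotation matrix for an angle in degrees."""
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


def ccw_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Signed counter-clockwise angle (degrees) from vector ``u`` to ``v``.

    Positive when ``v`` is rotated counter-clockwise from ``u`` in the
    medial-at-larger-x, y-up frame.  Raises ``ValueError`` for a zero vector.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.hypot(*u) == 0.0 or np.hypot(*v) == 0.0:
        raise ValueError("cannot measure an angle against a zero-length axis")
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return float(np.rad2deg(np.arctan2(cross, dot)))


def rotate_about(points: np.ndarray, angle_deg: float, centre) -> np.ndarray:
    """Rotate ``points`` (n, 2) counter-clockwise about ``centre``."""
    centre = np.asarray(centre, dtype=float)
    return (np.asarray(points, float) - centre) @ rotation_matrix(angle_deg).T + centre
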