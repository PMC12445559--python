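"""Lower-limb alignment angles (HKA, FTA) from total-body landmarks.

The femoral head centre is recovered by an algebraic (Kåsa) least-squares
circle fit to the ring of landmarks around the femoral head; a geometric
refinement is unnecessary at seven nearly-noise-free points.  The mechanical
femoral axis runs from that centre to the intercondylar notch, the tibial
shaft axis from the tibial plateau centre to the talus centre, and the
anatomical femoral axis is the least-squares line through the femoral shaft
points.  Angles are signed per :mod:`kneessm.conventions` (varus negative)
and reported in degrees.

Quality control mirrors image-failure handling: physiologically implausible
angles (|angle| >= 45 deg) or non-finite inputs yield a flagged, missing
angle rather than an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conventions import ALIGNMENT_SIGN, ccw_angle_deg
from .landmarks import BodyLandmarkSet

#: physiologic screen: angles at or beyond this magnitude are flagged
PHYSIOLOGIC_LIMIT_DEG = 45.0


@dataclass
class AlignmentAngles:
    """Signed alignment angles for one limb (degrees; varus negative)."""

    hka: float
    fta: float
    femoral_head_centre: np.ndarray
    qc_flags: tuple[str, ...] = field(default_factory=tuple)


class CollinearPointsError(ValueError):
    """Raised when a circle is requested through (near-)collinear points."""


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares circle through >= 3 points.

    Minimises the Kåsa loss sum((|p - c|^2 - r^2)^2), which is linear in the
    parameters (a, b, c) of x^2 + y^2 + a x + b y + c = 0.

    Returns
    -------
    centre : ndarray (2,)
    radius : float
    rms_residual : float
        RMS of the radial residuals |p - c| - r.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("need at least 3 (x, y) points to fit a circle")
    if not np.all(np.isfinite(pts)):
        raise ValueError("circle-fit points must be finite")
    A = np.column_stack([pts, np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    # rank-deficiency of [x y 1] <=> collinear points
    if rank < 3:
        raise CollinearPointsError("circle fit requires non-collinear points")
    centre = sol[:2] / 2.0
    r2 = sol[2] + centre @ centre
    if r2 <= 0:
        raise CollinearPointsError("degenerate circle fit (non-positive radius)")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(pts - centre, axis=1) - radius
    return centre, radius, float(np.sqrt(np.mean(resid ** 2)))


def _axis(p_from: np.ndarray, p_to: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(p_to, float) - np.asarray(p_from, float)
    if np.linalg.norm(v) == 0:
        raise ValueError(f"zero-length {what}")
    return v


def _tibial_axis(body: BodyLandmarkSet) -> np.ndarray:
    return _axis(body.tibial_plateau_centre, body.talus_centre, "tibial shaft axis")


def hka_angle(body: BodyLandmarkSet) -> float:
    """Hip-knee-ankle angle (degrees, varus negative).

    Angle between the femoral mechanical axis (femoral head centre ->
    intercondylar notch) and the tibial shaft axis (tibial plateau centre ->
    talus centre).
    """
    centre, _, _ = fit_circle(body.femoral_head_ring)
    femoral = _axis(centre, body.intercondylar_notch, "femoral mechanical axis")
    return ALIGNMENT_SIGN * ccw_angle_deg(femoral, _tibial_axis(body))


def _shaft_direction(shaft_points: np.ndarray) -> np.ndarray:
    """Distally-pointing unit direction of the least-squares line through the
    femoral shaft points (first principal axis of the point scatter)."""
    pts = np.asarray(shaft_points, float)
    centred = pts - pts.mean(axis=0)
    if np.allclose(centred, 0.0):
        raise ValueError("femoral shaft points are coincident")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    d = vt[0]
    if d[1] > 0:  # orient distally (decreasing y)
        d = -d
    return d


def fta_angle(body: BodyLandmarkSet) -> float:
    """Femorotibial angle (degrees, same sign convention as HKA).

    Angle between the anatomical femoral axis (least-squares line through the
    femoral shaft points, oriented distally) and the tibial shaft axis.
    """
    anat = _shaft_direction(body.femoral_shaft_points)
    return ALIGNMENT_SIGN * ccw_angle_deg(anat, _tibial_axis(body))


def alignment_angles(body: BodyLandmarkSet) -> AlignmentAngles:
    """Compute HKA and FTA with QC-flag propagation.

    Geometric failures and out-of-physiologic-range angles produce NaN angles
    plus a flag naming the reason, never an exception.
    """
    flags: list[str] = []
    centre = np.array([np.nan, np.nan])
    hka = fta = np.nan
    try:
        centre, _, _ = fit_circle(body.femoral_head_ring)
        hka = hka_angle(body)
    except (ValueError, CollinearPointsError) as exc:
        flags.append(f"hka_failed:{exc}")
    try:
        fta = fta_angle(body)
    except ValueError as exc:
        flags.append(f"fta_failed:{exc}")
    if np.isfinite(hka) and abs(hka) >= PHYSIOLOGIC_LIMIT_DEG:
        flags.append("hka_out_of_range")
        hka = np.nan
    if np.isfinite(fta) and abs(fta) >= PHYSIOLOGIC_LIMIT_DEG:
        flags.append("fta_out_of_range")
        fta = np.nan
    return AlignmentAngles(hka=hka, fta=fta, femoral_head_centre=centre,
                           qc_flags=tuple(flags))
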