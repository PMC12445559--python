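"""Idealised 129-point right-knee outline template.

The template traces four bone segments in a fixed index order:

======== ============ =========================================================
segment  indices      path
======== ============ =========================================================
femur    0-54         lateral shaft edge (0-16), distolateral corner (17),
                      lateral condyle (18-28), intercondylar notch (29-31,
                      notch apex at 30), medial condyle (32-42), medial shaft
                      edge (43-54)
tibia    55-94        medial shaft edge (55-63), medial plateau (64-74),
                      tibial spines (75-77, plateau centre at 76), lateral
                      plateau (78-86), lateral shaft edge (87-94)
fibula   95-108       proximal fibular head, closed ellipse
patella  109-128      superior patella, closed ellipse
======== ============ =========================================================

Index 17 sits at the distolateral corner of the femur and is the anchor used
when composite shapes are overlaid.  The medial femoral condyle is flat
(y = 0) for x <= 22.5 mm and the medial tibial plateau flat at y = -5 mm on
the same x grid, so the template's medial minimum joint-space width is
exactly 5.0 mm.

Osteophyte sites are short runs of outline points at the four joint margins;
protrusion displaces them along a fixed outward normal, and the displaced
medial-compartment points are excluded from the mJSW search
(:data:`MJSW_EXCLUDE`).
"""

from __future__ import annotations

import numpy as np

from .landmarks import N_POINTS, LandmarkSet

#: anchor for composite-figure overlays (distolateral femoral corner)
DISTOLATERAL_FEMUR_INDEX = 17
#: apex of the intercondylar notch (femur)
NOTCH_INDEX = 30
#: centre of the tibial plateau (tibial spine region)
TIBIAL_PLATEAU_CENTRE_INDEX = 76

MEDIAL_FEMORAL_CONDYLE = np.arange(32, 43)
MEDIAL_TIBIAL_PLATEAU = np.arange(64, 75)

#: outline indices excluded from the mJSW search because osteophyte
#: protrusion can displace them (medial femur site 41-42, medial tibia 64)
MJSW_EXCLUDE = (41, 42, 64)

#: per-site outline indices at the four scored joint margins, in the scoring
#: order (medial femur, lateral femur, medial tibia, lateral tibia)
OSTEOPHYTE_SITES: dict[str, np.ndarray] = {
    "medial_femur": np.array([41, 42, 43]),
    "lateral_femur": np.array([17, 18, 19]),
    "medial_tibia": np.array([63, 64]),
    "lateral_tibia": np.array([85, 86, 87]),
}

SITE_ORDER = ("medial_femur", "lateral_femur", "medial_tibia", "lateral_tibia")


def _template_points() -> np.ndarray:
    pts = np.empty((N_POINTS, 2))

    # femur -----------------------------------------------------------------
    pts[0:17, 0] = np.linspace(-26.0, -36.0, 17)
    pts[0:17, 1] = np.linspace(58.0, 4.0, 17)
    pts[17] = (-37.0, 0.0)
    x = np.linspace(-35.0, -10.0, 11)
    pts[18:29, 0] = x
    pts[18:29, 1] = -2.0 + 1.5 * ((x + 22.5) / 12.5) ** 2
    pts[29] = (-5.0, 3.0)
    pts[30] = (0.0, 6.0)
    pts[31] = (5.0, 3.0)
    x = np.linspace(10.0, 35.0, 11)
    pts[32:43, 0] = x
    pts[32:43, 1] = np.where(x <= 22.5, 0.0, 0.03 * (x - 22.5) ** 2)
    pts[43:55, 0] = np.linspace(36.0, 27.0, 12)
    pts[43:55, 1] = np.linspace(4.0, 58.0, 12)

    # tibia -----------------------------------------------------------------
    pts[55:64, 0] = np.linspace(26.0, 35.0, 9)
    pts[55:64, 1] = np.linspace(-50.0, -7.0, 9)
    pts[64:75, 0] = np.linspace(35.0, 10.0, 11)
    pts[64:75, 1] = -5.0
    pts[75] = (5.0, -3.0)
    pts[76] = (0.0, -2.0)
    pts[77] = (-5.0, -4.0)
    pts[78:87, 0] = np.linspace(-10.0, -33.0, 9)
    pts[78:87, 1] = -8.0
    pts[87:95, 0] = np.linspace(-34.0, -25.0, 8)
    pts[87:95, 1] = np.linspace(-10.0, -50.0, 8)

    # fibula ----------------------------------------------------------------
    t = 2.0 * np.pi * np.arange(14) / 14.0
    pts[95:109, 0] = -40.0 + 5.0 * np.cos(t)
    pts[95:109, 1] = -30.0 + 8.0 * np.sin(t)

    # patella ---------------------------------------------------------------
    t = 2.0 * np.pi * np.arange(20) / 20.0
    pts[109:129, 0] = 12.0 * np.cos(t)
    pts[109:129, 1] = 46.0 + 14.0 * np.sin(t)

    return pts


def segment_map() -> dict[str, np.ndarray]:
    """Index map for the template (segments partition 0..128)."""
    return {
        "femur": np.arange(0, 55),
        "tibia": np.arange(55, 95),
        "fibula": np.arange(95, 109),
        "patella": np.arange(109, 129),
        "medial_femoral_condyle": MEDIAL_FEMORAL_CONDYLE.copy(),
        "medial_tibial_plateau": MEDIAL_TIBIAL_PLATEAU.copy(),
    }


def make_template(id: str = "template") -> LandmarkSet:
    """Build the idealised 129-point right-knee outline.

    Returns a :class:`~kneessm.landmarks.LandmarkSet` whose segment map
    partitions all 129 indices into femur/tibia/fibula/patella and names the
    medial femoral condyle and medial tibial plateau subsets used for mJSW.
    """
    return LandmarkSet(points=_template_points(), segment_map=segment_map(), id=id)


def knee_centre(template: LandmarkSet | None = None) -> np.ndarray:
    """Centre of the joint: midpoint of the intercondylar-notch point and the
    tibial-plateau-centre point.  Used as the pivot for varus/valgus rotation
    of the tibia + fibula in the synthetic generator."""
    if template is None:
        template = make_template()
    return 0.5 * (
        template.points[NOTCH_INDEX] + template.points[TIBIAL_PLATEAU_CENTRE_INDEX]
    )


def site_normal(points: np.ndarray, indices: np.ndarray, segment_idx: np.ndarray) -> np.ndarray:
    """Unit outward normal for an osteophyte site.

    Perpendicular to the end-to-end chord of the site's points, with the sign
    chosen to point away from the centroid of the bone segment the site
    belongs to.
    """
    chord = points[indices[-1]] - points[indices[0]]
    n = np.array([-chord[1], chord[0]])
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("degenerate osteophyte site: zero chord")
    n /= norm
    outward = points[indices].mean(axis=0) - points[segment_idx].mean(axis=0)
    if float(n @ outward) < 0:
        n = -n
    return n


def flip_to_left(landmarks: LandmarkSet) -> LandmarkSet:
    """Mirror a right-knee configuration into a left-knee one (x -> -x).

    Utility only; every other module assumes the right-knee convention.
    """
    pts = landmarks.points.copy()
    pts[:, 0] = -pts[:, 0]
    return landmarks.copy(points=pts)
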