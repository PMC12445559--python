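"""Radiographic knee-OA (rKOA) assessment from landmark geometry and
osteophyte areas.

The assessment combines two components measured on a frontal-plane knee
outline:

* **Osteophytes** — graded 0-3 at four joint-margin sites (medial/lateral
  femur and tibia) from their projected area in mm², using three increasing
  area cut-offs per site.  The four grades are down-weighted by 0.5 and
  summed, giving a combined osteophyte score in 0-6.
* **Joint-space narrowing (JSN)** — graded 0-3 from the medial minimum
  joint-space width (mJSW): grade 0 for mJSW >= 3 mm, 1 for >= 2.5 and < 3,
  2 for >= 2 and < 2.5, and 3 for < 2 mm.

The weighted osteophyte score plus the JSN grade gives the overall rKOA
score (0-9), which is binned into rKOA grades 0-4.  The area cut-offs and
the score->grade bins are configuration values: the grading scheme that
introduced them published the thresholds separately, so the defaults here
(1, 3, 6 mm² and bins {0:0, (0,1]:1, (1,2.5]:2, (2.5,4.5]:3, >4.5:4}) are
explicit assumptions — see docs/methods.md.

Half-integer scores are held exactly as doubled integers internally, so no
floating-point comparisons enter the binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkSet
from .template import MJSW_EXCLUDE, SITE_ORDER

#: default per-site osteophyte area cut-offs (mm²) for grades 1, 2, 3
DEFAULT_AREA_CUTOFFS: tuple[float, float, float] = (1.0, 3.0, 6.0)

#: default rKOA score -> grade bin upper edges, stored on the doubled-score
#: scale (score 0 -> grade 0; (0, 1] -> 1; (1, 2.5] -> 2; (2.5, 4.5] -> 3;
#: > 4.5 -> 4)
DEFAULT_GRADE_BIN_EDGES: tuple[float, float, float, float] = (0.0, 1.0, 2.5, 4.5)

#: JSN thresholds in mm (lower bounds of grades 0, 1, 2; below the last is 3)
JSN_THRESHOLDS: tuple[float, float, float] = (3.0, 2.5, 2.0)


@dataclass(frozen=True)
class RKOAAssessment:
    """rKOA assessment of one knee.

    ``weighted_osteophyte_score`` is 0.5 x the sum of the four site grades
    (0-6); ``rkoa_score`` adds the JSN grade (0-9); ``rkoa_grade`` is the
    binned 0-4 grade.
    """

    mjsw: float
    jsn_grade: int
    osteophyte_grades: tuple[int, int, int, int]
    weighted_osteophyte_score: float
    rkoa_score: float
    rkoa_grade: int

    def __post_init__(self):
        doubled = sum(self.osteophyte_grades)
        assert abs(self.weighted_osteophyte_score - 0.5 * doubled) < 1e-12
        assert abs(self.rkoa_score - (self.weighted_osteophyte_score + self.jsn_grade)) < 1e-12
        assert 0.0 <= self.rkoa_score <= 9.0


def measure_mjsw(
    knee: LandmarkSet,
    exclude: tuple[int, ...] = MJSW_EXCLUDE,
) -> float:
    """Medial minimum joint-space width (mm).

    Minimum Euclidean distance over all pairs of points between the named
    ``medial_femoral_condyle`` and ``medial_tibial_plateau`` subsets,
    excluding outline indices that osteophyte protrusion can displace
    (default: the documented exclusion list for the template).
    """
    for name in ("medial_femoral_condyle", "medial_tibial_plateau"):
        if name not in knee.segment_map:
            raise ValueError(f"segment_map must name the {name!r} subset")
    excl = set(exclude)
    fem_idx = [i for i in knee.segment_map["medial_femoral_condyle"] if i not in excl]
    tib_idx = [i for i in knee.segment_map["medial_tibial_plateau"] if i not in excl]
    if not fem_idx or not tib_idx:
        raise ValueError("mJSW subsets are empty after applying exclusions")
    fem = knee.points[fem_idx]
    tib = knee.points[tib_idx]
    diff = fem[:, None, :] - tib[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    return float(d.min())


def jsn_grade(mjsw: float) -> int:
    """JSN grade 0-3 from the medial mJSW (mm); boundaries are inclusive on
    the >= side (3.0 mm -> grade 0, 2.5 mm -> grade 1, 2.0 mm -> grade 2)."""
    if not np.isfinite(mjsw) or mjsw < 0:
        raise ValueError(f"mJSW must be a non-negative finite value, got {mjsw}")
    g0, g1, g2 = JSN_THRESHOLDS
    if mjsw >= g0:
        return 0
    if mjsw >= g1:
        return 1
    if mjsw >= g2:
        return 2
    return 3


def osteophyte_grade(area: float, cutoffs=DEFAULT_AREA_CUTOFFS) -> int:
    """Osteophyte grade 0-3 for one site: the number of area cut-offs at or
    below ``area`` (mm²), capped at 3."""
    _validate_cutoffs(cutoffs)
    if not np.isfinite(area) or area < 0:
        raise ValueError(f"osteophyte area must be non-negative and finite, got {area}")
    return int(min(3, sum(area >= c for c in cutoffs)))


def _validate_cutoffs(cutoffs) -> None:
    cutoffs = tuple(cutoffs)
    if len(cutoffs) != 3 or not (cutoffs[0] < cutoffs[1] < cutoffs[2]):
        raise ValueError(f"cutoffs must be three strictly increasing areas, got {cutoffs}")
    if cutoffs[0] <= 0:
        raise ValueError("the first cutoff must be positive (area 0 is always grade 0)")


def grade_from_doubled_score(doubled_score: int, bin_edges=DEFAULT_GRADE_BIN_EDGES) -> int:
    """Map a doubled rKOA score (integer, 0-18) to the 0-4 grade."""
    edges = tuple(bin_edges)
    if list(edges) != sorted(edges) or len(edges) != 4:
        raise ValueError("grade bin edges must be four non-decreasing score values")
    grade = 0
    for e in edges:
        if doubled_score > 2 * e:
            grade += 1
    return grade


def rkoa_assess(
    areas,
    mjsw: float,
    cutoffs=DEFAULT_AREA_CUTOFFS,
    grade_bins=DEFAULT_GRADE_BIN_EDGES,
) -> RKOAAssessment:
    """Full rKOA assessment from the four site osteophyte areas (mm², in the
    order medial femur, lateral femur, medial tibia, lateral tibia) and the
    medial mJSW (mm)."""
    areas = tuple(float(a) for a in areas)
    if len(areas) != len(SITE_ORDER):
        raise ValueError(f"expected {len(SITE_ORDER)} site areas, got {len(areas)}")
    grades = tuple(osteophyte_grade(a, cutoffs) for a in areas)
    jsn = jsn_grade(mjsw)
    doubled = sum(grades) + 2 * jsn  # exact half-integer arithmetic
    return RKOAAssessment(
        mjsw=float(mjsw),
        jsn_grade=jsn,
        osteophyte_grades=grades,
        weighted_osteophyte_score=0.5 * sum(grades),
        rkoa_score=doubled / 2.0,
        rkoa_grade=grade_from_doubled_score(doubled, grade_bins),
    )
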