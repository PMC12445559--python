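"""Synthetic cohort generator emulating DXA-derived knee and total-body
landmark data.

Each simulated individual owns a deformed copy of the 129-point knee
template, a total-body landmark set for alignment, demographic covariates
and four osteophyte areas.  The deformation chain is:

1. smooth planted shape modes: template + sum sd_k * z_k * field_k, with
   z_k ~ N(0, 1) and the fields orthonormal and orthogonal to the similarity
   (translation/rotation/scale) directions of the template, so they survive
   Procrustes alignment and are recoverable by PCA in order of their SDs;
2. a varus/valgus rotation of the tibia + fibula about the knee centre by the
   latent varus angle (degrees; positive = varus);
3. a medial joint-space shrink proportional to max(0, varus), tapering from
   the medial plateau edge to the tibial spines;
4. osteophyte protrusion: outward displacement of 2-3 outline points per
   affected site, sized so the shoelace area between the displaced and
   original outline equals the drawn area in mm²;
5. iid isotropic Gaussian jitter on every landmark.

The total-body set is constructed so that the HKA recomputed from it equals
minus the same latent varus angle (exactly when ``noise_sd`` is 0), and the
anatomical femoral axis is offset from the mechanical one by a fixed
anatomic angle, so FTA = HKA + offset.

Outcome generation has two regimes:

* **naturalistic** (default, ``mode_effects`` empty): osteophyte presence and
  size are drawn from a varus-linked zero-inflated Gamma model and the rKOA
  grade follows from the grading module applied to the generated geometry;
* **embedded-effect** (``mode_effects`` maps generator mode index -> log-odds
  per SD): the rKOA grade is drawn from a baseline-category logit on the
  standardized latent mode scores (grade 0 as reference, intercepts matching
  the cohort grade marginals), and osteophyte areas are then constructed so
  the grading module reproduces exactly the drawn grade.  Conditional on a
  {0, g} contrast this is exactly the logistic model the association module
  fits, making per-SD odds-ratio recovery well-posed.  Mode index 1 is the
  varus rotation; indices 2..10 are the planted smooth fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .conventions import rotation_matrix, rotate_about
from .grading import DEFAULT_AREA_CUTOFFS, measure_mjsw
from .landmarks import BodyLandmarkSet, LandmarkSet
from .template import (
    MEDIAL_FEMORAL_CONDYLE,
    MEDIAL_TIBIAL_PLATEAU,
    MJSW_EXCLUDE,
    OSTEOPHYTE_SITES,
    SITE_ORDER,
    knee_centre,
    make_template,
    segment_map,
    site_normal,
)

#: Cohort rKOA grade marginals (grades 0, 1, 2, 3-4) used as the
#: baseline-category intercept anchor in the embedded-effect regime.
GRADE_MARGINALS = (0.807, 0.146, 0.036, 0.0116)

#: Ethnic-background category proportions for the emulated cohort.
ETHNICITY_PROBS = {
    "White": 0.9680,
    "Asian": 0.0106,
    "Chinese": 0.0027,
    "Black": 0.0059,
    "Mixed": 0.0046,
    "Other": 0.0056,
    "Unknown": 0.0026,
}

#: default SDs (mm) of the nine planted smooth shape modes (generator modes
#: 2..10), strictly decreasing so PCA recovers them in order
DEFAULT_SHAPE_MODE_SDS = tuple(0.9 * 0.85 ** k for k in range(9))

_RETRY_CAP = 10


class DegenerateGeometryError(RuntimeError):
    """Raised when an individual's geometry stays degenerate after retries."""


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic cohort.

    Demographic defaults follow the emulated cohort's descriptive statistics;
    the varus/osteophyte/noise parameters are generator assumptions with the
    rationale documented in docs/methods.md.
    """

    n_individuals: int
    seed: int = 0
    mean_age: float = 63.72          # years
    sd_age: float = 7.53             # years
    prop_male: float = 0.48
    height_mean_female: float = 163.59   # cm
    height_sd_female: float = 6.45
    height_mean_male: float = 177.29
    height_sd_male: float = 6.61
    weight_mean_female: float = 67.89    # kg
    weight_sd_female: float = 12.78
    weight_mean_male: float = 83.02
    weight_sd_male: float = 13.27
    ethnicity_probs: dict = field(default_factory=lambda: dict(ETHNICITY_PROBS))
    varus_mean_male: float = 1.51    # degrees (positive = varus); HKA = -varus
    varus_mean_female: float = -0.21
    varus_effect_sd: float = 2.0     # degrees
    jsn_varus_coupling: float = 0.18  # mm of medial-gap shrink per degree varus
    osteophyte_rate: float = 1.0     # scales naturalistic osteophyte hazard
    noise_sd: float = 0.25           # mm, isotropic landmark jitter
    anatomic_offset_deg: float = 5.5  # FTA - HKA
    #: SD (degrees) of an independent angular placement error on the
    #: total-body tibial axis, emulating the separate-scan derivation of the
    #: alignment angles.  Zero keeps HKA = -varus exact at noise_sd = 0.
    hka_noise_deg: float = 0.0
    #: draw osteophyte protrusions into the knee outline.  The emulated
    #: annotation protocol marked bone shape excluding osteophytes, so
    #: effect-recovery experiments may disable this to keep the scored
    #: outline free of outcome information.
    osteophytes_in_outline: bool = True
    shape_mode_sds: tuple = DEFAULT_SHAPE_MODE_SDS
    mode_effects: dict = field(default_factory=dict)  # mode index -> log-OR/SD
    #: log-odds per degree of the *measured* HKA in the embedded outcome
    #: model.  A negative value makes varus (negative HKA) knees higher risk
    #: and embeds a varus-mode association that is fully mediated by HKA.
    hka_effect: float = 0.0
    area_cutoffs: tuple = DEFAULT_AREA_CUTOFFS

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be at least 2")
        if not 0.0 <= self.prop_male <= 1.0:
            raise ValueError("prop_male must lie in [0, 1]")
        for name in ("sd_age", "height_sd_female", "height_sd_male",
                     "weight_sd_female", "weight_sd_male", "varus_effect_sd",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(s < 0 for s in self.shape_mode_sds):
            raise ValueError("shape_mode_sds must be non-negative")
        if abs(sum(self.ethnicity_probs.values()) - 1.0) > 1e-6:
            raise ValueError("ethnicity_probs must sum to 1")
        bad = [k for k in self.mode_effects if not 1 <= int(k) <= 1 + len(self.shape_mode_sds)]
        if bad:
            raise ValueError(f"mode_effects keys out of range: {bad}")


@dataclass
class SyntheticIndividual:
    knee_landmarks: LandmarkSet
    body_landmarks: BodyLandmarkSet
    covariates: dict
    true_varus_angle: float
    osteophyte_areas: tuple
    true_mjsw: float
    latent_modes: np.ndarray         # z_2..z_10, standardized
    drawn_grade: int | None = None   # embedded-effect regime only


# ---------------------------------------------------------------------------
# planted smooth shape fields


def _similarity_basis(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    n = len(points)
    basis = np.stack([
        np.tile([1.0, 0.0], n),                       # translate x
        np.tile([0.0, 1.0], n),                       # translate y
        np.column_stack([-c[:, 1], c[:, 0]]).ravel(),  # rotate
        c.ravel(),                                    # scale
    ])
    q, _ = np.linalg.qr(basis.T)
    return q.T  # orthonormal (4, 2n)


def planted_fields(template: LandmarkSet | None = None, n_fields: int = 9) -> np.ndarray:
    """Deterministic orthonormal smooth deformation fields (n_fields, 258).

    Low-frequency Fourier fields on the outline index, projected off the
    template's similarity directions and orthonormalised; unit L2 norm, so a
    latent score of z with SD s displaces the outline by an RMS of
    ``s * z / sqrt(129)`` mm per point.
    """
    if template is None:
        template = make_template()
    pts = template.points
    n = len(pts)
    t = np.arange(n) / n
    rng = np.random.default_rng(987654321)  # fixed: the fields are a constant
    raw = np.empty((n_fields, 2 * n))
    for j in range(n_fields):
        fx = np.zeros(n)
        fy = np.zeros(n)
        for f in range(1, 6):
            ax, bx, ay, by = rng.normal(0.0, 1.0 / f, size=4)
            fx += ax * np.cos(2 * np.pi * f * t) + bx * np.sin(2 * np.pi * f * t)
            fy += ay * np.cos(2 * np.pi * f * t) + by * np.sin(2 * np.pi * f * t)
        raw[j] = np.column_stack([fx, fy]).ravel()
    sim = _similarity_basis(pts)
    raw -= (raw @ sim.T) @ sim
    q, _ = np.linalg.qr(raw.T)
    fields = q.T[:n_fields]
    # deterministic sign: largest-|loading| coordinate positive
    for j in range(n_fields):
        lead = np.argmax(np.abs(fields[j]))
        if fields[j, lead] < 0:
            fields[j] = -fields[j]
    return fields


# ---------------------------------------------------------------------------
# osteophyte geometry


def apply_osteophyte(points: np.ndarray, site: str, area: float,
                     seg_map: dict) -> np.ndarray:
    """Displace the site's outline points outward so the shoelace area of the
    displaced-vs-original polygon equals ``area`` (mm²).  Returns new points.
    """
    if area <= 0:
        return points
    idx = OSTEOPHYTE_SITES[site]
    bone = "femur" if "femur" in site else "tibia"
    n_hat = site_normal(points, idx, seg_map[bone])
    chord = np.linalg.norm(points[idx[-1]] - points[idx[0]])
    d = area / chord
    out = points.copy()
    out[idx] = out[idx] + d * n_hat
    return out


def shoelace_area(polygon: np.ndarray) -> float:
    x, y = polygon[:, 0], polygon[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ---------------------------------------------------------------------------
# outcome models


def _grade_logit_intercepts() -> np.ndarray:
    p = np.asarray(GRADE_MARGINALS)
    return np.log(p[1:] / p[0])


def _draw_embedded_grade(params: CohortParams, z_std: np.ndarray, hka: float,
                         rng) -> int:
    """Baseline-category logit draw of the grade category (0, 1, 2, 3)
    where category 3 stands for the merged 3-4 band."""
    lam = np.zeros(1 + len(params.shape_mode_sds))
    for k, beta in params.mode_effects.items():
        lam[int(k) - 1] = beta
    lp = _grade_logit_intercepts() + float(lam @ z_std) + params.hka_effect * hka
    w = np.concatenate([[1.0], np.exp(lp)])
    return int(rng.choice(4, p=w / w.sum()))


_GRADE_TO_OSTEO_SCORE2 = {0: 0, 1: 2, 2: 4}  # doubled weighted score


def _site_grades_for(doubled_weighted: int, rng) -> np.ndarray:
    """Random allocation of a doubled weighted osteophyte score (= sum of the
    four site grades) across the sites, each capped at grade 3."""
    grades = np.zeros(4, dtype=int)
    remaining = int(doubled_weighted)
    while remaining > 0:
        open_sites = np.flatnonzero(grades < 3)
        grades[rng.choice(open_sites)] += 1
        remaining -= 1
    return grades


def _area_for_grade(g: int, cutoffs, rng) -> float:
    if g == 0:
        return 0.0
    c = list(cutoffs) + [2.0 * cutoffs[-1]]
    return float(rng.uniform(c[g - 1], c[g]))


def _naturalistic_areas(params: CohortParams, varus: float, rng) -> np.ndarray:
    """Zero-inflated Gamma osteophyte areas, hazard increasing with varus at
    the medial sites and mildly at the lateral ones."""
    areas = np.zeros(4)
    if params.osteophyte_rate <= 0:
        return areas
    for i, site in enumerate(SITE_ORDER):
        boost = 0.25 if "medial" in site else 0.08
        p = min(0.9, 0.045 * params.osteophyte_rate * np.exp(boost * max(varus, 0.0)))
        if rng.random() < p:
            areas[i] = rng.gamma(shape=1.1, scale=1.3)
    return areas


# ---------------------------------------------------------------------------
# individual and cohort generation


def _body_landmarks(varus_deg: float, params: CohortParams, rng, ident: str) -> BodyLandmarkSet:
    """Total-body landmark construction for an *effective* (already
    measurement-perturbed) varus angle."""
    head = np.array([0.0, 780.0])
    notch = np.array([0.0, 360.0])
    u = np.array([0.0, -1.0])                       # femoral mechanical axis, distal
    t_dir = rotation_matrix(varus_deg) @ u          # CCW by varus => HKA = -varus
    plateau = notch + np.array([0.0, -10.0])
    talus = plateau + 380.0 * t_dir
    a_dir = rotation_matrix(params.anatomic_offset_deg) @ u
    shaft0 = head + np.array([0.0, -160.0])
    shaft = shaft0 + np.outer([0.0, 60.0, 120.0], a_dir)
    theta = 2.0 * np.pi * np.arange(7) / 7.0
    ring = head + 23.0 * np.column_stack([np.cos(theta), np.sin(theta)])

    def jit(x):
        return x + rng.normal(0.0, params.noise_sd, size=np.shape(x)) if params.noise_sd > 0 else x

    return BodyLandmarkSet(
        femoral_head_ring=jit(ring),
        intercondylar_notch=jit(notch),
        tibial_plateau_centre=jit(plateau),
        talus_centre=jit(talus),
        femoral_shaft_points=jit(shaft),
        id=ident,
    )


_MJSW_FEM = np.array([i for i in MEDIAL_FEMORAL_CONDYLE if i not in MJSW_EXCLUDE])
_MJSW_TIB = np.array([i for i in MEDIAL_TIBIAL_PLATEAU if i not in MJSW_EXCLUDE])


def _surfaces_intact(pts: np.ndarray) -> bool:
    """Joint surfaces must not interpenetrate: every medial femoral surface
    point stays above every medial plateau point."""
    return bool(np.all(np.isfinite(pts))
                and pts[_MJSW_FEM, 1].min() > pts[_MJSW_TIB, 1].max())


def _draw_covariates(params: CohortParams, rng) -> dict:
    male = rng.random() < params.prop_male
    if male:
        height = rng.normal(params.height_mean_male, params.height_sd_male)
        weight = rng.normal(params.weight_mean_male, params.weight_sd_male)
    else:
        height = rng.normal(params.height_mean_female, params.height_sd_female)
        weight = rng.normal(params.weight_mean_female, params.weight_sd_female)
    cats = list(params.ethnicity_probs)
    probs = np.array([params.ethnicity_probs[c] for c in cats])
    return {
        "sex": "male" if male else "female",
        "age": float(rng.normal(params.mean_age, params.sd_age)),
        "height": float(height),
        "weight": float(weight),
        "ethnicity": str(rng.choice(cats, p=probs / probs.sum())),
    }


def generate_individual(params: CohortParams, rng, ident: str = "ind",
                        _template=None, _fields=None) -> SyntheticIndividual:
    """Draw one synthetic individual.

    Degenerate geometry (joint surfaces crossing after jitter) is regenerated
    with fresh randomness up to a cap of 10, then raises
    :class:`DegenerateGeometryError`.
    """
    template = _template if _template is not None else make_template()
    fields = _fields if _fields is not None else planted_fields(template)
    seg = template.segment_map
    centre = knee_centre(template)
    covs = _draw_covariates(params, rng)

    for _attempt in range(_RETRY_CAP):
        mu_v = params.varus_mean_male if covs["sex"] == "male" else params.varus_mean_female
        varus = float(mu_v + params.varus_effect_sd * rng.standard_normal())
        z = rng.standard_normal(len(params.shape_mode_sds))

        pts = template.points.copy()
        sds = np.asarray(params.shape_mode_sds)
        if len(sds):
            pts = pts + ((sds * z) @ fields[: len(sds)]).reshape(-1, 2)

        # varus/valgus: rigid rotation of tibia + fibula about the knee centre
        tf = np.concatenate([seg["tibia"], seg["fibula"]])
        pts[tf] = rotate_about(pts[tf], varus, centre)

        # medial joint-space shrink coupled to varus, tapered toward the spines
        if params.jsn_varus_coupling > 0 and varus > 0:
            xs = template.points[MEDIAL_TIBIAL_PLATEAU, 0]
            taper = (xs - xs.min()) / (xs.max() - xs.min())
            pts[MEDIAL_TIBIAL_PLATEAU, 1] += params.jsn_varus_coupling * varus * taper

        # effective varus seen by the total-body scan (separate placement
        # error), fixed before the outcome draw so HKA can act as mediator
        varus_body = varus
        if params.hka_noise_deg > 0:
            varus_body = varus + params.hka_noise_deg * rng.standard_normal()

        # outcome + osteophytes
        drawn_grade: int | None = None
        if params.mode_effects or params.hka_effect != 0.0:
            z_std = np.concatenate([[
                (varus - mu_v) / params.varus_effect_sd if params.varus_effect_sd > 0 else 0.0
            ], z])
            drawn_grade = _draw_embedded_grade(params, z_std, -varus_body, rng)
            if drawn_grade < 3:
                doubled = _GRADE_TO_OSTEO_SCORE2[drawn_grade]
            else:
                # split the merged 3-4 band with the cohort's internal ratio
                doubled = 10 if rng.random() < 0.31 else 7
            site_grades = _site_grades_for(doubled, rng)
            areas = np.array([
                _area_for_grade(g, params.area_cutoffs, rng) for g in site_grades
            ])
        else:
            areas = _naturalistic_areas(params, varus, rng)

        if params.osteophytes_in_outline:
            for site, area in zip(SITE_ORDER, areas):
                pts = apply_osteophyte(pts, site, float(area), seg)

        clean_pts = pts
        if params.noise_sd > 0:
            pts = pts + rng.normal(0.0, params.noise_sd, size=pts.shape)

        if _surfaces_intact(clean_pts) and _surfaces_intact(pts):
            knee = LandmarkSet(points=pts, segment_map=segment_map(), id=ident)
            true_mjsw = measure_mjsw(
                LandmarkSet(points=clean_pts, segment_map=segment_map(), id=ident))
            body = _body_landmarks(varus_body, params, rng, ident)
            return SyntheticIndividual(
                knee_landmarks=knee,
                body_landmarks=body,
                covariates=dict(covs, id=ident),
                true_varus_angle=varus,
                osteophyte_areas=tuple(float(a) for a in areas),
                true_mjsw=float(true_mjsw),
                latent_modes=z,
                drawn_grade=drawn_grade,
            )
    raise DegenerateGeometryError(
        f"individual {ident}: geometry degenerate after {_RETRY_CAP} attempts"
    )


@dataclass
class Cohort:
    params: CohortParams
    individuals: list
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.individuals)

    def knee_arrays(self) -> np.ndarray:
        return np.stack([ind.knee_landmarks.points for ind in self.individuals])

    def covariates_frame(self) -> pd.DataFrame:
        return pd.DataFrame([ind.covariates for ind in self.individuals]).set_index("id")


def generate_cohort(params: CohortParams) -> Cohort:
    """Generate a reproducible cohort plus a truth table of every latent value
    (varus angle, planted-mode scores, pre-noise mJSW, osteophyte areas and,
    in the embedded-effect regime, the drawn grade)."""
    rng = np.random.default_rng(params.seed)
    template = make_template()
    fields = planted_fields(template)
    individuals = []
    rows = []
    for i in range(params.n_individuals):
        ident = f"ind{i:06d}"
        ind = generate_individual(params, rng, ident, _template=template, _fields=fields)
        individuals.append(ind)
        row = {
            "id": ident,
            "sex": ind.covariates["sex"],
            "age": ind.covariates["age"],
            "height": ind.covariates["height"],
            "weight": ind.covariates["weight"],
            "ethnicity": ind.covariates["ethnicity"],
            "true_varus_angle": ind.true_varus_angle,
            "true_mjsw": ind.true_mjsw,
            "drawn_grade": np.nan if ind.drawn_grade is None else ind.drawn_grade,
        }
        for site, area in zip(SITE_ORDER, ind.osteophyte_areas):
            row[f"area_{site}"] = area
        for k, zk in enumerate(ind.latent_modes, start=2):
            row[f"z_mode{k}"] = zk
        rows.append(row)
    return Cohort(params=params, individuals=individuals,
                  truth=pd.DataFrame(rows).set_index("id"))


def with_params(params: CohortParams, **overrides) -> CohortParams:
    """Convenience: a copy of ``params`` with fields replaced."""
    return replace(params, **overrides)
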