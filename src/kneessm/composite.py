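"""Composite shape vectors: the knee shape associated with an rKOA grade.

A composite is built from the per-SD logistic log-odds coefficients of the
first 10 shape modes: each mode is weighted by its beta coefficient times
its unstandardised SD, an arbitrary visual scaling (default 5) is applied,
and the weighted modes are summed onto the mean shape:

    shape = mean + scale * sum_k beta_k * raw_sd_k * mode_k   (k = 1..10)

All ten betas enter regardless of significance.  For display, composites
are overlaid on the mean by *pure translation* anchored at outline point 17
(the distolateral femoral corner) — no re-rotation, so varus/valgus
differences stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import N_POINTS, LandmarkSet
from .shape import ShapeModelResults
from .template import DISTOLATERAL_FEMUR_INDEX


@dataclass
class CompositeShape:
    grade_contrast: str
    model_spec: int
    shape: LandmarkSet
    reference: LandmarkSet
    betas: np.ndarray
    scale: float

    def __post_init__(self):
        if self.shape.points.shape[0] != N_POINTS:
            raise ValueError("composite shape must have 129 points")
        self.betas = np.asarray(self.betas, float)
        if self.betas.shape != (10,):
            raise ValueError("exactly 10 beta coefficients are required")


def composite_vector(model: ShapeModelResults, betas, scale: float = 5.0) -> LandmarkSet:
    """Composite landmark configuration from 10 log-OR coefficients.

    shape = mean + scale * sum_{k=1..10} beta_k * raw_sd_k * mode_k
    """
    betas = np.asarray(betas, float)
    if betas.shape != (10,):
        raise ValueError(f"expected 10 betas, got shape {betas.shape}")
    if not np.all(np.isfinite(betas)):
        raise ValueError("betas must be finite")
    if model.n_modes < 10:
        raise ValueError(f"model has only {model.n_modes} modes; 10 are required")
    delta = scale * (betas * model.raw_sds[:10]) @ model.modes[:10]
    pts = (model.mean_shape + delta).reshape(-1, 2)
    return LandmarkSet(points=pts, segment_map=model.segment_map, id="composite")


def align_at_point(shape: LandmarkSet, reference: LandmarkSet,
                   point_index: int = DISTOLATERAL_FEMUR_INDEX) -> LandmarkSet:
    """Translate ``shape`` so its ``point_index`` landmark coincides with the
    reference's; no rotation or scaling is applied."""
    if not 0 <= point_index < N_POINTS:
        raise IndexError(f"point index {point_index} out of range 0..{N_POINTS - 1}")
    offset = reference.points[point_index] - shape.points[point_index]
    return shape.copy(points=shape.points + offset)


def _segment_paths(lms: LandmarkSet):
    closed = {"fibula", "patella"}
    for seg in LandmarkSet.SEGMENTS:
        pts = lms.segment(seg)
        if seg in closed:
            pts = np.vstack([pts, pts[:1]])
        yield pts


def render_overlay(composites: dict[str, LandmarkSet], reference: LandmarkSet,
                   out_path=None, point_index: int = DISTOLATERAL_FEMUR_INDEX,
                   title: str | None = None):
    """One panel per grade contrast: reference outline dashed black,
    composite solid red, both anchored at ``point_index``."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    n = len(composites)
    fig = Figure(figsize=(4 * n, 5))
    FigureCanvasAgg(fig)
    for i, (contrast, comp) in enumerate(composites.items(), start=1):
        ax = fig.add_subplot(1, n, i)
        shifted = align_at_point(comp, reference, point_index)
        for pts in _segment_paths(reference):
            ax.plot(pts[:, 0], pts[:, 1], "k--", lw=1.0)
        for pts in _segment_paths(shifted):
            ax.plot(pts[:, 0], pts[:, 1], "r-", lw=1.2)
        ax.set_title(f"rKOA {contrast}")
        ax.set_aspect("equal")
        ax.axis("off")
    if title:
        fig.suptitle(title)
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig


def composites_from_association(model: ShapeModelResults, assoc_results,
                                model_spec: int = 3, contrasts=("1v0", "2v0", "34v0"),
                                scale: float = 5.0) -> dict[str, CompositeShape]:
    """Build one composite per grade contrast from fitted association betas
    (combined-sex stratum of the requested covariate model)."""
    reference = model.mean_landmarks()
    out = {}
    for contrast in contrasts:
        betas = assoc_results.betas(contrast, model_spec).to_numpy()
        shape = composite_vector(model, betas, scale=scale)
        out[contrast] = CompositeShape(
            grade_contrast=contrast, model_spec=model_spec, shape=shape,
            reference=reference, betas=betas, scale=scale,
        )
    return out
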