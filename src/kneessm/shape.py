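"""Point-distribution shape model: generalized Procrustes alignment followed
by principal component analysis of the aligned landmark coordinates.

:func:`gpa_align` performs full similarity alignment (translation, scale,
rotation; reflections forbidden) of a set of landmark configurations to an
iteratively re-estimated mean.  :class:`ShapePCA` is the model object; its
:meth:`ShapePCA.fit` returns a :class:`ShapeModelResults` carrying the mean
shape, orthonormal variation modes, per-mode variances and unstandardised
SDs.  An individual's *mode score* is the projection of their aligned shape
onto a mode divided by that mode's training SD — i.e. how many standard
deviations their shape deviates from the mean along that mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .landmarks import N_POINTS, LandmarkSet


class GPAConvergenceError(RuntimeError):
    pass


@dataclass
class GPAResult:
    """Aligned configurations and consensus from generalized Procrustes
    alignment.  ``aligned`` has shape (n, k, 2) in the unit-centroid-size
    frame; ``mean`` is the unit-size consensus."""

    aligned: np.ndarray
    mean: np.ndarray
    n_iter: int
    residual: float


def _as_array(shapes) -> np.ndarray:
    if isinstance(shapes, np.ndarray):
        arr = shapes.astype(float)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValueError("expected an (n, k, 2) landmark array")
        return arr.copy()
    pts = [s.points if isinstance(s, LandmarkSet) else np.asarray(s, float) for s in shapes]
    k = {p.shape for p in pts}
    if len(k) != 1:
        raise ValueError(f"all shapes must share one point count, got {sorted(k)}")
    return np.stack(pts).astype(float)


def _centre_and_scale(arr: np.ndarray) -> np.ndarray:
    arr = arr - arr.mean(axis=1, keepdims=True)
    size = np.sqrt((arr ** 2).sum(axis=(1, 2)))
    if np.any(size <= 0) or not np.all(np.isfinite(size)):
        raise ValueError("degenerate shape: zero centroid size (all points coincident)")
    return arr / size[:, None, None]


def _rotate_to(arr: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation-only Procrustes of each configuration onto ``target``
    (vectorised; det(R) = +1 always, since a 2-D rotation fit via the signed
    angle cannot reflect)."""
    xs, ys = arr[..., 0], arr[..., 1]
    tx, ty = target[:, 0], target[:, 1]
    num = (xs * ty - ys * tx).sum(axis=1)
    den = (xs * tx + ys * ty).sum(axis=1)
    theta = np.arctan2(num, den)
    c, s = np.cos(theta), np.sin(theta)
    out = np.empty_like(arr)
    out[..., 0] = c[:, None] * xs - s[:, None] * ys
    out[..., 1] = s[:, None] * xs + c[:, None] * ys
    return out


def _canonicalise(mean: np.ndarray, arr: np.ndarray):
    """Rotate the consensus (and all aligned shapes) into a canonical frame
    determined only by the consensus geometry: major principal axis along +y,
    sign fixed so the largest-|value| mean coordinate is positive.  Makes the
    GPA output independent of the orientation of the input shapes."""
    cov = np.cov(mean.T)
    _, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]  # major axis
    theta = np.arctan2(v[0], v[1])
    best = None
    for extra in (0.0, np.pi):
        c, s = np.cos(theta + extra), np.sin(theta + extra)
        rot = np.array([[c, -s], [s, c]])
        m = mean @ rot.T
        flat = m.reshape(-1)
        if flat[np.argmax(np.abs(flat))] >= 0:
            best = rot
            break
    if best is None:  # pragma: no cover - one of the two signs always works
        best = rot
    return mean @ best.T, arr @ best.T


def gpa_align(shapes, tol: float = 1e-10, max_iter: int = 100) -> GPAResult:
    """Generalized Procrustes alignment of >= 2 equal-point-count shapes.

    Each configuration is centred, scaled to unit centroid size and
    iteratively rotated to the evolving mean; the mean is re-scaled to unit
    centroid size at every iteration.  Iteration stops when the RMS change in
    the mean drops below ``tol``.

    Raises
    ------
    GPAConvergenceError
        If the mean has not stabilised after ``max_iter`` iterations; the
        message names the last residual.
    """
    arr = _as_array(shapes)
    if arr.shape[0] < 2:
        raise ValueError("GPA needs at least two shapes")
    if not np.all(np.isfinite(arr)):
        raise ValueError("shapes contain non-finite coordinates")
    arr = _centre_and_scale(arr)
    mean = arr[0].copy()
    mean /= np.sqrt((mean ** 2).sum())
    residual = np.inf
    for it in range(1, max_iter + 1):
        arr = _rotate_to(arr, mean)
        new_mean = arr.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        norm = np.sqrt((new_mean ** 2).sum())
        if norm <= 0:
            raise ValueError("degenerate consensus: shapes cancel to a point")
        new_mean /= norm
        residual = float(np.sqrt(((new_mean - mean) ** 2).mean()))
        mean = new_mean
        if residual < tol:
            mean, arr = _canonicalise(mean, arr)
            # final pass: every shape exactly rotation-optimal w.r.t. the
            # converged mean (required for exact score round-trips)
            arr = _rotate_to(arr, mean)
            return GPAResult(aligned=arr, mean=mean, n_iter=it, residual=residual)
    raise GPAConvergenceError(
        f"GPA did not converge in {max_iter} iterations (last mean change RMS {residual:.3e})"
    )


@dataclass
class ModeScores:
    """Standardized per-mode scores (SD units) for a set of individuals."""

    scores: np.ndarray  # (n, k_modes)
    ids: list[str] = field(default_factory=list)
    flagged_modes: tuple[int, ...] = ()  # zero-variance modes, scores NaN


class ShapePCA:
    """Point-distribution shape model of 2-D landmark configurations.

    Parameters
    ----------
    shapes : sequence of LandmarkSet or (n, k, 2) array
        Training configurations (raw coordinates; alignment is internal).
    segment_map : dict, optional
        Segment index map carried through to reconstructed shapes (defaults
        to the map of the first LandmarkSet, if any).
    """

    def __init__(self, shapes, segment_map: dict | None = None):
        self._raw = shapes
        if segment_map is None and not isinstance(shapes, np.ndarray):
            first = next(iter(shapes))
            if isinstance(first, LandmarkSet):
                segment_map = first.segment_map
        self.segment_map = segment_map or {}
        self.ids = [
            s.id for s in shapes if isinstance(s, LandmarkSet)
        ] if not isinstance(shapes, np.ndarray) else []

    def fit(self, tol: float = 1e-10, max_iter: int = 100) -> "ShapeModelResults":
        """Align the training shapes and eigen-decompose their covariance.

        Retains min(n - 1, 2k) modes ordered by decreasing variance, with a
        deterministic sign convention (the largest-|loading| coordinate of
        each mode is positive).  Requires >= 3 training shapes.
        """
        gpa = gpa_align(self._raw, tol=tol, max_iter=max_iter)
        n = gpa.aligned.shape[0]
        if n < 3:
            raise ValueError("shape-model fit requires at least 3 training shapes")
        # tangent-space projection: rescale each aligned shape so its dot
        # product with the consensus is 1, putting all shapes in the plane
        # tangent to the unit shape sphere at the mean.  Residuals are then
        # exactly orthogonal to the rotation and scale directions, which
        # makes mode scores exact under reconstruct -> score round trips.
        anchor = gpa.mean.reshape(-1)
        X = gpa.aligned.reshape(n, -1)
        X = X / (X @ anchor)[:, None]
        mean_flat = X.mean(axis=0)
        centred = X - mean_flat
        # SVD of the centred data == eigen-decomposition of the covariance
        _, svals, vt = np.linalg.svd(centred, full_matrices=False)
        n_modes = min(n - 1, X.shape[1])
        modes = vt[:n_modes]
        variances = (svals[:n_modes] ** 2) / (n - 1)
        # deterministic sign: largest-|loading| coordinate positive
        for j in range(n_modes):
            lead = np.argmax(np.abs(modes[j]))
            if modes[j, lead] < 0:
                modes[j] = -modes[j]
        degenerate = bool(variances.sum() <= 1e-24)
        return ShapeModelResults(
            mean_shape=mean_flat,
            modes=modes,
            variances=variances,
            n_training=n,
            gpa=gpa,
            segment_map=self.segment_map,
            training_ids=list(self.ids),
            degenerate=degenerate,
            tangent_anchor=anchor,
            training_matrix=X,
        )


class ShapeModelResults:
    """Fitted point-distribution model.

    Attributes
    ----------
    mean_shape : (2k,) flattened mean of the aligned training shapes.
    modes : (m, 2k) orthonormal variation modes, variance-ordered.
    variances : (m,) per-mode variance of the aligned training projections.
    raw_sds : (m,) unstandardised per-mode SDs (sqrt of ``variances``).
    """

    def __init__(self, mean_shape, modes, variances, n_training, gpa=None,
                 segment_map=None, training_ids=None, degenerate=False,
                 tangent_anchor=None, training_matrix=None):
        self.mean_shape = np.asarray(mean_shape, float)
        self.modes = np.asarray(modes, float)
        variances = np.asarray(variances, float)
        # clamp numerically-zero modes so their scores are flagged, not huge
        tiny = max(float(variances.max(initial=0.0)), 1.0) * 1e-24
        self.variances = np.where(variances > tiny, variances, 0.0)
        self.raw_sds = np.sqrt(self.variances)
        self.tangent_anchor = (self.mean_shape if tangent_anchor is None
                               else np.asarray(tangent_anchor, float))
        self.training_matrix = training_matrix
        self.n_training = int(n_training)
        self.gpa = gpa
        self.segment_map = segment_map or {}
        self.training_ids = training_ids or []
        self.degenerate = bool(degenerate)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    # -- scoring -----------------------------------------------------------

    def _align_one(self, points: np.ndarray) -> np.ndarray:
        """Single similarity Procrustes fit of one configuration onto the
        model consensus: centre, optimal rotation (no reflection), then the
        tangent-space scaling used at training time (dot with anchor = 1)."""
        pts = np.asarray(points, float)
        anchor_pts = self.tangent_anchor.reshape(-1, 2)
        if pts.shape != anchor_pts.shape:
            raise ValueError(f"expected {anchor_pts.shape} points, got {pts.shape}")
        arr = _centre_and_scale(pts[None])
        flat = _rotate_to(arr, anchor_pts)[0].reshape(-1)
        denom = flat @ self.tangent_anchor
        if denom <= 0:
            raise ValueError("shape is orthogonal to the model consensus")
        return flat / denom

    def score(self, shape) -> np.ndarray:
        """Standardized mode scores for one shape (or an (n, k, 2) stack).

        score_k = (aligned shape - mean) . mode_k / raw_sd_k.  Zero-variance
        modes yield NaN scores (flagged via :meth:`scores_table`).
        """
        if isinstance(shape, LandmarkSet):
            shape = shape.points
        arr = np.asarray(shape, float)
        single = arr.ndim == 2
        stack = arr[None] if single else arr
        out = np.empty((stack.shape[0], self.n_modes))
        for i, pts in enumerate(stack):
            aligned = self._align_one(pts)
            proj = self.modes @ (aligned - self.mean_shape)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[i] = np.where(self.raw_sds > 0, proj / self.raw_sds, np.nan)
        return out[0] if single else out

    def scores_table(self, shapes, ids=None, n_modes: int = 10) -> "pandas.DataFrame":
        """DataFrame of the first ``n_modes`` standardized scores
        (columns ksm1..ksmN), indexed by individual id."""
        import pandas as pd

        arr = _as_array(shapes)
        if ids is None:
            ids = [s.id for s in shapes] if not isinstance(shapes, np.ndarray) else [
                str(i) for i in range(arr.shape[0])
            ]
        k = min(n_modes, self.n_modes)
        scores = self.score(arr)[:, :k]
        return pd.DataFrame(
            scores, columns=[f"ksm{j + 1}" for j in range(k)], index=pd.Index(ids, name="id")
        )

    # -- reconstruction ------------------------------------------------------

    def reconstruct(self, scores, k_modes: int | None = None) -> LandmarkSet:
        """Shape at the given standardized scores: mean + sum score_k *
        raw_sd_k * mode_k over the first ``k_modes`` modes (aligned frame)."""
        scores = np.asarray(scores, float)
        if k_modes is None:
            k_modes = scores.shape[-1]
        if k_modes > self.n_modes:
            raise ValueError(f"k_modes={k_modes} exceeds available modes ({self.n_modes})")
        delta = (scores[:k_modes] * self.raw_sds[:k_modes]) @ self.modes[:k_modes]
        pts = (self.mean_shape + delta).reshape(-1, 2)
        if pts.shape[0] == N_POINTS:
            return LandmarkSet(points=pts, segment_map=self.segment_map, id="reconstruction")
        return pts

    def variance_explained(self, k: int) -> float:
        """Fraction of total shape variance captured by the first ``k``
        modes; non-decreasing in k and 1.0 at k = n_modes."""
        if not 1 <= k <= self.n_modes:
            raise ValueError(f"k must be in [1, {self.n_modes}], got {k}")
        total = self.variances.sum()
        if total <= 0:
            raise ValueError("degenerate model: zero total variance")
        return float(self.variances[:k].sum() / total)

    # -- presentation / persistence -----------------------------------------

    def summary(self, n_modes: int = 10) -> str:
        k = min(n_modes, self.n_modes)
        lines = [
            "Point-distribution shape model",
            "=" * 46,
            f"training shapes: {self.n_training}    modes retained: {self.n_modes}",
            f"degenerate: {self.degenerate}",
            "",
            f"{'mode':>4}  {'raw SD':>12}  {'var %':>7}  {'cum %':>7}",
        ]
        total = self.variances.sum()
        cum = 0.0
        for j in range(k):
            frac = self.variances[j] / total if total > 0 else np.nan
            cum += frac
            lines.append(f"{j + 1:>4}  {self.raw_sds[j]:>12.6g}  {100 * frac:>6.2f}%  {100 * cum:>6.2f}%")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        """Serialise the model (mean, modes, variances, n_training,
        segment_map) to a single JSON archive."""
        payload = {
            "schema": "kneessm-shape-model-v1",
            "n_training": self.n_training,
            "mean_shape": self.mean_shape.tolist(),
            "modes": self.modes.tolist(),
            "variances": self.variances.tolist(),
            "segment_map": {k: np.asarray(v).tolist() for k, v in self.segment_map.items()},
            "degenerate": self.degenerate,
            "tangent_anchor": self.tangent_anchor.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ShapeModelResults":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != "kneessm-shape-model-v1":
            raise ValueError(f"unrecognised model schema in {path}")
        return cls(
            mean_shape=np.array(payload["mean_shape"]),
            modes=np.array(payload["modes"]),
            variances=np.array(payload["variances"]),
            n_training=payload["n_training"],
            segment_map={k: np.array(v, int) for k, v in payload["segment_map"].items()},
            degenerate=payload.get("degenerate", False),
            tangent_anchor=np.array(payload["tangent_anchor"])
            if "tangent_anchor" in payload else None,
        )

    def mean_landmarks(self) -> LandmarkSet:
        pts = self.mean_shape.reshape(-1, 2)
        if pts.shape[0] != N_POINTS:
            raise ValueError("mean_landmarks requires a 129-point model")
        return LandmarkSet(points=pts, segment_map=self.segment_map, id="mean")
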