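"""Landmark containers for knee outlines and total-body alignment points."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: number of points in the knee outline model
N_POINTS = 129


@dataclass
class LandmarkSet:
    """One individual's 2-D knee landmark configuration.

    Parameters
    ----------
    points : ndarray, shape (129, 2)
        Outline coordinates in mm (medial at larger x, y superior).
    segment_map : dict[str, ndarray]
        Named index subsets.  The keys ``femur``, ``tibia``, ``fibula`` and
        ``patella`` partition ``range(129)``; further named subsets (e.g.
        ``medial_femoral_condyle``) may overlap the segments.
    id : str
        Individual identifier.
    """

    points: np.ndarray
    segment_map: dict[str, np.ndarray] = field(default_factory=dict)
    id: str = ""

    SEGMENTS = ("femur", "tibia", "fibula", "patella")

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_POINTS, 2):
            raise ValueError(
                f"expected ({N_POINTS}, 2) landmark array, got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        self.segment_map = {k: np.asarray(v, dtype=int) for k, v in self.segment_map.items()}
        if self.segment_map:
            self._check_partition()

    def _check_partition(self) -> None:
        present = [s for s in self.SEGMENTS if s in self.segment_map]
        if len(present) < len(self.SEGMENTS):
            missing = set(self.SEGMENTS) - set(present)
            raise ValueError(f"segment_map missing segments: {sorted(missing)}")
        idx = np.concatenate([self.segment_map[s] for s in self.SEGMENTS])
        if sorted(idx.tolist()) != list(range(N_POINTS)):
            raise ValueError("femur/tibia/fibula/patella must partition the 129 indices")

    def segment(self, name: str) -> np.ndarray:
        """Coordinates of a named subset."""
        return self.points[self.segment_map[name]]

    def copy(self, points: np.ndarray | None = None, id: str | None = None) -> "LandmarkSet":
        return LandmarkSet(
            points=self.points.copy() if points is None else np.asarray(points, float),
            segment_map={k: v.copy() for k, v in self.segment_map.items()},
            id=self.id if id is None else id,
        )

    def flattened(self) -> np.ndarray:
        """(258,) vector, x/y interleaved row-wise."""
        return self.points.reshape(-1)


@dataclass
class BodyLandmarkSet:
    """Total-body landmark subset needed for HKA/FTA.

    All coordinates in mm, same frontal-plane frame as the knee set.
    """

    femoral_head_ring: np.ndarray  # (>=3, 2); seven points in practice
    intercondylar_notch: np.ndarray  # (2,)
    tibial_plateau_centre: np.ndarray  # (2,)
    talus_centre: np.ndarray  # (2,)
    femoral_shaft_points: np.ndarray  # (>=2, 2)
    id: str = ""

    def __post_init__(self) -> None:
        self.femoral_head_ring = np.atleast_2d(np.asarray(self.femoral_head_ring, float))
        self.intercondylar_notch = np.asarray(self.intercondylar_notch, float).reshape(2)
        self.tibial_plateau_centre = np.asarray(self.tibial_plateau_centre, float).reshape(2)
        self.talus_centre = np.asarray(self.talus_centre, float).reshape(2)
        self.femoral_shaft_points = np.atleast_2d(np.asarray(self.femoral_shaft_points, float))
        for name in ("femoral_head_ring", "intercondylar_notch", "tibial_plateau_centre",
                     "talus_centre", "femoral_shaft_points"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite coordinates")
        if self.femoral_head_ring.shape[0] < 3:
            raise ValueError("need at least 3 femoral head ring points")
        if self.femoral_shaft_points.shape[0] < 2:
            raise ValueError("need at least 2 femoral shaft points")
        span = np.linalg.norm(
            self.femoral_shaft_points.max(axis=0) - self.femoral_shaft_points.min(axis=0)
        )
        if span <= 10.0:
            raise ValueError("femoral shaft points must span more than 10 mm")
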