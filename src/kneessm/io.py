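"""CSV/JSON readers and writers with strict schema validation.

Every CSV written here starts with a ``# kneessm-schema: <name>`` comment
line; readers check it and validate the required columns, reporting the
offending columns or row numbers.  Unknown extra columns are preserved with
a warning.  All writers are deterministic (stable row order, no timestamps).
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .landmarks import N_POINTS, BodyLandmarkSet, LandmarkSet
from .template import segment_map

SCHEMAS = {
    "knee-landmarks": ["id", "point_index", "x", "y"],
    "body-landmarks": ["id", "landmark", "point_index", "x", "y"],
    "covariates": ["id", "sex", "age", "height", "weight", "ethnicity"],
    "areas": ["id", "area_medial_femur", "area_lateral_femur",
              "area_medial_tibia", "area_lateral_tibia"],
    "scores": ["id"],          # + ksm1..ksmN
    "assessments": ["id", "mjsw", "jsn_grade", "grade_medial_femur",
                    "grade_lateral_femur", "grade_medial_tibia",
                    "grade_lateral_tibia", "weighted_osteophyte_score",
                    "rkoa_score", "rkoa_grade"],
    "angles": ["id", "hka", "fta", "qc_flags"],
    "association": ["ksm", "contrast", "model", "stratum", "or", "ci_low",
                    "ci_high", "p", "log_or", "se", "interaction_p",
                    "n_cases", "n_controls", "flag", "significant"],
    "composite": ["contrast", "point_index", "x", "y"],
    "truth": ["id"],
}


class SchemaError(ValueError):
    pass


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    cols = SCHEMAS[schema]
    df = df.reset_index() if df.index.name == "id" else df.copy()
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema}: cannot write, missing columns {missing}")
    ordered = cols + [c for c in df.columns if c not in cols]
    with open(path, "w", newline="") as fh:
        fh.write(f"# kneessm-schema: {schema}-v1\n")
        df[ordered].to_csv(fh, index=False, lineterminator="\n")


def read_table(path, schema: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith(f"# kneessm-schema: {schema}-v1"):
            raise SchemaError(
                f"{path}: expected schema header '{schema}-v1', got {header.strip()!r}")
        df = pd.read_csv(_io.StringIO(fh.read()))
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in SCHEMAS[schema]
             and not (schema in ("scores", "truth") or c.startswith("ksm"))]
    if extra and schema not in ("scores", "truth"):
        warnings.warn(f"{path}: unknown columns preserved: {extra}", stacklevel=2)
    return df


def _check_finite(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if len(bad):
            raise SchemaError(
                f"{path}: malformed value in column {c!r} at data row(s) "
                f"{(bad + 2).tolist()[:5]} (1-based, incl. header)")
        df[c] = vals


# -- knee landmarks ---------------------------------------------------------


def write_knee_landmarks(path, landmark_sets) -> None:
    rows = []
    for lms in landmark_sets:
        for j, (x, y) in enumerate(lms.points):
            rows.append((lms.id, j, x, y))
    df = pd.DataFrame(rows, columns=["id", "point_index", "x", "y"])
    write_table(df, path, "knee-landmarks")


def read_knee_landmarks(path) -> list[LandmarkSet]:
    df = read_table(path, "knee-landmarks")
    _check_finite(df, ["x", "y"], path)
    out = []
    smap = segment_map()
    for ident, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("point_index")
        if list(grp["point_index"]) != list(range(N_POINTS)):
            raise SchemaError(f"{path}: id {ident!r} does not have point indices 0..{N_POINTS - 1}")
        out.append(LandmarkSet(points=grp[["x", "y"]].to_numpy(),
                               segment_map=smap, id=str(ident)))
    return out


# -- body landmarks ---------------------------------------------------------

_BODY_GROUPS = ("femoral_head_ring", "intercondylar_notch",
                "tibial_plateau_centre", "talus_centre", "femoral_shaft_points")


def write_body_landmarks(path, body_sets) -> None:
    rows = []
    for b in body_sets:
        for name in _BODY_GROUPS:
            pts = np.atleast_2d(getattr(b, name))
            for j, (x, y) in enumerate(pts):
                rows.append((b.id, name, j, x, y))
    df = pd.DataFrame(rows, columns=["id", "landmark", "point_index", "x", "y"])
    write_table(df, path, "body-landmarks")


def read_body_landmarks(path) -> list[BodyLandmarkSet]:
    df = read_table(path, "body-landmarks")
    _check_finite(df, ["x", "y"], path)
    out = []
    for ident, grp in df.groupby("id", sort=False):
        kwargs = {"id": str(ident)}
        for name in _BODY_GROUPS:
            sub = grp[grp["landmark"] == name].sort_values("point_index")
            if sub.empty:
                raise SchemaError(f"{path}: id {ident!r} missing landmark group {name!r}")
            pts = sub[["x", "y"]].to_numpy()
            kwargs[name] = pts if name in ("femoral_head_ring", "femoral_shaft_points") else pts[0]
        out.append(BodyLandmarkSet(**kwargs))
    return out


# -- simple keyed tables ----------------------------------------------------


def write_covariates(path, covariates: pd.DataFrame) -> None:
    write_table(covariates, path, "covariates")


def read_covariates(path) -> pd.DataFrame:
    df = read_table(path, "covariates")
    _check_finite(df, ["age", "height", "weight"], path)
    return df.set_index("id")


def write_areas(path, areas: pd.DataFrame) -> None:
    write_table(areas, path, "areas")


def read_areas(path) -> pd.DataFrame:
    df = read_table(path, "areas")
    _check_finite(df, SCHEMAS["areas"][1:], path)
    return df.set_index("id")
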