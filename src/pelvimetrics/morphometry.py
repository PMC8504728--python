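"""Landmark-based pelvimetry of the true pelvis.

An 11-landmark configuration on the pelvic canal is reduced to the three
obstetric planes' linear dimensions (anteroposterior and mediolateral at the
inlet, midplane and outlet), the corresponding shape indices (AP/ML), and two
angular statistics of the "spine triangle" formed by the apex of the fifth
sacral vertebra and the two ischial spines:

* ``theta_a`` — the angle at the S5 apex subtended by the two ischial spines.
  A smaller angle means more medially projecting spines (a narrower midplane
  in a sense the interspinous distance alone does not capture).
* ``theta_b`` — the angle at the *left* ischial spine between the line to the
  S5 apex and the interspinous line.  A larger angle means the sacrum sits
  farther from the spines (more posterior canal space).

Both angles are computed from the three interlandmark distances by the law of
cosines, mirroring how they are constructed from a distance "triangle" rather
than from raw vectors; a vector (dot-product) computation exists only as a
test oracle.  All measures are therefore invariant under rigid motion of the
landmark set, and no anatomical axis convention is assumed — coordinates are
just millimetres in any right-handed frame.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    InconsistentDistancesError,
    InvalidLandmarkError,
    SchemaError,
)

#: Canonical landmark names, in their traditional numbering order (1-11).
LANDMARK_NAMES: tuple[str, ...] = (
    "ischial_spine_L",
    "ischial_spine_R",
    "ischial_tuberosity_L",
    "ischial_tuberosity_R",
    "sacral_promontory",
    "between_S4_S5",
    "apex_S5",
    "dorsal_sup_pubic_symphysis",
    "dorsal_inf_pubic_symphysis",
    "max_iliopectineal_L",
    "max_iliopectineal_R",
)

#: Bilateral pairs that must never coincide.
PAIRED_LANDMARKS: tuple[tuple[str, str], ...] = (
    ("ischial_spine_L", "ischial_spine_R"),
    ("ischial_tuberosity_L", "ischial_tuberosity_R"),
    ("max_iliopectineal_L", "max_iliopectineal_R"),
)

#: Landmark pair defining each linear canal dimension.
DIMENSION_LANDMARKS: dict[str, tuple[str, str]] = {
    "IAP": ("sacral_promontory", "dorsal_sup_pubic_symphysis"),
    "IML": ("max_iliopectineal_L", "max_iliopectineal_R"),
    "MAP": ("between_S4_S5", "dorsal_inf_pubic_symphysis"),
    "MML": ("ischial_spine_L", "ischial_spine_R"),
    "OAP": ("apex_S5", "dorsal_inf_pubic_symphysis"),
    "OML": ("ischial_tuberosity_L", "ischial_tuberosity_R"),
}

# Relative slack on the triangle inequality below which a triangle is treated
# as degenerate (collinear) rather than merely ill-conditioned.
_TRIANGLE_RTOL = 1e-6


@dataclass(frozen=True)
class LandmarkSet:
    """One specimen/observer/replicate's 11 named 3D landmarks (mm)."""

    specimen_id: str
    observer_id: str
    replicate_id: int
    coords: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [n for n in LANDMARK_NAMES if n not in self.coords]
        if missing:
            raise SchemaError(
                f"specimen {self.specimen_id!r}: missing landmark(s) {missing}"
            )
        extra = [n for n in self.coords if n not in LANDMARK_NAMES]
        if extra:
            raise SchemaError(
                f"specimen {self.specimen_id!r}: unknown landmark(s) {extra}"
            )
        clean = {}
        for name in LANDMARK_NAMES:
            v = np.asarray(self.coords[name], dtype=float)
            if v.shape != (3,):
                raise SchemaError(
                    f"specimen {self.specimen_id!r}: landmark {name!r} is not a 3-vector"
                )
            if not np.all(np.isfinite(v)):
                raise InvalidLandmarkError(
                    f"specimen {self.specimen_id!r}: landmark {name!r} has "
                    f"non-finite coordinates {v}"
                )
            clean[name] = v
        for a, b in PAIRED_LANDMARKS:
            if np.allclose(clean[a], clean[b]):
                raise DegenerateGeometryError(
                    f"specimen {self.specimen_id!r}: paired landmarks "
                    f"{a!r} and {b!r} coincide"
                )
        object.__setattr__(self, "coords", clean)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.coords[name]


@dataclass(frozen=True)
class CanalMeasurements:
    """Linear dimensions (mm), shape indices (AP/ML) and angles (deg) of the canal."""

    IAP: float
    IML: float
    MAP: float
    MML: float
    OAP: float
    OML: float
    inlet_shape: float
    midplane_shape: float
    outlet_shape: float
    theta_a: float
    theta_b: float

    LINEAR_FIELDS = ("IAP", "IML", "MAP", "MML", "OAP", "OML")
    SHAPE_FIELDS = ("inlet_shape", "midplane_shape", "outlet_shape")
    ANGLE_FIELDS = ("theta_a", "theta_b")

    def __post_init__(self) -> None:
        for f in self.LINEAR_FIELDS + self.SHAPE_FIELDS:
            v = getattr(self, f)
            if not (np.isfinite(v) and v > 0):
                raise SchemaError(f"canal measurement {f} must be positive, got {v}")
        for f in self.ANGLE_FIELDS:
            v = getattr(self, f)
            if not (0.0 < v < 180.0):
                raise DegenerateGeometryError(
                    f"angle {f} = {v} deg is outside the open interval (0, 180)"
                )

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in FIELD_ORDER}


FIELD_ORDER: tuple[str, ...] = (
    "IAP",
    "IML",
    "inlet_shape",
    "MAP",
    "MML",
    "midplane_shape",
    "OAP",
    "OML",
    "outlet_shape",
    "theta_a",
    "theta_b",
)


def interlandmark_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance (mm) between two landmark coordinates."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidLandmarkError(f"non-finite landmark coordinates: {a}, {b}")
    return float(np.linalg.norm(a - b))


def shape_index(ap: float, ml: float) -> float:
    """Plane shape index: anteroposterior over mediolateral dimension."""
    if ml <= 0 or ap <= 0 or not (np.isfinite(ap) and np.isfinite(ml)):
        raise DegenerateGeometryError(
            f"shape index needs positive finite dimensions, got ap={ap}, ml={ml}"
        )
    return ap / ml


def _angle_from_sides(adj1: float, adj2: float, opposite: float) -> float:
    """Law-of-cosines angle (deg) between the two adjacent sides.

    ``adj1`` and ``adj2`` meet at the vertex whose angle is returned;
    ``opposite`` is the side facing that vertex.
    """
    if adj1 <= 0 or adj2 <= 0 or opposite <= 0:
        raise DegenerateGeometryError(
            f"coincident triangle vertices (sides {adj1}, {adj2}, {opposite})"
        )
    scale = max(adj1, adj2, opposite)
    slack = _TRIANGLE_RTOL * scale
    deficit = (adj1 + adj2) - opposite
    # The other two triangle inequalities cannot fail when `opposite` is not
    # the largest side; check them all for a clean error message anyway.
    deficits = (deficit, (adj1 + opposite) - adj2, (adj2 + opposite) - adj1)
    worst = min(deficits)
    if worst < -slack:
        raise InconsistentDistancesError(
            f"distances ({adj1}, {adj2}, {opposite}) violate the triangle "
            f"inequality by {-worst:.6g} mm"
        )
    if worst <= slack:
        raise DegenerateGeometryError(
            f"collinear triangle: distances ({adj1}, {adj2}, {opposite}) are "
            "degenerate within tolerance"
        )
    cosang = (adj1**2 + adj2**2 - opposite**2) / (2.0 * adj1 * adj2)
    cosang = min(1.0, max(-1.0, cosang))
    return math.degrees(math.acos(cosang))


def _spine_triangle(lm: LandmarkSet) -> tuple[float, float, float]:
    """The three ILDs of the S5-apex / ischial-spine triangle: (L-S5, R-S5, L-R)."""
    d_ls5 = interlandmark_distance(lm["ischial_spine_L"], lm["apex_S5"])
    d_rs5 = interlandmark_distance(lm["ischial_spine_R"], lm["apex_S5"])
    d_lr = interlandmark_distance(lm["ischial_spine_L"], lm["ischial_spine_R"])
    return d_ls5, d_rs5, d_lr


def ischial_spine_angle(lm: LandmarkSet) -> float:
    """Medial projection of the ischial spines (theta_a, degrees).

    Angle at the S5 apex between the lines to the left and right ischial
    spines, from the three interlandmark distances by the law of cosines.
    """
    d_ls5, d_rs5, d_lr = _spine_triangle(lm)
    return _angle_from_sides(d_ls5, d_rs5, d_lr)


def s5_position_angle(lm: LandmarkSet) -> float:
    """Sacral apex position (theta_b, degrees).

    Angle at the left ischial spine between the line to the S5 apex and the
    interspinous line.  The left spine is the vertex by definition, so
    left/right asymmetry of a specimen is visible in this statistic.
    """
    d_ls5, d_rs5, d_lr = _spine_triangle(lm)
    return _angle_from_sides(d_ls5, d_lr, d_rs5)


def compute_canal_dimensions(lm: LandmarkSet) -> CanalMeasurements:
    """All canal measurements for one landmark configuration."""
    dims = {
        name: interlandmark_distance(lm[a], lm[b])
        for name, (a, b) in DIMENSION_LANDMARKS.items()
    }
    return CanalMeasurements(
        **dims,
        inlet_shape=shape_index(dims["IAP"], dims["IML"]),
        midplane_shape=shape_index(dims["MAP"], dims["MML"]),
        outlet_shape=shape_index(dims["OAP"], dims["OML"]),
        theta_a=ischial_spine_angle(lm),
        theta_b=s5_position_angle(lm),
    )


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------

_LANDMARK_COLUMNS = [
    "specimen_id",
    "observer_id",
    "replicate_id",
    "landmark",
    "x_mm",
    "y_mm",
    "z_mm",
]


def _landmark_sets_from_frame(df: pd.DataFrame) -> list[LandmarkSet]:
    missing_cols = [c for c in _LANDMARK_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"landmark table missing column(s) {missing_cols}")
    sets: list[LandmarkSet] = []
    for (spec, obs, rep), grp in df.groupby(
        ["specimen_id", "observer_id", "replicate_id"], sort=True
    ):
        if grp["landmark"].duplicated().any():
            dupes = sorted(grp.loc[grp["landmark"].duplicated(), "landmark"])
            raise SchemaError(
                f"specimen {spec!r} observer {obs!r} replicate {rep}: "
                f"duplicated landmark rows {dupes}"
            )
        coords = {
            row.landmark: np.array([row.x_mm, row.y_mm, row.z_mm], dtype=float)
            for row in grp.itertuples()
        }
        sets.append(
            LandmarkSet(
                specimen_id=str(spec),
                observer_id=str(obs),
                replicate_id=int(rep),
                coords=coords,
            )
        )
    return sets


def read_landmarks_csv(path) -> list[LandmarkSet]:
    """Read a long-format landmark CSV (one row per landmark)."""
    return _landmark_sets_from_frame(pd.read_csv(path))


def read_landmarks_json(path) -> list[LandmarkSet]:
    """Read landmarks from a JSON list of row records with the CSV schema."""
    with open(path) as fh:
        records = json.load(fh)
    return _landmark_sets_from_frame(pd.DataFrame.from_records(records))


def landmarks_to_frame(sets: Iterable[LandmarkSet]) -> pd.DataFrame:
    rows = []
    for lm in sets:
        for name in LANDMARK_NAMES:
            x, y, z = lm[name]
            rows.append(
                dict(
                    specimen_id=lm.specimen_id,
                    observer_id=lm.observer_id,
                    replicate_id=lm.replicate_id,
                    landmark=name,
                    x_mm=x,
                    y_mm=y,
                    z_mm=z,
                )
            )
    return pd.DataFrame(rows, columns=_LANDMARK_COLUMNS)


def write_landmarks_csv(sets: Iterable[LandmarkSet], path) -> None:
    landmarks_to_frame(sets).to_csv(path, index=False)


def measure_all(sets: Iterable[LandmarkSet]) -> pd.DataFrame:
    """Canal measurements for many landmark sets, one row per set."""
    rows = []
    for lm in sets:
        meas = compute_canal_dimensions(lm)
        row = dict(
            specimen_id=lm.specimen_id,
            observer_id=lm.observer_id,
            replicate_id=lm.replicate_id,
        )
        row.update(meas.as_dict())
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["specimen_id", "observer_id", "replicate_id", *FIELD_ORDER]
    )
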