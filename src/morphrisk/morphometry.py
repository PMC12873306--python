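"""Rigid pose normalization and extraction of 47 facial anthropometric features.

Canonical frame (after :func:`normalize_pose`): origin at pronasale (nasal
tip), +x toward the subject's anatomical left (inter-endocanthion axis),
+y toward the scalp (trichion-gnathion axis orthogonalized against x),
+z = x cross y, toward the observer.  Normalization is rigid: a proper
rotation plus translation, so every inter-landmark distance is preserved.

The feature roster comprises 32 distance-class measurements (point-to-point
distances, axis-aligned bounding extents of landmark subsets, perpendicular
depths to a chord, frontal-plane projected distances and a depth offset),
12 axis angles ("slopes" of facial segments against the coordinate axes,
folded to [0, pi/2] and stored in radians), 2 eyelid-contour areas (shoelace
formula in the frontal plane), and 1 midpoint projection (forehead height).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from morphrisk.landmark_io import LandmarkSet, Laterality, mirror_label

__all__ = [
    "RigidTransform",
    "NormalizationError",
    "convert_laterality",
    "normalize_pose",
    "euclidean_distance",
    "axis_extent",
    "perpendicular_depth",
    "projected_distance",
    "axis_angle",
    "polygon_area",
    "FeatureDefinition",
    "default_feature_definitions",
    "extract_features",
    "FEATURE_NAMES",
    "ANGLE_FEATURES",
    "AREA_FEATURES",
    "CALIBRATION_FEATURES",
]

_AXES = {"x": 0, "y": 1, "z": 2}


class NormalizationError(ValueError):
    """Degenerate landmark geometry prevents pose normalization."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> R @ p + t (rotation in SO(3), translation in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation is improper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self . other)(p) = self(other(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def convert_laterality(lm: LandmarkSet) -> LandmarkSet:
    """Convert photographer-view laterality to anatomical orientation.

    Mirrors the face about the midsagittal plane (negating x) and swaps each
    ``_L``/``_R`` label pair, so that labels name the subject's own left and
    right.  Applying the conversion twice restores the original set.
    """
    flip = np.diag([-1.0, 1.0, 1.0])
    pts = {mirror_label(lab): flip @ xyz for lab, xyz in lm.points.items()}
    new_lat = (
        Laterality.ANATOMICAL
        if lm.laterality == Laterality.PHOTOGRAPHER
        else Laterality.PHOTOGRAPHER
    )
    return lm.with_points(pts, laterality=new_lat)


def normalize_pose(lm: LandmarkSet) -> Tuple[LandmarkSet, RigidTransform]:
    """Rigidly move a face into the canonical frame centered at the nasal tip.

    Returns the normalized landmark set and the transform that was applied
    (so ``transform.apply(original) == normalized``).

    Raises
    ------
    NormalizationError
        If the inter-endocanthion axis is (near-)parallel to the
        trichion-gnathion axis, leaving the frame underdetermined.
    """
    prn = lm["pronasale"]
    ex_axis = lm["endocanthion_L"] - lm["endocanthion_R"]
    nx = np.linalg.norm(ex_axis)
    if nx < 1e-9:
        raise NormalizationError(f"subject {lm.subject_id!r}: coincident endocanthions")
    xhat = ex_axis / nx
    vert = lm["trichion"] - lm["gnathion"]
    vert = vert - (vert @ xhat) * xhat
    ny = np.linalg.norm(vert)
    if ny < 1e-9:
        raise NormalizationError(
            f"subject {lm.subject_id!r}: vertical axis parallel to eye axis"
        )
    yhat = vert / ny
    zhat = np.cross(xhat, yhat)
    R = np.stack([xhat, yhat, zhat])  # rows: new basis -> R maps world to face frame
    transform = RigidTransform(R, -R @ prn)
    pts = {lab: transform.apply(xyz) for lab, xyz in lm.points.items()}
    return lm.with_points(pts, normalized=True), transform


# --------------------------------------------------------------------------
# Geometric primitives
# --------------------------------------------------------------------------


def euclidean_distance(a, b) -> float:
    """Straight-line distance between two 3D points, in mm."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def axis_extent(labels: Sequence[str], axis: str, lm: LandmarkSet) -> float:
    """Bounding extent (max - min) of a landmark subset along a frame axis."""
    if not labels:
        raise ValueError("axis_extent requires a nonempty landmark subset")
    vals = lm.coords(labels)[:, _AXES[axis]]
    return float(vals.max() - vals.min())


def perpendicular_depth(p, a, b) -> float:
    """Distance from point ``p`` to the infinite line through ``a`` and ``b``."""
    a = np.asarray(a, float)
    u = np.asarray(b, float) - a
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise ValueError("chord endpoints coincide")
    w = np.asarray(p, float) - a
    return float(np.linalg.norm(w - (w @ u / nu**2) * u))


def projected_distance(a, b, plane: str = "frontal_xy") -> float:
    """Distance between two points after projection onto the frontal (xy) plane."""
    if plane != "frontal_xy":
        raise ValueError(f"unknown plane {plane!r}")
    d = np.asarray(a, float)[:2] - np.asarray(b, float)[:2]
    return float(np.linalg.norm(d))


def axis_angle(v, axis: str) -> float:
    """Acute angle between a direction vector and a coordinate axis, radians.

    Defined as arccos(|v . e| / ||v||), folded to [0, pi/2]; the three angles
    of any vector satisfy cos^2(tx) + cos^2(ty) + cos^2(tz) = 1.
    """
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("axis_angle of zero vector is undefined")
    c = abs(v[_AXES[axis]]) / n
    return float(np.arccos(min(c, 1.0)))


def polygon_area(labels: Sequence[str], lm: LandmarkSet) -> float:
    """Shoelace area of an ordered contour projected onto the frontal plane, mm^2."""
    if len(labels) < 3:
        raise ValueError("polygon_area requires at least 3 contour points")
    xy = lm.coords(labels)[:, :2]
    x, y = xy[:, 0], xy[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if _self_intersects(xy):
        warnings.warn("self-intersecting contour; returning absolute shoelace area")
    return float(abs(signed))


def _self_intersects(xy: np.ndarray) -> bool:
    n = len(xy)
    segs = [(xy[i], xy[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through wrap-around
            if _segments_cross(*segs[i], *segs[j]):
                return True
    return False


def _segments_cross(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        u, v = b - a, c - a
        return np.sign(u[0] * v[1] - u[1] * v[0])

    return (
        orient(p1, p2, p3) * orient(p1, p2, p4) < 0
        and orient(p3, p4, p1) * orient(p3, p4, p2) < 0
    )


# --------------------------------------------------------------------------
# Feature definitions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureDefinition:
    """One named morphometric feature.

    kind : {"distance", "extent", "perpendicular", "projected_distance",
            "axis_offset", "axis_angle", "polygon_area", "midpoint_projection"}
    operands : landmark labels consumed by the construction
    axis : coordinate axis for extent/axis_angle/axis_offset/midpoint_projection
    """

    name: str
    kind: str
    operands: Tuple[str, ...]
    axis: Optional[str] = None


_EYE_SUBSET_L = (
    "endocanthion_L",
    "exocanthion_L",
    "upper_eyelid1_L",
    "upper_eyelid2_L",
    "lower_eyelid1_L",
    "lower_eyelid2_L",
)
_EYE_SUBSET_R = tuple(mirror_label(lab) for lab in _EYE_SUBSET_L)
_NOSE_SUBSET = ("glabella", "nasion", "pronasale", "subnasale", "alare_L", "alare_R")
_MOUTH_SUBSET = (
    "cheilion_L",
    "cheilion_R",
    "labiale_superius",
    "labiale_inferius",
    "stomion",
)
# ordered eyelid contour for the shoelace area (counter-clockwise, left eye)
_EYE_CONTOUR_L = (
    "endocanthion_L",
    "upper_eyelid1_L",
    "upper_eyelid2_L",
    "exocanthion_L",
    "lower_eyelid2_L",
    "lower_eyelid1_L",
)
_EYE_CONTOUR_R = tuple(mirror_label(lab) for lab in _EYE_CONTOUR_L)


def default_feature_definitions() -> Tuple[FeatureDefinition, ...]:
    """The canonical 47-feature roster.

    "center eye" is a documented alias for the left eye.  Angle features are
    stored in radians.
    """
    D = FeatureDefinition
    defs = (
        # --- distances (mm) -------------------------------------------------
        D("Forehead width", "distance", ("frontotemporale_L", "frontotemporale_R")),
        D("Face width", "distance", ("zygion_L", "zygion_R")),
        D("Face length", "distance", ("trichion", "gnathion")),
        D("Jaw width", "distance", ("gonion_L", "gonion_R")),
        D("Nose width", "distance", ("alare_L", "alare_R")),
        D("Nose height", "distance", ("pronasale", "subnasale")),
        D("Nose depth", "axis_offset", ("pronasale", "alare_L", "alare_R"), axis="z"),
        D("Nose length", "distance", ("nasion", "pronasale")),
        D("Part nose x", "extent", _NOSE_SUBSET, axis="x"),
        D("Part nose y", "extent", _NOSE_SUBSET, axis="y"),
        D(
            "Philtrum depth",
            "perpendicular",
            ("philtrum_midpoint", "subnasale", "labiale_superius"),
        ),
        D("Philtrum length", "distance", ("subnasale", "labiale_superius")),
        D(
            "Philtrum length flat",
            "projected_distance",
            ("subnasale", "labiale_superius"),
        ),
        D("Mouth width", "distance", ("cheilion_L", "cheilion_R")),
        D("Part mouth x", "extent", _MOUTH_SUBSET, axis="x"),
        D("Dist nose lip", "distance", ("subnasale", "stomion")),
        D("Upper lip thick", "distance", ("labiale_superius", "stomion")),
        D("Lower lip thick", "distance", ("stomion", "labiale_inferius")),
        D(
            "Chin depth",
            "perpendicular",
            ("pogonion", "labiale_inferius", "gnathion"),
        ),
        D("Chin length", "distance", ("labiale_inferius", "gnathion")),
        D("center eye width", "distance", ("endocanthion_L", "exocanthion_L")),
        D("Right eye width", "distance", ("endocanthion_R", "exocanthion_R")),
        D("Dist inner eyes", "distance", ("endocanthion_L", "endocanthion_R")),
        D("Dist outer eyes", "distance", ("exocanthion_L", "exocanthion_R")),
        D("Dist Leye nose", "distance", ("endocanthion_L", "nasion")),
        D("Dist Reye nose", "distance", ("endocanthion_R", "nasion")),
        D("Part Leye x", "extent", _EYE_SUBSET_L, axis="x"),
        D("Part Leye y", "extent", _EYE_SUBSET_L, axis="y"),
        D("Part Reye x", "extent", _EYE_SUBSET_R, axis="x"),
        D("Part Reye y", "extent", _EYE_SUBSET_R, axis="y"),
        D(
            "Part Leyepit y",
            "extent",
            _EYE_SUBSET_L + ("orbital_superius_L",),
            axis="y",
        ),
        D(
            "Part Reyepit y",
            "extent",
            _EYE_SUBSET_R + ("orbital_superius_R",),
            axis="y",
        ),
        # --- axis angles (radians) -----------------------------------------
        D("Philtrum slope x", "axis_angle", ("subnasale", "labiale_superius"), axis="x"),
        D("Philtrum slope y", "axis_angle", ("subnasale", "labiale_superius"), axis="y"),
        D("Philtrum slope z", "axis_angle", ("subnasale", "labiale_superius"), axis="z"),
        D("Chin slope x", "axis_angle", ("labiale_inferius", "gnathion"), axis="x"),
        D("Chin slope y", "axis_angle", ("labiale_inferius", "gnathion"), axis="y"),
        D("Chin slope z", "axis_angle", ("labiale_inferius", "gnathion"), axis="z"),
        D(
            "center eye slope x",
            "axis_angle",
            ("endocanthion_L", "exocanthion_L"),
            axis="x",
        ),
        D(
            "center eye slope y",
            "axis_angle",
            ("endocanthion_L", "exocanthion_L"),
            axis="y",
        ),
        D(
            "center eye slope z",
            "axis_angle",
            ("endocanthion_L", "exocanthion_L"),
            axis="z",
        ),
        D(
            "Right eye slope x",
            "axis_angle",
            ("endocanthion_R", "exocanthion_R"),
            axis="x",
        ),
        D(
            "Right eye slope y",
            "axis_angle",
            ("endocanthion_R", "exocanthion_R"),
            axis="y",
        ),
        D(
            "Right eye slope z",
            "axis_angle",
            ("endocanthion_R", "exocanthion_R"),
            axis="z",
        ),
        # --- areas (mm^2) ---------------------------------------------------
        D("center eye area", "polygon_area", _EYE_CONTOUR_L),
        D("Right eye area", "polygon_area", _EYE_CONTOUR_R),
        # --- midpoint projection (mm) ----------------------------------------
        D(
            "Forehead height",
            "midpoint_projection",
            ("frontotemporale_L", "frontotemporale_R", "gnathion"),
            axis="y",
        ),
    )
    assert len(defs) == 47
    return defs


_DEFAULT_DEFS = default_feature_definitions()

#: Names of the 47 default features, in roster order.
FEATURE_NAMES = tuple(d.name for d in _DEFAULT_DEFS)

ANGLE_FEATURES = tuple(d.name for d in _DEFAULT_DEFS if d.kind == "axis_angle")
AREA_FEATURES = tuple(d.name for d in _DEFAULT_DEFS if d.kind == "polygon_area")

#: Features whose template values are calibrated against published normative means.
CALIBRATION_FEATURES = (
    "Face width",
    "Jaw width",
    "Nose width",
    "Philtrum length",
    "Philtrum depth",
    "Mouth width",
    "Dist inner eyes",
    "Dist outer eyes",
    "center eye width",
    "Dist nose lip",
)


def _evaluate(defn: FeatureDefinition, lm: LandmarkSet) -> float:
    ops = defn.operands
    if defn.kind == "distance":
        return euclidean_distance(lm[ops[0]], lm[ops[1]])
    if defn.kind == "extent":
        return axis_extent(ops, defn.axis, lm)
    if defn.kind == "perpendicular":
        return perpendicular_depth(lm[ops[0]], lm[ops[1]], lm[ops[2]])
    if defn.kind == "projected_distance":
        return projected_distance(lm[ops[0]], lm[ops[1]])
    if defn.kind == "axis_offset":
        # depth of the first landmark above the midpoint of the remaining two
        mid = 0.5 * (lm[ops[1]] + lm[ops[2]])
        return float(abs(lm[ops[0]][_AXES[defn.axis]] - mid[_AXES[defn.axis]]))
    if defn.kind == "axis_angle":
        return axis_angle(lm[ops[1]] - lm[ops[0]], defn.axis)
    if defn.kind == "polygon_area":
        return polygon_area(ops, lm)
    if defn.kind == "midpoint_projection":
        mid = 0.5 * (lm[ops[0]] + lm[ops[1]])
        return float(abs(mid[_AXES[defn.axis]] - lm[ops[2]][_AXES[defn.axis]]))
    raise ValueError(f"unknown feature kind {defn.kind!r}")


def extract_features(
    lm: LandmarkSet,
    defs: Optional[Sequence[FeatureDefinition]] = None,
) -> Dict[str, float]:
    """Compute the named morphometric features of one subject.

    The landmark set must use anatomical laterality; if it is not yet pose
    normalized, normalization is applied internally (features are therefore
    invariant to any rigid motion of the input).
    """
    if lm.laterality != Laterality.ANATOMICAL:
        raise ValueError(
            f"subject {lm.subject_id!r}: convert photographer laterality to "
            "anatomical before feature extraction"
        )
    if not lm.normalized:
        lm, _ = normalize_pose(lm)
    defs = _DEFAULT_DEFS if defs is None else tuple(defs)
    return {d.name: _evaluate(d, lm) for d in defs}
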