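"""Geometry of pose normalization and the 47-feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphrisk.landmark_io import Laterality, mirror_label
from morphrisk.morphometry import (
    ANGLE_FEATURES,
    CALIBRATION_FEATURES,
    FEATURE_NAMES,
    RigidTransform,
    axis_angle,
    axis_extent,
    convert_laterality,
    default_feature_definitions,
    euclidean_distance,
    extract_features,
    normalize_pose,
    perpendicular_depth,
    polygon_area,
    projected_distance,
)
from morphrisk.synthetic_cohort import GeneratorConfig, sample_cohort

# Normative means the template is calibrated against (5% tolerance).
CALIBRATION_TARGETS = {
    "Face width": 155.00,
    "Jaw width": 139.56,
    "Nose width": 28.76,
    "Philtrum length": 16.14,
    "Philtrum depth": 3.83,
    "Mouth width": 49.38,
    "Dist inner eyes": 39.88,
    "Dist outer eyes": 90.30,
    "center eye width": 25.93,
    "Dist nose lip": 22.69,
}


def random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return RigidTransform(R, rng.uniform(-30, 30, 3))


# --------------------------------------------------------------------------
# Primitives
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [((0, 0, 0), (3, 4, 0), 5.0), ((1, 2, 3), (1, 2, 3), 0.0)],
)
def test_euclidean_distance_examples(a, b, expected):
    assert euclidean_distance(a, b) == pytest.approx(expected)


def test_distance_rigid_invariance(rng):
    a, b = rng.normal(size=(2, 3)) * 20
    d0 = euclidean_distance(a, b)
    for _ in range(20):
        T = random_rigid(rng)
        assert euclidean_distance(T.apply(a), T.apply(b)) == pytest.approx(d0)


def test_perpendicular_depth_examples():
    assert perpendicular_depth((0, 0, 1), (0, -8, 0), (0, 8, 0)) == pytest.approx(1.0)
    assert perpendicular_depth((0, 3, 0), (0, -8, 0), (0, 8, 0)) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        perpendicular_depth((1, 1, 1), (0, 0, 0), (0, 0, 0))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_perpendicular_depth_matches_vector_algebra(seed):
    rng = np.random.default_rng(seed)
    p, a, b = rng.normal(size=(3, 3)) * 10
    if np.linalg.norm(b - a) < 1e-6:
        return
    u = (b - a) / np.linalg.norm(b - a)
    w = p - a
    oracle = np.linalg.norm(w - (w @ u) * u)
    assert perpendicular_depth(p, a, b) == pytest.approx(oracle, abs=1e-9)


def test_projected_distance_examples():
    assert projected_distance((0, 0, 0), (0, 16, 0)) == pytest.approx(16.0)
    assert projected_distance((0, 0, 0), (0, 15, 5)) == pytest.approx(15.0)
    assert projected_distance((0, 0, 0), (0, 15, 5)) < euclidean_distance(
        (0, 0, 0), (0, 15, 5)
    )


def test_axis_angle_examples_and_closure(rng):
    assert axis_angle((1, 0, 0), "x") == pytest.approx(0.0)
    assert axis_angle((1, 0, 0), "y") == pytest.approx(np.pi / 2)
    v = (0.0, 15.9, 2.6)  # near-vertical philtrum-like segment
    assert axis_angle(v, "x") == pytest.approx(1.571, abs=1e-3)
    assert axis_angle(v, "y") == pytest.approx(0.162, abs=1e-3)
    assert axis_angle(v, "z") == pytest.approx(1.409, abs=1e-3)
    for _ in range(20):
        w = rng.normal(size=3)
        total = sum(np.cos(axis_angle(w, ax)) ** 2 for ax in "xyz")
        assert total == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        axis_angle((0, 0, 0), "x")


def test_axis_extent(template):
    # nasal x-extent coincides with the alare span when alares are extremes
    ext = axis_extent(("alare_L", "alare_R"), "x", template)
    assert ext == pytest.approx(
        abs(template["alare_L"][0] - template["alare_R"][0])
    )
    assert axis_extent(("pronasale",), "x", template) == 0.0
    with pytest.raises(ValueError):
        axis_extent((), "x", template)


def test_polygon_area_square_and_degenerate(template):
    pts = dict(template.points)
    square = ["contour01_L", "contour02_L", "contour03_L", "contour04_L"]
    for lab, xy in zip(square, [(0, 0), (1, 0), (1, 1), (0, 1)]):
        pts[lab] = np.array([xy[0], xy[1], 0.0])
    lm = template.with_points(pts)
    assert polygon_area(square, lm) == pytest.approx(1.0)
    for i, lab in enumerate(square[:3]):
        pts[lab] = np.array([float(i), 0.0, 0.0])
    lm = template.with_points(pts)
    assert polygon_area(square[:3], lm) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        polygon_area(square[:2], lm)


def test_eye_area_within_geometric_bounds(template):
    # hexagonal contour with width w and opening h: between the two-triangle
    # area (w*h/2) and the ellipse bound (pi*w*h/4)
    feats = extract_features(template)
    w = feats["center eye width"]
    h = feats["Part Leye y"]
    assert w * h / 2 <= feats["center eye area"] <= np.pi * w * h / 4


# --------------------------------------------------------------------------
# Laterality
# --------------------------------------------------------------------------


def test_convert_laterality_mirrors_and_swaps(template):
    photo = template.with_points(template.points, laterality=Laterality.PHOTOGRAPHER)
    anat = convert_laterality(photo)
    assert anat.laterality == Laterality.ANATOMICAL
    en_l = photo["endocanthion_L"]
    np.testing.assert_allclose(
        anat["endocanthion_R"], en_l * np.array([-1, 1, 1]), atol=1e-12
    )
    # involution
    back = convert_laterality(anat)
    for lab in photo.points:
        np.testing.assert_allclose(back[lab], photo[lab], atol=1e-12)
    # midline landmarks at x=0 are fixed points
    np.testing.assert_allclose(anat["pronasale"], photo["pronasale"], atol=1e-12)


# --------------------------------------------------------------------------
# Pose normalization
# --------------------------------------------------------------------------


def test_normalize_template_is_fixed_point(template):
    normalized, transform = normalize_pose(template)
    np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(transform.translation, 0, atol=1e-9)
    np.testing.assert_allclose(normalized.coords(), template.coords(), atol=1e-9)


def test_normalize_recovers_random_rigid_motion(template, rng):
    for _ in range(10):
        T = random_rigid(rng)
        moved = template.with_points(
            {lab: T.apply(xyz) for lab, xyz in template.points.items()},
            normalized=False,
        )
        normalized, rec = normalize_pose(moved)
        np.testing.assert_allclose(normalized.coords(), template.coords(), atol=1e-9)
        # recovered transform inverts the applied one
        roundtrip = rec.compose(T)
        np.testing.assert_allclose(roundtrip.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(roundtrip.translation, 0, atol=1e-9)


def test_normalization_preserves_distances(template, rng):
    T = random_rigid(rng)
    moved = template.with_points(
        {lab: T.apply(xyz) for lab, xyz in template.points.items()}, normalized=False
    )
    normalized, _ = normalize_pose(moved)
    before = euclidean_distance(moved["zygion_L"], moved["zygion_R"])
    after = euclidean_distance(normalized["zygion_L"], normalized["zygion_R"])
    assert after == pytest.approx(before, abs=1e-9)


# --------------------------------------------------------------------------
# Feature extraction
# --------------------------------------------------------------------------


def test_feature_roster_shape():
    defs = default_feature_definitions()
    assert len(defs) == 47
    kinds = [d.kind for d in defs]
    distance_class = {
        "distance",
        "extent",
        "perpendicular",
        "projected_distance",
        "axis_offset",
    }
    assert sum(k in distance_class for k in kinds) == 32
    assert kinds.count("axis_angle") == 12
    assert kinds.count("polygon_area") == 2
    assert kinds.count("midpoint_projection") == 1


def test_template_calibration(template):
    feats = extract_features(template)
    for name, target in CALIBRATION_TARGETS.items():
        assert feats[name] == pytest.approx(target, rel=0.05), name
    assert set(CALIBRATION_TARGETS) == set(CALIBRATION_FEATURES)


def test_features_rigid_invariant(template, rng):
    base = extract_features(template)
    for _ in range(5):
        T = random_rigid(rng)
        moved = template.with_points(
            {lab: T.apply(xyz) for lab, xyz in template.points.items()},
            normalized=False,
        )
        feats = extract_features(moved)
        for name in FEATURE_NAMES:
            assert feats[name] == pytest.approx(base[name], rel=1e-6), name


def test_mirror_covariance(template, rng):
    """Reflecting across the midline swaps L/R feature pairs, fixes midline ones."""
    # perturb asymmetrically so the swap is non-trivial
    pts = {
        lab: xyz + rng.normal(0, 0.5, 3) for lab, xyz in template.points.items()
    }
    face = template.with_points(pts, normalized=False)
    flip = np.diag([-1.0, 1.0, 1.0])
    mirrored = face.with_points(
        {mirror_label(lab): flip @ xyz for lab, xyz in face.points.items()}
    )
    base = extract_features(face)
    mirr = extract_features(mirrored)
    swaps = {
        "center eye width": "Right eye width",
        "center eye area": "Right eye area",
        "Dist Leye nose": "Dist Reye nose",
        "Part Leye x": "Part Reye x",
        "Part Leye y": "Part Reye y",
        "Part Leyepit y": "Part Reyepit y",
    }
    for left, right in swaps.items():
        assert mirr[left] == pytest.approx(base[right], abs=1e-9)
        assert mirr[right] == pytest.approx(base[left], abs=1e-9)
    for midline in ("Face width", "Mouth width", "Dist outer eyes", "Philtrum length"):
        assert mirr[midline] == pytest.approx(base[midline], abs=1e-9)


def test_angle_closure_over_cohort():
    faces, _, _ = sample_cohort(GeneratorConfig(n_subjects=10, seed=7))
    from morphrisk.study_pipeline import build_feature_table

    table = build_feature_table(faces)
    for stem in ("Philtrum slope", "Chin slope", "center eye slope", "Right eye slope"):
        total = sum(np.cos(table[f"{stem} {ax}"]) ** 2 for ax in "xyz")
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
    assert set(ANGLE_FEATURES) == {
        f"{stem} {ax}"
        for stem in ("Philtrum slope", "Chin slope", "center eye slope", "Right eye slope")
        for ax in "xyz"
    }


def test_flat_length_never_exceeds_full_length():
    faces, _, _ = sample_cohort(GeneratorConfig(n_subjects=30, seed=11))
    from morphrisk.study_pipeline import build_feature_table

    table = build_feature_table(faces)
    assert (
        table["Philtrum length flat"] <= table["Philtrum length"] + 1e-12
    ).all()


def test_philtrum_depth_unit_displacement():
    """A +1 mm z-displacement of the philtrum midpoint raises the depth by 1 mm
    when the chord lies in the x=0 plane at constant z."""
    from morphrisk.synthetic_cohort import _raw_template_points
    from morphrisk.landmark_io import LandmarkSet

    pts = _raw_template_points()
    pts["subnasale"] = np.array([0.0, -14.0, -5.0])
    pts["labiale_superius"] = np.array([0.0, -30.0, -5.0])  # constant-z chord
    pts["philtrum_midpoint"] = np.array([0.0, -22.0, -5.0])
    lm = LandmarkSet("constructed", pts, laterality=Laterality.ANATOMICAL)
    d0 = perpendicular_depth(lm["philtrum_midpoint"], lm["subnasale"], lm["labiale_superius"])
    pts["philtrum_midpoint"] = pts["philtrum_midpoint"] + np.array([0.0, 0.0, 1.0])
    lm2 = LandmarkSet("constructed2", pts, laterality=Laterality.ANATOMICAL)
    d1 = perpendicular_depth(lm2["philtrum_midpoint"], lm2["subnasale"], lm2["labiale_superius"])
    assert d1 - d0 == pytest.approx(1.0, abs=1e-12)


def test_extract_requires_anatomical_laterality(template):
    photo = template.with_points(template.points, laterality=Laterality.PHOTOGRAPHER)
    with pytest.raises(ValueError, match="laterality"):
        extract_features(photo)
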