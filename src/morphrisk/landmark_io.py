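"""Data model and file I/O for 3D facial landmark sets and cohort tables.

Each subject carries 72 labeled landmarks.  The anatomically named subset
(canthi, alae, lip points, jaw and brow points, ...) drives every morphometric
feature; the remaining labels are facial-contour filler points kept for
completeness of the point cloud.  Landmark indices on the original scans are
treated as opaque: this module names points by anatomy, and features reference
only those names.

Files are plain CSV (UTF-8, '.' decimal, mandatory header).  Long landmark
layout: ``subject_id, landmark, x_mm, y_mm, z_mm`` (+ optional ``laterality``);
wide layout: one row per subject with ``<label>_x`` / ``_y`` / ``_z`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Laterality",
    "LandmarkSet",
    "CohortTable",
    "LandmarkParseError",
    "CohortValidationError",
    "LANDMARK_LABELS",
    "MIDLINE_LABELS",
    "PAIRED_LABELS",
    "mirror_label",
    "read_landmarks",
    "write_landmarks",
    "read_cohort",
    "write_cohort",
    "SCALE_RANGES",
]


class Laterality(str, Enum):
    """Whether left/right labels follow the photographer's view or anatomy."""

    PHOTOGRAPHER = "photographer"
    ANATOMICAL = "anatomical"


# --------------------------------------------------------------------------
# Landmark dictionary
# --------------------------------------------------------------------------

#: Midline anatomical landmarks (x = 0 on a perfectly symmetric face).
MIDLINE_NAMED = (
    "trichion",
    "glabella",
    "nasion",
    "pronasale",
    "subnasale",
    "labiale_superius",
    "philtrum_midpoint",
    "stomion",
    "labiale_inferius",
    "sublabiale",
    "pogonion",
    "gnathion",
)

#: Bilateral anatomical landmarks; stored label is ``<stem>_L`` / ``<stem>_R``.
PAIRED_STEMS = (
    "frontotemporale",
    "zygion",
    "gonion",
    "alare",
    "endocanthion",
    "exocanthion",
    "upper_eyelid1",
    "upper_eyelid2",
    "lower_eyelid1",
    "lower_eyelid2",
    "orbital_superius",
    "cheilion",
)

#: Facial-contour filler stems (17 bilateral pairs + 2 midline points).
CONTOUR_STEMS = tuple(f"contour{i:02d}" for i in range(1, 18))
CONTOUR_MIDLINE = ("contour_forehead_mid", "contour_chin_mid")

MIDLINE_LABELS = MIDLINE_NAMED + CONTOUR_MIDLINE
PAIRED_LABELS = tuple(
    f"{stem}_{side}" for stem in PAIRED_STEMS + CONTOUR_STEMS for side in ("L", "R")
)

#: The full ordered label set: 14 midline + 29 L/R pairs = 72 landmarks.
LANDMARK_LABELS = MIDLINE_LABELS + PAIRED_LABELS

assert len(LANDMARK_LABELS) == 72

_LABEL_SET = frozenset(LANDMARK_LABELS)


def mirror_label(label: str) -> str:
    """Return the contralateral label (``_L`` <-> ``_R``); midline labels map to themselves."""
    if label.endswith("_L"):
        return label[:-2] + "_R"
    if label.endswith("_R"):
        return label[:-2] + "_L"
    return label


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class LandmarkParseError(ValueError):
    """Malformed landmark input; the message names the offending subject/row."""


class CohortValidationError(ValueError):
    """Cohort table violates an invariant; message lists subject and field."""


# --------------------------------------------------------------------------
# LandmarkSet
# --------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """One subject's 72 labeled 3D points, in millimetres.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    points : dict of str -> (3,) ndarray
        Ordered map label -> xyz coordinates in mm.
    laterality : Laterality
        Convention of the left/right labels.  Scanner output records the
        photographer's view; analysis requires anatomical orientation.
    normalized : bool
        True once the face is in the canonical pose (nasal tip at the
        origin, inter-canthal axis along x, vertical face axis along +y).
    """

    subject_id: str
    points: Dict[str, np.ndarray]
    laterality: Laterality = Laterality.PHOTOGRAPHER
    normalized: bool = False

    def __post_init__(self) -> None:
        self.laterality = Laterality(self.laterality)
        clean: Dict[str, np.ndarray] = {}
        for label, xyz in self.points.items():
            arr = np.asarray(xyz, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise LandmarkParseError(
                    f"subject {self.subject_id!r}: non-finite coordinate for {label!r}"
                )
            clean[label] = arr
        self.points = clean
        missing = _LABEL_SET - set(self.points)
        if missing:
            raise LandmarkParseError(
                f"subject {self.subject_id!r}: missing landmark(s) {sorted(missing)}"
            )
        extra = set(self.points) - _LABEL_SET
        if extra:
            raise LandmarkParseError(
                f"subject {self.subject_id!r}: unknown landmark label(s) {sorted(extra)}"
            )
        if self.normalized:
            if np.linalg.norm(self.points["pronasale"]) > 1e-9:
                raise LandmarkParseError(
                    f"subject {self.subject_id!r}: flagged normalized but pronasale "
                    "is not at the origin"
                )

    def __getitem__(self, label: str) -> np.ndarray:
        return self.points[label]

    def coords(self, labels: Optional[Iterable[str]] = None) -> np.ndarray:
        """Stack coordinates as an (n, 3) array in dictionary order."""
        labels = LANDMARK_LABELS if labels is None else tuple(labels)
        return np.stack([self.points[lab] for lab in labels])

    def with_points(self, points: Dict[str, np.ndarray], **changes) -> "LandmarkSet":
        """Copy with replaced coordinates (and optional metadata changes)."""
        return replace(self, points=dict(points), **changes)


# --------------------------------------------------------------------------
# Cohort table
# --------------------------------------------------------------------------

#: Instrument ranges for clinical scale totals (inclusive bounds).
SCALE_RANGES = {
    "ims": (-66, 66),
    "phq9": (0, 27),
    "gad7": (0, 21),
    "hdrs17": (0, 68),
    "hama": (0, 56),
    "ymrs": (0, 60),
}

#: Retained subjects must score YMRS <= 6 (mania exclusion criterion).
YMRS_CUTOFF = 6

COHORT_COLUMNS = [
    "subject_id",
    "sex",
    "group",
    "age",
    "bmi",
    "diagnosis",
    "psychotic",
    "ims",
    "phq9",
    "gad7",
    "hdrs17",
    "hama",
    "ymrs",
]

_SEX_VALUES = {"male", "female"}
_GROUP_VALUES = {"NSR", "SR"}
_DIAGNOSIS_VALUES = {"single_episode", "recurrent"}


@dataclass
class CohortTable:
    """Per-subject labels and clinical covariates.

    Wraps a validated :class:`pandas.DataFrame` with one row per subject:
    sex (male/female), risk group (SR = suicide risk, NSR = no suicide
    risk), age, BMI, diagnosis subtype, psychotic-symptom flag and the six
    clinical scale totals (IMS, PHQ-9, GAD-7, HDRS-17, HAMA, YMRS).
    """

    data: pd.DataFrame
    excluded: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CohortValidationError(f"cohort table missing columns {missing_cols}")
        if df["subject_id"].duplicated().any():
            dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise CohortValidationError(f"duplicate subject id(s) {dups}")
        problems = []
        for _, row in df.iterrows():
            sid = row["subject_id"]
            if row["sex"] not in _SEX_VALUES:
                problems.append(f"{sid}: sex={row['sex']!r}")
            if row["group"] not in _GROUP_VALUES:
                problems.append(f"{sid}: group={row['group']!r}")
            if row["diagnosis"] not in _DIAGNOSIS_VALUES and not pd.isna(row["diagnosis"]):
                problems.append(f"{sid}: diagnosis={row['diagnosis']!r}")
            for scale, (lo, hi) in SCALE_RANGES.items():
                val = row[scale]
                if pd.isna(val):
                    continue  # optional covariates may be absent
                if not lo <= val <= hi:
                    problems.append(f"{sid}: {scale}={val} outside [{lo}, {hi}]")
        if problems:
            raise CohortValidationError(
                "cohort validation failed: " + "; ".join(problems)
            )
        # mania exclusion: flag rather than silently drop
        over = df.loc[df["ymrs"] > YMRS_CUTOFF, "subject_id"].tolist()
        self.excluded = list(dict.fromkeys(list(self.excluded) + over))
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def retained(self) -> pd.DataFrame:
        """Rows passing the YMRS exclusion criterion."""
        return self.data[~self.data["subject_id"].isin(self.excluded)].reset_index(
            drop=True
        )


# --------------------------------------------------------------------------
# Landmark file I/O
# --------------------------------------------------------------------------


def read_landmarks(path, layout: str = "long") -> List[LandmarkSet]:
    """Read landmark sets from CSV.

    Parameters
    ----------
    path : path-like
        CSV file.  Long layout requires columns ``subject_id, landmark,
        x_mm, y_mm, z_mm`` and optionally ``laterality`` and ``normalized``.
        Wide layout requires ``subject_id`` plus ``<label>_x/_y/_z``.
    layout : {"long", "wide"}

    Returns
    -------
    list of LandmarkSet
        One per subject, in order of first appearance.
    """
    df = pd.read_csv(path)
    if layout == "long":
        return _read_long(df)
    if layout == "wide":
        return _read_wide(df)
    raise ValueError(f"unknown layout {layout!r}")


def _read_long(df: pd.DataFrame) -> List[LandmarkSet]:
    required = {"subject_id", "landmark", "x_mm", "y_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise LandmarkParseError(f"landmark file missing columns {sorted(missing)}")
    for col in ("x_mm", "y_mm", "z_mm"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise LandmarkParseError(
                f"non-numeric coordinate in column {col!r} at row {row} "
                f"(subject {df.loc[df.index[bad][0], 'subject_id']!r})"
            )
        df[col] = pd.to_numeric(df[col])
    sets: List[LandmarkSet] = []
    seen = set()
    for sid, grp in df.groupby("subject_id", sort=False):
        if sid in seen:
            raise LandmarkParseError(f"duplicate subject block for {sid!r}")
        seen.add(sid)
        if grp["landmark"].duplicated().any():
            dup = grp.loc[grp["landmark"].duplicated(), "landmark"].iloc[0]
            raise LandmarkParseError(
                f"subject {sid!r}: duplicate row for landmark {dup!r}"
            )
        pts = {
            row.landmark: np.array([row.x_mm, row.y_mm, row.z_mm])
            for row in grp.itertuples()
        }
        lat = (
            Laterality(grp["laterality"].iloc[0])
            if "laterality" in grp.columns
            else Laterality.PHOTOGRAPHER
        )
        norm = bool(grp["normalized"].iloc[0]) if "normalized" in grp.columns else False
        sets.append(LandmarkSet(str(sid), pts, laterality=lat, normalized=norm))
    return sets


def _read_wide(df: pd.DataFrame) -> List[LandmarkSet]:
    if "subject_id" not in df.columns:
        raise LandmarkParseError("wide landmark file missing 'subject_id'")
    sets = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        pts = {}
        for lab in LANDMARK_LABELS:
            try:
                pts[lab] = np.array(
                    [row[f"{lab}_x"], row[f"{lab}_y"], row[f"{lab}_z"]], dtype=float
                )
            except KeyError as exc:
                raise LandmarkParseError(
                    f"subject {sid!r}: missing wide column for landmark {lab!r}"
                ) from exc
        lat = (
            Laterality(row["laterality"])
            if "laterality" in df.columns
            else Laterality.PHOTOGRAPHER
        )
        sets.append(LandmarkSet(sid, pts, laterality=lat))
    return sets


def write_landmarks(sets: List[LandmarkSet], path) -> None:
    """Write landmark sets in the long CSV layout (lossless round trip)."""
    rows = []
    for lm in sets:
        for lab in LANDMARK_LABELS:
            x, y, z = lm.points[lab]
            rows.append(
                {
                    "subject_id": lm.subject_id,
                    "landmark": lab,
                    "x_mm": x,
                    "y_mm": y,
                    "z_mm": z,
                    "laterality": lm.laterality.value,
                    "normalized": lm.normalized,
                }
            )
    cols = ["subject_id", "landmark", "x_mm", "y_mm", "z_mm", "laterality", "normalized"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.12g")


# --------------------------------------------------------------------------
# Cohort file I/O
# --------------------------------------------------------------------------


def read_cohort(path) -> CohortTable:
    """Read and validate a cohort CSV; raises :class:`CohortValidationError`."""
    df = pd.read_csv(path)
    if "psychotic" in df.columns:
        df["psychotic"] = df["psychotic"].astype(bool)
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, index=False, float_format="%.12g")
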