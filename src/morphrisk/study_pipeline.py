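"""End-to-end orchestration: simulate or ingest -> normalize -> extract ->
screen (overall and by sex) -> interaction regression -> report.

The report mirrors the table structure of a case-control facial-morphometry
study: a cohort-characteristics table, an overall 47-feature screen, a
sex-stratified screen, and a logistic regression of risk on sex, selected
facial features, and sex x feature interaction terms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd

from morphrisk.landmark_io import CohortTable, LandmarkSet, Laterality
from morphrisk.morphometry import (
    FEATURE_NAMES,
    convert_laterality,
    extract_features,
    normalize_pose,
)
from morphrisk.stats_engine import (
    RegressionResult,
    bh_adjust,
    chi_square_2x2,
    gate_test,
    logistic_fit,
)
from morphrisk.synthetic_cohort import GeneratorConfig, default_study_config, sample_intake

logger = logging.getLogger("morphrisk")

__all__ = [
    "AnalysisConfig",
    "StudyReport",
    "build_feature_table",
    "summarize_cohort",
    "run_overall_screen",
    "run_sex_stratified_screen",
    "run_interaction_regression",
    "run_full_study",
]

DEFAULT_REGRESSION_FEATURES = ("Philtrum length", "Philtrum depth", "Dist Leye nose")
DEFAULT_INTERACTION_FEATURES = ("Philtrum depth", "Dist Leye nose")


@dataclass
class AnalysisConfig:
    """Parameters of a full study run."""

    generator: Optional[GeneratorConfig] = None
    landmarks_path: Optional[str] = None
    cohort_path: Optional[str] = None
    gate_alpha: float = 0.05
    screen_alpha: float = 0.05
    regression_features: Tuple[str, ...] = DEFAULT_REGRESSION_FEATURES
    interaction_features: Tuple[str, ...] = DEFAULT_INTERACTION_FEATURES
    n_withdrawn: int = 10
    n_quality_fail: int = 9
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.gate_alpha < 1 or not 0 < self.screen_alpha < 1:
            raise ValueError("alphas must lie in (0, 1)")
        for f in self.regression_features + self.interaction_features:
            if f not in FEATURE_NAMES:
                raise ValueError(f"unknown regression feature {f!r}")


@dataclass
class StudyReport:
    cohort_summary: pd.DataFrame
    overall_screen: pd.DataFrame
    sex_stratified_screen: pd.DataFrame
    regression: pd.DataFrame
    provenance: Dict = dc_field(default_factory=dict)
    counts: Dict[str, int] = dc_field(default_factory=dict)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        self.cohort_summary.to_csv(out / "cohort_summary.csv", index=False, float_format=fmt)
        self.overall_screen.to_csv(out / "overall_screen.csv", index=False, float_format=fmt)
        self.sex_stratified_screen.to_csv(
            out / "sex_stratified_screen.csv", index=False, float_format=fmt
        )
        self.regression.to_csv(out / "regression.csv", index=False, float_format=fmt)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True, default=str) + "\n"
        )
        (out / "summary.txt").write_text(self._summary_text())

    def _summary_text(self) -> str:
        sig = self.overall_screen[self.overall_screen["significant_raw"]]
        lines = [
            "morphrisk study report",
            "======================",
            f"subjects screened : {self.counts.get('screened', 'n/a')}",
            f"subjects excluded : {self.counts.get('excluded', 'n/a')}",
            f"subjects analyzed : {self.counts.get('analyzed', 'n/a')}",
            "",
            f"overall screen: {len(sig)} of {len(self.overall_screen)} features "
            f"significant at raw p < 0.05:",
        ]
        for _, row in sig.iterrows():
            lines.append(
                f"  {row['feature']}: {row['test']} = {row['statistic']:.3f}, "
                f"p = {row['p']:.4f} (p_adj = {row['p_adj']:.4f})"
            )
        lines.append("")
        lines.append("regression (angle terms in radians where applicable):")
        for _, row in self.regression.iterrows():
            lines.append(
                f"  {row['term']}: OR = {row['OR']:.3f} "
                f"[{row['ci95_low']:.3f}, {row['ci95_high']:.3f}], p = {row['p']:.4f}"
            )
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Feature extraction over a cohort
# --------------------------------------------------------------------------


def build_feature_table(faces: Sequence[LandmarkSet]) -> pd.DataFrame:
    """Convert laterality, normalize pose and extract the 47 features per subject."""
    rows = []
    for lm in faces:
        if lm.laterality == Laterality.PHOTOGRAPHER:
            lm = convert_laterality(lm)
        if not lm.normalized:
            lm, _ = normalize_pose(lm)
        feats = extract_features(lm)
        feats["subject_id"] = lm.subject_id
        rows.append(feats)
    return pd.DataFrame(rows)[["subject_id", *FEATURE_NAMES]]


# --------------------------------------------------------------------------
# Cohort characteristics (Table 1 analog)
# --------------------------------------------------------------------------


def summarize_cohort(cohort: pd.DataFrame, gate_alpha: float = 0.05) -> pd.DataFrame:
    """Group comparison of demographics and clinical covariates.

    Categorical variables (sex, diagnosis, psychotic symptoms) use the
    Yates-corrected chi-square; continuous covariates use the
    Shapiro-Wilk-gated two-sample test.
    """
    nsr = cohort[cohort["group"] == "NSR"]
    sr = cohort[cohort["group"] == "SR"]
    rows = []

    def add_categorical(name, level_of_interest, series_name):
        a = int((nsr[series_name] == level_of_interest).sum())
        b = int((nsr[series_name] != level_of_interest).sum())
        c = int((sr[series_name] == level_of_interest).sum())
        d = int((sr[series_name] != level_of_interest).sum())
        chi2, p = chi_square_2x2(a, b, c, d)
        rows.append(
            {
                "variable": name,
                "nsr_summary": f"{a} ({100 * a / max(a + b, 1):.0f}%)",
                "sr_summary": f"{c} ({100 * c / max(c + d, 1):.0f}%)",
                "test": "chi_square",
                "statistic": chi2,
                "p": p,
            }
        )

    add_categorical("Female, n (%)", "female", "sex")
    add_categorical("Single-episode, n (%)", "single_episode", "diagnosis")
    add_categorical("Psychotic symptoms, n (%)", True, "psychotic")
    for var in ("age", "bmi", "ims", "phq9", "gad7", "hdrs17", "hama"):
        res = gate_test(
            nsr[var].astype(float),
            sr[var].astype(float),
            alpha_gate=gate_alpha,
            feature=var,
            group_names=("NSR", "SR"),
        )
        s1 = res.group_summaries["NSR"]
        s2 = res.group_summaries["SR"]
        rows.append(
            {
                "variable": var,
                "nsr_summary": f"{s1['mean']:.2f} ({s1['sd']:.2f})",
                "sr_summary": f"{s2['mean']:.2f} ({s2['sd']:.2f})",
                "test": res.test_kind,
                "statistic": res.statistic,
                "p": res.p_raw,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Screens
# --------------------------------------------------------------------------


def _screen(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    merged = features.merge(cohort[["subject_id", "group"]], on="subject_id", how="inner")
    if len(merged) != len(features):
        raise ValueError("subject ids in feature table and cohort table do not match")
    nsr = merged[merged["group"] == "NSR"]
    sr = merged[merged["group"] == "SR"]
    rows = []
    for feat in FEATURE_NAMES:
        res = gate_test(
            nsr[feat],
            sr[feat],
            alpha_gate=cfg.gate_alpha,
            feature=feat,
            group_names=("NSR", "SR"),
        )
        s1, s2 = res.group_summaries["NSR"], res.group_summaries["SR"]
        rows.append(
            {
                "feature": feat,
                "nsr_mean": s1["mean"],
                "nsr_sd": s1["sd"],
                "nsr_n": s1["n"],
                "sr_mean": s2["mean"],
                "sr_sd": s2["sd"],
                "sr_n": s2["n"],
                "test": res.test_kind,
                "statistic": res.statistic,
                "p": res.p_raw,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    # headline significance calls follow raw p (adjusted values reported alongside)
    out["significant_raw"] = out["p"] < cfg.screen_alpha
    return out


def run_overall_screen(
    features: pd.DataFrame, cohort: CohortTable, cfg: Optional[AnalysisConfig] = None
) -> pd.DataFrame:
    """Gated two-group comparison of all 47 features (SR vs NSR)."""
    cfg = cfg or AnalysisConfig()
    return _screen(features, _cohort_frame(cohort), cfg)


def run_sex_stratified_screen(
    features: pd.DataFrame, cohort: CohortTable, cfg: Optional[AnalysisConfig] = None
) -> pd.DataFrame:
    """The 47-feature screen repeated within males and within females."""
    cfg = cfg or AnalysisConfig()
    cdf = _cohort_frame(cohort)
    frames = []
    for sex in ("male", "female"):
        sub = cdf[cdf["sex"] == sex]
        if sub.empty or sub["group"].nunique() < 2:
            raise ValueError(f"stratum {sex!r} is empty or single-group")
        feats = features[features["subject_id"].isin(sub["subject_id"])]
        scr = _screen(feats, sub, cfg)
        scr = scr.rename(
            columns={
                c: f"{sex}_{c}"
                for c in scr.columns
                if c != "feature"
            }
        )
        frames.append(scr)
    out = frames[0].merge(frames[1], on="feature")
    return out


# --------------------------------------------------------------------------
# Interaction regression
# --------------------------------------------------------------------------


def run_interaction_regression(
    features: pd.DataFrame,
    cohort: CohortTable,
    cfg: Optional[AnalysisConfig] = None,
) -> Tuple[RegressionResult, pd.DataFrame]:
    """Logistic regression of risk group on sex, features and sex x feature terms.

    Continuous features are z-scored before fitting, so estimates are per-SD
    log-odds; the returned table also reports the per-mm (per-unit)
    estimate.  Sex coding: male = 0 (reference), female = 1.
    """
    cfg = cfg or AnalysisConfig()
    cdf = _cohort_frame(cohort)
    merged = features.merge(cdf[["subject_id", "sex", "group"]], on="subject_id")
    if merged.empty:
        raise ValueError("no overlapping subject ids")
    y = (merged["group"] == "SR").astype(int).to_numpy()
    female = (merged["sex"] == "female").astype(float)
    X = pd.DataFrame({"Female": female})
    scales = {"Female": 1.0}
    for feat in cfg.regression_features:
        sd = merged[feat].std(ddof=1)
        if sd == 0:
            raise ValueError(f"feature {feat!r} is constant")
        X[feat] = (merged[feat] - merged[feat].mean()) / sd
        scales[feat] = float(sd)
    for feat in cfg.interaction_features:
        name = f"Female*{feat}"
        X[name] = X["Female"] * X[feat]
        scales[name] = scales[feat]
    result = logistic_fit(y, X)
    frame = result.to_frame()
    frame["estimate_per_unit"] = [
        row.estimate / scales.get(row.term, 1.0) for row in frame.itertuples()
    ]
    return result, frame


# --------------------------------------------------------------------------
# Full study
# --------------------------------------------------------------------------


def _cohort_frame(cohort) -> pd.DataFrame:
    return cohort.data if isinstance(cohort, CohortTable) else cohort


def _apply_exclusions(cohort: CohortTable) -> Tuple[pd.DataFrame, Dict[str, int]]:
    df = _cohort_frame(cohort).copy()
    n_in = len(df)
    drop = pd.Series(False, index=df.index)
    for flag in ("withdrawn", "quality_fail"):
        if flag in df.columns:
            drop |= df[flag].astype(bool)
    drop |= df["subject_id"].isin(cohort.excluded)
    retained = df[~drop].reset_index(drop=True)
    counts = {"screened": n_in, "excluded": int(drop.sum()), "analyzed": len(retained)}
    assert counts["screened"] == counts["excluded"] + counts["analyzed"]
    return retained, counts


def run_full_study(cfg: AnalysisConfig) -> StudyReport:
    """Execute the complete pipeline and (optionally) write the report files.

    With a generator config, a synthetic intake cohort is simulated
    (including subjects flagged for withdrawal or scan-quality failure);
    otherwise landmark and cohort CSVs are ingested.  Deterministic under a
    fixed seed.
    """
    from morphrisk.landmark_io import read_cohort, read_landmarks

    gen = None
    if cfg.generator is not None:
        gen = cfg.generator
        faces, cohort, _ = sample_intake(
            gen, n_withdrawn=cfg.n_withdrawn, n_quality_fail=cfg.n_quality_fail
        )
    elif cfg.landmarks_path and cfg.cohort_path:
        faces = read_landmarks(cfg.landmarks_path)
        cohort = read_cohort(cfg.cohort_path)
    else:
        gen = default_study_config(seed=cfg.seed)
        faces, cohort, _ = sample_intake(
            gen, n_withdrawn=cfg.n_withdrawn, n_quality_fail=cfg.n_quality_fail
        )
    logger.info("intake: %d subjects", len(faces))

    retained, counts = _apply_exclusions(cohort)
    logger.info(
        "exclusion stage: %d screened, %d excluded, %d analyzed",
        counts["screened"], counts["excluded"], counts["analyzed"],
    )
    keep = set(retained["subject_id"])
    faces = [f for f in faces if f.subject_id in keep]

    features = build_feature_table(faces)
    logger.info("extracted %d features for %d subjects", len(FEATURE_NAMES), len(features))

    retained_cohort = CohortTable(retained)
    cohort_summary = summarize_cohort(retained, gate_alpha=cfg.gate_alpha)
    overall = run_overall_screen(features, retained_cohort, cfg)
    stratified = run_sex_stratified_screen(features, retained_cohort, cfg)
    _, regression = run_interaction_regression(features, retained_cohort, cfg)

    report = StudyReport(
        cohort_summary=cohort_summary,
        overall_screen=overall,
        sex_stratified_screen=stratified,
        regression=regression,
        provenance={
            "seed": cfg.seed,
            "gate_alpha": cfg.gate_alpha,
            "screen_alpha": cfg.screen_alpha,
            "regression_features": list(cfg.regression_features),
            "interaction_features": list(cfg.interaction_features),
            "generator": None if gen is None else vars(gen),
            "software_version": __import__("morphrisk").__version__,
        },
        counts=counts,
    )
    if cfg.output_dir:
        report.write(cfg.output_dir)
    return report
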