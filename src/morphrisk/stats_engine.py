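"""Statistical toolkit for the morphometric screens and the risk regression.

Conventions match common psychiatric-morphometry practice:

* Each feature is routed by a Shapiro-Wilk gate — if both groups look
  normal (p > 0.05 in each), a pooled-variance two-sample t-test is used,
  otherwise a two-sided Mann-Whitney U with midrank tie handling and a
  continuity-corrected normal approximation.
* 2x2 contingency tables use the chi-square test with Yates continuity
  correction.
* Families of p-values are adjusted by the Benjamini-Hochberg step-up
  procedure (implemented here; monotone, capped at 1).
* The risk model is a maximum-likelihood logistic regression; Wald
  standard errors give two-sided p-values and 95% CIs on the odds-ratio
  scale, with BH adjustment across the model's non-intercept terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "TermResult",
    "RegressionResult",
    "SeparationError",
    "RankDeficiencyError",
    "shapiro_wilk",
    "gate_test",
    "t_from_summary",
    "mann_whitney_u",
    "chi_square_2x2",
    "bh_adjust",
    "logistic_fit",
    "or_from_estimate",
]


class SeparationError(RuntimeError):
    """Logistic fit is degenerate: a term (quasi-)separates the outcome."""


class RankDeficiencyError(ValueError):
    """Design matrix columns are collinear; message names the columns."""


@dataclass
class TestResult:
    """Outcome of one two-group comparison."""

    feature: str
    test_kind: str  # "t", "mann_whitney_u" or "chi_square"
    statistic: float
    p_raw: float
    p_adjusted: Optional[float] = None
    df: Optional[float] = None
    group_summaries: Dict[str, Dict[str, float]] = field(default_factory=dict)


@dataclass
class TermResult:
    name: str
    estimate: float
    se: float
    odds_ratio: float
    ci95: Tuple[float, float]
    p_wald: float
    p_adjusted: Optional[float] = None


@dataclass
class RegressionResult:
    terms: List[TermResult]
    log_likelihood: float
    converged: bool

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [t.name for t in self.terms],
                "estimate": [t.estimate for t in self.terms],
                "se": [t.se for t in self.terms],
                "OR": [t.odds_ratio for t in self.terms],
                "ci95_low": [t.ci95[0] for t in self.terms],
                "ci95_high": [t.ci95[1] for t in self.terms],
                "p": [t.p_wald for t in self.terms],
                "p_adj": [t.p_adjusted for t in self.terms],
            }
        )


# --------------------------------------------------------------------------
# Univariate tests
# --------------------------------------------------------------------------


def shapiro_wilk(sample: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk normality test: returns (W, p)."""
    x = np.asarray(sample, float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _summaries(name1, g1, name2, g2) -> Dict[str, Dict[str, float]]:
    out = {}
    for name, g in ((name1, g1), (name2, g2)):
        g = np.asarray(g, float)
        out[name] = {
            "mean": float(g.mean()),
            "sd": float(g.std(ddof=1)) if len(g) > 1 else float("nan"),
            "median": float(np.median(g)),
            "n": int(len(g)),
        }
    return out


def gate_test(
    g1: Sequence[float],
    g2: Sequence[float],
    alpha_gate: float = 0.05,
    feature: str = "",
    group_names: Tuple[str, str] = ("group1", "group2"),
) -> TestResult:
    """Normality-gated two-sample comparison.

    Pooled-variance t-test when both groups pass Shapiro-Wilk at
    ``alpha_gate``; Mann-Whitney U otherwise.  The returned result records
    which route fired.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("gate_test requires n >= 3 in both groups")
    normal = True
    for g in (g1, g2):
        if np.ptp(g) == 0:
            normal = False  # constant sample: gate routes to the rank test
            break
        _, p_sw = shapiro_wilk(g)
        if p_sw <= alpha_gate:
            normal = False
            break
    if normal:
        t, p = stats.ttest_ind(g1, g2, equal_var=True)
        res = TestResult(
            feature, "t", float(t), float(p), df=float(len(g1) + len(g2) - 2)
        )
    else:
        res = mann_whitney_u(g1, g2, feature=feature)
    res.group_summaries = _summaries(group_names[0], g1, group_names[1], g2)
    return res


def t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> Tuple[float, float, float]:
    """Pooled-variance two-sample t from group summaries.

    Returns (t, df, two-sided p).  The statistic equals the raw-data pooled
    t whenever the summaries are exact.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("t_from_summary requires n >= 2 per group")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def mann_whitney_u(
    g1: Sequence[float], g2: Sequence[float], feature: str = ""
) -> TestResult:
    """Two-sided Mann-Whitney U (first group's U; ties by midranks).

    p-value from the normal approximation with tie-corrected variance and
    continuity correction.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    res = stats.mannwhitneyu(
        g1, g2, use_continuity=True, alternative="two-sided", method="asymptotic"
    )
    return TestResult(feature, "mann_whitney_u", float(res.statistic), float(res.pvalue))


def chi_square_2x2(
    a: int, b: int, c: int, d: int, corrected: bool = True
) -> Tuple[float, float]:
    """Chi-square test of a 2x2 table [[a, b], [c, d]] with df = 1.

    ``corrected`` applies the Yates continuity correction
    chi2 = sum (max(0, |O - E| - 0.5))^2 / E.
    """
    table = np.array([[a, b], [c, d]], float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("all table margins must be positive")
    expected = np.outer(rows, cols) / n
    dev = np.abs(table - expected)
    if corrected:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def bh_adjust(p: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted ascending, p(i) is multiplied by m/i, the cumulative minimum is
    taken from the largest down, values are capped at 1.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


# --------------------------------------------------------------------------
# Logistic regression
# --------------------------------------------------------------------------


def logistic_fit(
    y: Sequence[int],
    X: pd.DataFrame,
    add_intercept: bool = True,
    adjust_family: bool = True,
) -> RegressionResult:
    """Maximum-likelihood logistic regression with Wald inference.

    Parameters
    ----------
    y : binary outcomes (0/1)
    X : design matrix with named columns (no intercept column)
    add_intercept : prepend a constant term
    adjust_family : BH-adjust the Wald p-values across non-intercept terms

    Raises
    ------
    RankDeficiencyError
        If design columns are collinear (names the offending columns).
    SeparationError
        If the likelihood is unbounded (perfect or quasi separation).
    """
    y = np.asarray(y, float)
    X = pd.DataFrame(X).astype(float)
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    mat = design.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify columns that do not increase rank
        bad = []
        r = 0
        for j in range(mat.shape[1]):
            rj = np.linalg.matrix_rank(mat[:, : j + 1])
            if rj == r:
                bad.append(design.columns[j])
            r = rj
        raise RankDeficiencyError(f"collinear design column(s): {bad}")
    model = sm.Logit(y, design)
    try:
        fit = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    converged = bool(fit.mle_retvals.get("converged", False))
    se = np.asarray(fit.bse)
    if not converged or np.any(~np.isfinite(se)) or np.any(se > 1e3):
        worst = design.columns[int(np.nanargmax(se))]
        raise SeparationError(
            f"logistic fit degenerate (suspected separation via term {worst!r})"
        )
    params = np.asarray(fit.params)
    zcrit = stats.norm.ppf(0.975)
    terms = []
    for name, est, s in zip(design.columns, params, se):
        pw = 2.0 * stats.norm.sf(abs(est) / s)
        terms.append(
            TermResult(
                name=str(name),
                estimate=float(est),
                se=float(s),
                odds_ratio=float(np.exp(est)),
                ci95=(float(np.exp(est - zcrit * s)), float(np.exp(est + zcrit * s))),
                p_wald=float(pw),
            )
        )
    if adjust_family:
        family = [t for t in terms if t.name != "const"]
        adj = bh_adjust([t.p_wald for t in family])
        for t, pa in zip(family, adj):
            t.p_adjusted = float(pa)
    return RegressionResult(
        terms=terms, log_likelihood=float(fit.llf), converged=converged
    )


def or_from_estimate(estimate: float) -> float:
    """Odds ratio from a log-odds estimate: exp(estimate)."""
    if not np.isfinite(estimate):
        raise ValueError("estimate must be finite")
    return float(np.exp(estimate))
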