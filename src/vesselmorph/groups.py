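"""Cross-sample statistics for capillary–neurite cohort tables.

Implements the cohort-level analyses performed on per-sample skeleton
summaries: Spearman rank correlation between capillary and neurite
morphometrics, Bartlett's test for a variance difference between brain
areas, ordinary least-squares regression lines, and a slope-difference
(interaction) test between diagnostic groups.  Significance is declared at
α = 0.05 per test, with no multiple-testing correction — the analyses are
reported the way they would be in the source field, one test at a time.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError

__all__ = [
    "AssociationResult",
    "LinearFit",
    "spearman_association",
    "bartlett_variance_test",
    "linear_regression",
    "CohortReport",
    "run_fig4_analysis",
    "COHORT_COLUMNS",
]

ALPHA = 0.05

#: Required columns of a cohort table (one row per sample × brain area).
COHORT_COLUMNS = (
    "sample_id", "area", "group",
    "capillary_curvature", "capillary_diameter",
    "neurite_curvature", "neurite_radius",
)

#: Exact-permutation p-values are used below this sample size, the
#: t-approximation at or above it.
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of one statistical test, flagged at α = 0.05."""

    name: str
    estimate: float
    p_value: float
    n: int
    method: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def __str__(self) -> str:
        flag = "significant" if self.significant else "not significant"
        return (f"{self.name}: estimate={self.estimate:.4f}, "
                f"p={self.p_value:.4g}, n={self.n} ({flag} at alpha={ALPHA})")


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # mid-ranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(np.dot(rx, rx) * np.dot(ry, ry))
    if denom == 0:
        raise InsufficientDataError("constant input; correlation undefined")
    return float(np.dot(rx, ry) / denom)


def spearman_association(x, y, name: str = "Spearman rho") -> AssociationResult:
    """Spearman rank correlation with a two-sided p-value.

    ρ is the Pearson correlation of mid-ranks (ties averaged).  For n ≥ 10
    the p-value uses the t-approximation t = ρ·√((n−2)/(1−ρ²)) on n−2
    degrees of freedom; for n < 10 it is the exact permutation p-value over
    all n! orderings (the fraction of permutations with |ρ| at least as
    large as observed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {n}")
    rho = _spearman_rho(x, y)
    if n > EXACT_PERMUTATION_MAX_N:
        method = "t-approximation"
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    else:
        method = "exact permutation"
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(np.dot(rxc, rxc) * np.dot(ryc, ryc))
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return AssociationResult(name=name, estimate=rho, p_value=float(min(p, 1.0)),
                             n=n, method=method)


def bartlett_variance_test(groups, name: str = "Bartlett") -> AssociationResult:
    """Bartlett's test for equal variances across k groups.

    The K² statistic (with the standard correction factor) is compared to a
    χ² distribution on k−1 degrees of freedom.  Each group needs at least
    two values and nonzero variance.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise InsufficientDataError("each group needs at least 2 values")
        if np.var(g, ddof=1) == 0:
            raise ParameterError("zero-variance group; Bartlett statistic undefined")
    stat, p = stats.bartlett(*groups)
    return AssociationResult(name=name, estimate=float(stat), p_value=float(p),
                             n=sum(len(g) for g in groups), method="chi-squared")


def linear_regression(x, y) -> LinearFit:
    """Ordinary least-squares line y = slope·x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ParameterError("x and y must be 1-D of equal length >= 2")
    if np.ptp(x) == 0:
        raise ParameterError("constant x; regression undefined")
    res = stats.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept))


def _slope_interaction_test(df: pd.DataFrame) -> AssociationResult:
    """OLS interaction test: does the curvature–curvature slope differ by group?"""
    import statsmodels.api as sm
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise InsufficientDataError("slope comparison needs exactly 2 groups")
    g = (df["group"] == groups[1]).astype(float).to_numpy()
    x = df["neurite_curvature"].to_numpy(dtype=float)
    y = df["capillary_curvature"].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([x, g, x * g]))
    fit = sm.OLS(y, X).fit()
    return AssociationResult(
        name=f"slope difference ({groups[1]} vs {groups[0]})",
        estimate=float(fit.params[3]), p_value=float(fit.pvalues[3]),
        n=len(df), method="OLS interaction t-test")


@dataclass
class CohortReport:
    """Results of the cohort correlation/variance analysis."""

    curvature_association: AssociationResult
    diameter_association: AssociationResult
    area_variance: AssociationResult
    curvature_regression: LinearFit
    slope_difference: AssociationResult | None
    n_rows: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in (self.curvature_association, self.diameter_association,
                  self.area_variance, self.slope_difference):
            if r is None:
                continue
            rows.append({"test": r.name, "estimate": r.estimate,
                         "p_value": r.p_value, "n": r.n, "method": r.method,
                         "significant": r.significant})
        rows.append({"test": "curvature regression slope",
                     "estimate": self.curvature_regression.slope,
                     "p_value": float("nan"), "n": self.n_rows,
                     "method": "OLS", "significant": False})
        rows.append({"test": "curvature regression intercept",
                     "estimate": self.curvature_regression.intercept,
                     "p_value": float("nan"), "n": self.n_rows,
                     "method": "OLS", "significant": False})
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [
            "Cohort analysis (alpha = 0.05 per test; no multiple-testing correction)",
            f"  rows: {self.n_rows}",
            f"  {self.curvature_association}",
            f"  {self.diameter_association}",
            f"  {self.area_variance}",
            (f"  regression (capillary vs neurite curvature): "
             f"slope={self.curvature_regression.slope:.4g}, "
             f"intercept={self.curvature_regression.intercept:.4g}"),
        ]
        if self.slope_difference is not None:
            lines.append(f"  {self.slope_difference}")
        return "\n".join(lines) + "\n"


def run_fig4_analysis(cohort: pd.DataFrame, area_pair: tuple[str, str] | None = None
                      ) -> CohortReport:
    """Run the full cohort analysis on a capillary/neurite summary table.

    Expects the columns in :data:`COHORT_COLUMNS` (one row per
    sample × area).  Emits: (a) Spearman ρ for mean capillary curvature vs
    mean neurite curvature; (b) Spearman ρ for mean capillary diameter vs
    neurite thickness radius; (c) Bartlett's test of the between-area
    variances of mean capillary curvature; (d) the OLS regression line for
    (a), fitted on all rows; and a descriptive slope-difference interaction
    test between groups when exactly two groups are present.
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ParameterError(f"cohort table missing columns: {missing}")
    df = cohort.dropna(subset=[c for c in COHORT_COLUMNS]).copy()
    if len(df) < 3:
        raise InsufficientDataError(
            f"need at least 3 complete rows, got {len(df)}")

    curv = spearman_association(
        df["neurite_curvature"], df["capillary_curvature"],
        name="capillary curvature vs neurite curvature (Spearman rho)")
    diam = spearman_association(
        df["neurite_radius"], df["capillary_diameter"],
        name="capillary diameter vs neurite thickness radius (Spearman rho)")

    areas = sorted(df["area"].unique()) if area_pair is None else list(area_pair)
    if len(areas) >= 2:
        grouped = [df.loc[df["area"] == a, "capillary_curvature"].to_numpy()
                   for a in areas]
        var = bartlett_variance_test(
            grouped, name=f"area variance of capillary curvature "
                          f"({' vs '.join(map(str, areas))}, Bartlett)")
    else:
        raise InsufficientDataError("variance comparison needs >= 2 areas")

    fit = linear_regression(df["neurite_curvature"], df["capillary_curvature"])
    slope_diff = None
    if df["group"].nunique() == 2:
        slope_diff = _slope_interaction_test(df)
    return CohortReport(curvature_association=curv, diameter_association=diam,
                        area_variance=var, curvature_regression=fit,
                        slope_difference=slope_diff, n_rows=len(df))
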