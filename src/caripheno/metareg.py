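"""Inverse-SE-weighted linear meta-regression of cohort-level estimates.

Each cohort contributes a point: an estimate (e.g. the cohort mean score on
a caries cluster), its standard error, and a cohort-level covariate (e.g.
mean age).  The fixed-effect meta-regression fits

    estimate_j = intercept + slope * covariate_j + error_j,
    Var(error_j) = se_j^2,

by weighted least squares.  The default weights are 1/se^2 (inverse
variance), the standard precision weighting; a literal 1/se scheme is also
provided because "inverse standard error-weighted" is read both ways in the
literature.  Either way the slope variance is computed from the weighted
normal equations with the known per-point variances (the sandwich form,
which collapses to (X'WX)^-1 under inverse-variance weights); no residual
variance is estimated, i.e. no between-cohort heterogeneity component.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CohortPoint:
    """One cohort's estimate, its standard error, and a cohort-level covariate."""

    estimate: float
    se: float
    covariate: float
    n: int | None = None
    cohort: str = ""

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"standard error must be positive (got {self.se})")


@dataclass(frozen=True)
class MetaRegressionFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_ci95: tuple[float, float]
    weights_used: str
    residuals: tuple[float, ...]

    def predict(self, covariate: float) -> float:
        return self.intercept + self.slope * covariate


def fit_meta_regression(
    points: list[CohortPoint], weight_scheme: str = "inverse_variance"
) -> MetaRegressionFit:
    """Weighted least squares of cohort estimates on a cohort covariate.

    Requires at least 3 points with non-constant covariate values.
    """
    if weight_scheme not in ("inverse_variance", "inverse_se"):
        raise ValueError(f"unknown weight_scheme: {weight_scheme!r}")
    if len(points) < 3:
        raise ValueError("meta-regression needs at least 3 cohort points")
    x = np.array([p.covariate for p in points], dtype=float)
    y = np.array([p.estimate for p in points], dtype=float)
    se = np.array([p.se for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant across cohorts")

    w = 1.0 / se**2 if weight_scheme == "inverse_variance" else 1.0 / se
    X = np.column_stack([np.ones_like(x), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    beta = np.linalg.solve(xtwx, xtwy)

    # sandwich covariance with known per-point variances se^2; equals
    # (X'WX)^-1 when w = 1/se^2
    bread = np.linalg.inv(xtwx)
    meat = X.T @ ((w**2 * se**2)[:, None] * X)
    cov = bread @ meat @ bread

    slope, intercept = float(beta[1]), float(beta[0])
    slope_se = sqrt(cov[1, 1])
    z = stats.norm.ppf(0.975)
    return MetaRegressionFit(
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=sqrt(cov[0, 0]),
        slope_ci95=(slope - z * slope_se, slope + z * slope_se),
        weights_used=weight_scheme,
        residuals=tuple(float(r) for r in (y - X @ beta)),
    )


def standard_error_of_mean(scores) -> tuple[float, float]:
    """Mean and standard error (sample SD over sqrt n) of a list of values."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("empty score list")
    if arr.size == 1:
        raise ValueError("standard error undefined for a single value")
    return float(arr.mean()), float(arr.std(ddof=1) / sqrt(arr.size))
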