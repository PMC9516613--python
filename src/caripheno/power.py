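"""GWAS design calculations for quantitative and binary caries traits.

A single-variant association test is a 1-df chi-square test; under the
alternative the statistic is noncentral chi-square with noncentrality
parameter (NCP) lambda, and power is

    power = P[ chi2_1(lambda) > chi2_1 upper-alpha quantile ].

For a quantitative trait where the variant explains a fraction q of the
phenotypic variance, the marginal-test NCP is

    lambda = n * q / (1 - q),

the exact noncentrality of the F/chi-square limit of the marginal regression
test (at q ~ 1e-4 the /(1-q) correction is negligible but the convention must
be fixed).  For a binary trait tested with the 1-df allelic trend (score)
test under Hardy-Weinberg equilibrium,

    lambda = (ln OR)^2 * 2 * maf * (1 - maf) * n_cases * n_controls / n,

the standard small-effect approximation in terms of the per-allele odds
ratio and minor allele frequency.

The significance threshold defaults to genome-wide alpha = 5e-8.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import log

import pandas as pd
from scipy import optimize, stats

#: Conventional genome-wide significance threshold.
GENOME_WIDE_ALPHA = 5e-8


@dataclass(frozen=True)
class PowerResult:
    """Detection probability and the chi-square quantities behind it."""

    power: float
    ncp: float
    critical_value: float


def _chi2_power(ncp: float, alpha: float) -> PowerResult:
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if ncp < 0:
        raise ValueError("noncentrality parameter must be nonnegative")
    crit = stats.chi2.isf(alpha, df=1)
    if ncp == 0.0:
        power = alpha  # central null: power equals the test size
    else:
        power = float(stats.ncx2.sf(crit, df=1, nc=ncp))
    return PowerResult(power=power, ncp=float(ncp), critical_value=float(crit))


def quantitative_power(
    n: int, variance_explained_pct: float, alpha: float = GENOME_WIDE_ALPHA
) -> PowerResult:
    """Power to detect a variant explaining the given percent of trait variance."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= variance_explained_pct < 100.0:
        raise ValueError("variance_explained_pct must be in [0, 100)")
    q = variance_explained_pct / 100.0
    return _chi2_power(n * q / (1.0 - q), alpha)


def min_detectable_var_explained(
    n: int,
    alpha: float = GENOME_WIDE_ALPHA,
    target_power: float = 0.80,
    rtol: float = 1e-8,
) -> float:
    """Smallest percent of variance explained detectable with the target power.

    Power is strictly increasing in the variance explained, so the inverse is
    found by monotone root-finding to relative tolerance ``rtol``.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    if target_power <= alpha:
        raise ValueError("target power at or below alpha is reached at zero effect")

    def gap(q_pct: float) -> float:
        return quantitative_power(n, q_pct, alpha).power - target_power

    lo, hi = 0.0, 1e-6
    while gap(hi) < 0:
        hi *= 10.0
        if hi > 99.0:
            raise ValueError("target power unreachable below 99% variance explained")
    return float(optimize.brentq(gap, lo, hi, rtol=rtol, xtol=1e-300))


def binary_power(
    n_cases: int,
    n_controls: int,
    maf: float,
    odds_ratio: float,
    alpha: float = GENOME_WIDE_ALPHA,
) -> PowerResult:
    """Power of the 1-df allelic trend test for a binary trait."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    n = n_cases + n_controls
    ncp = log(odds_ratio) ** 2 * 2.0 * maf * (1.0 - maf) * n_cases * n_controls / n
    return _chi2_power(ncp, alpha)


def power_grid(
    mafs,
    effects,
    n: int | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
    trait_type: str = "quantitative",
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> pd.DataFrame:
    """Evaluate power over a cartesian grid of MAF and effect size.

    ``trait_type="quantitative"`` interprets ``effects`` as percent variance
    explained (power is MAF-free under that parametrization, but the MAF
    column is kept for plotting symmetry); ``trait_type="binary"`` interprets
    them as per-allele odds ratios and requires case/control counts.
    """
    mafs, effects = list(mafs), list(effects)
    if not mafs or not effects:
        raise ValueError("maf and effect grids must be nonempty")
    rows = []
    for maf, effect in product(mafs, effects):
        if trait_type == "quantitative":
            if n is None:
                raise ValueError("quantitative grid requires n")
            res = quantitative_power(n, effect, alpha)
        elif trait_type == "binary":
            if n_cases is None or n_controls is None:
                raise ValueError("binary grid requires n_cases and n_controls")
            res = binary_power(n_cases, n_controls, maf, effect, alpha)
        else:
            raise ValueError(f"unknown trait_type: {trait_type!r}")
        rows.append((maf, effect, res.power))
    return pd.DataFrame(rows, columns=["maf", "effect", "power"])
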