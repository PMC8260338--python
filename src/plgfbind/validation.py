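"""Method-comparison statistics: measured vs predicted total PlGF.

Provides the Spearman correlation (with an exact permutation p-value for
small samples), a line-of-identity regression check (OLS confidence
intervals by default, Passing-Bablok as an option), and the recovery
fraction used in spike-in validation experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import islice, permutations
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._exceptions import InputError, NotFittableError

__all__ = [
    "ComparisonResult",
    "IdentityFit",
    "spearman_correlation",
    "identity_line_fit",
    "spike_recovery",
]

#: Largest n for which the permutation null of Spearman's rho is enumerated
#: exactly (n! permutations); beyond this the t-approximation is used.
EXACT_SPEARMAN_MAX_N = 10


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a statistical comparison: statistic, p-value, and how it was obtained."""

    statistic_name: str
    statistic: float
    p_value: float
    n: int
    method_notes: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise InputError(f"p-value outside [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "method_notes": self.method_notes,
        }
        d.update(self.extra)
        return d


@dataclass(frozen=True)
class IdentityFit:
    """Regression of predicted on measured values, judged against the identity line.

    ``identity_compatible`` is true when the 95% CI of the slope contains 1
    and the 95% CI of the intercept contains 0.
    """

    slope: float
    slope_ci: tuple
    intercept: float
    intercept_ci: tuple
    n: int
    method: str

    @property
    def identity_compatible(self) -> bool:
        return (
            self.slope_ci[0] <= 1.0 <= self.slope_ci[1]
            and self.intercept_ci[0] <= 0.0 <= self.intercept_ci[1]
        )

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_ci_low": self.slope_ci[0],
            "slope_ci_high": self.slope_ci[1],
            "intercept": self.intercept,
            "intercept_ci_low": self.intercept_ci[0],
            "intercept_ci_high": self.intercept_ci[1],
            "n": self.n,
            "method": self.method,
            "identity_compatible": self.identity_compatible,
        }


def _exact_spearman_p(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    """Two-sided p by full enumeration of the n! pairings of the rank vectors.

    Under the permutation null only the cross-product sum varies, so the
    comparison is done on |sum(rx * ry_perm) - n * mean_rx * mean_ry|.
    """
    n = rank_x.size
    center = n * rank_x.mean() * rank_y.mean()
    observed = abs(float(rank_x @ rank_y) - center)
    count = 0
    total = 0
    perm_iter = permutations(rank_y)
    while True:
        chunk = list(islice(perm_iter, 100_000))
        if not chunk:
            break
        dots = np.asarray(chunk, dtype=float) @ rank_x
        count += int(np.sum(np.abs(dots - center) >= observed - 1e-9))
        total += len(chunk)
    return count / total


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Spearman rank correlation with tie-aware average ranks.

    The p-value is exact (full permutation enumeration) for n <= 10 and the
    usual t-approximation for larger samples; two-sided throughout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise InputError(f"need at least 3 paired observations, got {x.size}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise InputError("missing values are not allowed")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise InputError("correlation undefined: one variable is constant")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if x.size <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(rx, ry)
        notes = f"exact permutation p ({math.factorial(x.size)} pairings)"
    else:
        p = float(stats.spearmanr(x, y).pvalue)
        notes = "t-approximation"
    return ComparisonResult(
        statistic_name="spearman_rho",
        statistic=rho,
        p_value=p,
        n=int(x.size),
        method_notes=notes,
    )


def _passing_bablok(x: np.ndarray, y: np.ndarray, alpha: float) -> IdentityFit:
    n = x.size
    slopes = []
    n_neg1 = 0
    for i in range(n - 1):
        dx = x[i + 1 :] - x[i]
        dy = y[i + 1 :] - y[i]
        ok = dx != 0
        s = dy[ok] / dx[ok]
        n_neg1 += int(np.sum(s == -1.0))
        slopes.extend(s[s != -1.0])
    slopes = np.sort(np.asarray(slopes))
    n_slopes = slopes.size
    if n_slopes == 0:
        raise NotFittableError("no defined pairwise slopes")
    k = int(np.sum(slopes < -1.0))
    if n_slopes % 2:
        b = slopes[k + (n_slopes + 1) // 2 - 1]
    else:
        b = 0.5 * (slopes[k + n_slopes // 2 - 1] + slopes[min(k + n_slopes // 2, n_slopes - 1)])
    z = stats.norm.ppf(1 - alpha / 2)
    w = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = max(int(round((n_slopes - w) / 2.0)), 1)
    m2 = n_slopes - m1 + 1
    b_lo = slopes[max(m1 + k - 1, 0)]
    b_hi = slopes[min(m2 + k - 1, n_slopes - 1)]
    a = float(np.median(y - b * x))
    a_lo = float(np.median(y - b_hi * x))
    a_hi = float(np.median(y - b_lo * x))
    return IdentityFit(
        slope=float(b),
        slope_ci=(float(b_lo), float(b_hi)),
        intercept=a,
        intercept_ci=(a_lo, a_hi),
        n=n,
        method="passing_bablok",
    )


def identity_line_fit(
    measured: Sequence[float],
    predicted: Sequence[float],
    method: Literal["ols", "passing_bablok"] = "ols",
    alpha: float = 0.05,
) -> IdentityFit:
    """Fit predicted = a + b * measured and test compatibility with a=0, b=1.

    Default is ordinary least squares with (1-alpha) confidence intervals;
    ``method="passing_bablok"`` gives the nonparametric method-comparison
    regression instead.
    """
    x = np.asarray(measured, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("measured and predicted must be 1-D and equal length")
    if x.size < 3:
        raise InputError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise NotFittableError("measured values have zero variance")
    if method == "passing_bablok":
        return _passing_bablok(x, y, alpha)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=alpha)
    # pad the intervals by a float-precision margin so an exact fit
    # (zero residual variance) still registers as identity-compatible
    s_eps = 1e-9
    i_eps = 1e-9 * max(float(np.max(np.abs(y))), 1.0)
    return IdentityFit(
        slope=float(res.params[1]),
        slope_ci=(float(ci[1][0]) - s_eps, float(ci[1][1]) + s_eps),
        intercept=float(res.params[0]),
        intercept_ci=(float(ci[0][0]) - i_eps, float(ci[0][1]) + i_eps),
        n=int(x.size),
        method="ols",
    )


def spike_recovery(
    added_pg_ml: float, endogenous_total_pg_ml: float, measured_total_after_heating_pg_ml: float
) -> float:
    """Fraction of the expected (added + endogenous) total recovered after heating."""
    expected = added_pg_ml + endogenous_total_pg_ml
    if expected <= 0:
        raise InputError("added + endogenous total must be positive")
    return measured_total_after_heating_pg_ml / expected
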