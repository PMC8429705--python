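"""Hedges g standardized effect size with small-sample correction and CIs.

Compares two group means by scaling their difference by the pooled (n-1)
standard deviation, then applies the small-sample bias correction
J = 1 - 3/(4*df - 1) with df = n1 + n2 - 2 (the convention of the
effect-size literature; the exact gamma-ratio J is available behind a
flag and differs by <0.1% at the group sizes seen here). Confidence
intervals invert the noncentral t distribution by default; a normal
approximation is available for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DataError, InputError


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float  # sample SD, n-1 denominator

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InputError("a group needs n >= 2 for a sample SD")
        if self.sd < 0:
            raise InputError("sd must be >= 0")


def group_summary(values: Sequence[float]) -> GroupSummary:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InputError("need at least 2 values per group")
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()),
                        sd=float(arr.std(ddof=1)))


@dataclass(frozen=True)
class EffectSizeResult:
    group1: GroupSummary
    group2: GroupSummary
    pooled_sd: float
    d: float  # uncorrected standardized mean difference
    J: float  # small-sample correction factor, in (0, 1)
    g: float  # J * d
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_level: Optional[float] = None
    ci_method: Optional[str] = None

    @property
    def df(self) -> int:
        return self.group1.n + self.group2.n - 2

    def summary(self) -> str:
        lines = [
            "Hedges g effect size",
            f"  group 1: n={self.group1.n}, mean={self.group1.mean:.2f}, "
            f"sd={self.group1.sd:.2f}",
            f"  group 2: n={self.group2.n}, mean={self.group2.mean:.2f}, "
            f"sd={self.group2.sd:.2f}",
            f"  mean difference: {self.group1.mean - self.group2.mean:.2f}",
            f"  pooled sd: {self.pooled_sd:.2f}",
            f"  d = {self.d:.3f}, J = {self.J:.4f}, g = {self.g:.1f}",
        ]
        if self.ci_low is not None:
            lines.append(
                f"  {100 * self.ci_level:.0f}% CI ({self.ci_method}): "
                f"{self.ci_low:.1f} to {self.ci_high:.1f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        row = {
            "n1": self.group1.n, "mean1": self.group1.mean, "sd1": self.group1.sd,
            "n2": self.group2.n, "mean2": self.group2.mean, "sd2": self.group2.sd,
            "pooled_sd": self.pooled_sd, "d": self.d, "J": self.J, "g": self.g,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "ci_level": self.ci_level, "ci_method": self.ci_method,
        }
        return pd.DataFrame([row])


def _exact_J(df: int) -> float:
    return math.exp(
        math.lgamma(df / 2) - math.log(math.sqrt(df / 2)) - math.lgamma((df - 1) / 2)
    )


def hedges_g(
    g1: GroupSummary, g2: GroupSummary, exact_correction: bool = False
) -> EffectSizeResult:
    """Hedges g for two summarized groups (no CI yet; see :func:`ci_hedges_g`)."""
    n1, n2 = g1.n, g2.n
    df = n1 + n2 - 2
    pooled = math.sqrt(((n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2) / df)
    if pooled == 0:
        if g1.mean != g2.mean:
            raise DataError(
                "pooled SD is zero with unequal means: effect size undefined"
            )
        d = 0.0
    else:
        d = (g1.mean - g2.mean) / pooled
    J = _exact_J(df) if exact_correction else 1 - 3 / (4 * df - 1)
    return EffectSizeResult(group1=g1, group2=g2, pooled_sd=pooled, d=d, J=J, g=J * d)


def _nct_inverse_nc(t_obs: float, df: int, prob: float) -> float:
    """Noncentrality lambda with P(T_{df,lambda} <= t_obs) = prob."""

    def f(nc: float) -> float:
        return stats.nct.cdf(t_obs, df, nc) - prob

    lo, hi = t_obs - 2.0, t_obs + 2.0
    # cdf decreases in nc; expand the bracket until it straddles the root
    for _ in range(60):
        if f(lo) > 0 and f(hi) < 0:
            break
        if f(lo) <= 0:
            lo -= 2.0
        if f(hi) >= 0:
            hi += 2.0
    return optimize.brentq(f, lo, hi, xtol=1e-12)


def ci_hedges_g(
    result: EffectSizeResult, level: float = 0.95, method: str = "noncentral_t"
) -> EffectSizeResult:
    """Attach a confidence interval for g to an effect-size result.

    ``noncentral_t`` (default): the observed t statistic is
    ``t = d * sqrt(n1*n2/(n1+n2))``; the CI inverts the noncentral t
    distribution for its noncentrality parameter at the two tail
    probabilities and rescales the bounds to the g scale (times J).
    ``normal_approx``: ``g +/- z * sqrt((n1+n2)/(n1*n2) + g^2/(2(n1+n2)))``.
    """
    if not 0 < level < 1:
        raise InputError("level must lie in (0, 1)")
    n1, n2 = result.group1.n, result.group2.n
    if method == "noncentral_t":
        scale = math.sqrt(n1 * n2 / (n1 + n2))
        t_obs = result.d * scale
        alpha = 1 - level
        nc_low = _nct_inverse_nc(t_obs, result.df, 1 - alpha / 2)
        nc_high = _nct_inverse_nc(t_obs, result.df, alpha / 2)
        lo, hi = result.J * nc_low / scale, result.J * nc_high / scale
    elif method == "normal_approx":
        g = result.g
        se = math.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2 * (n1 + n2)))
        z = stats.norm.ppf(1 - (1 - level) / 2)
        lo, hi = g - z * se, g + z * se
    else:
        raise InputError("method must be 'noncentral_t' or 'normal_approx'")
    return replace(result, ci_low=lo, ci_high=hi, ci_level=level, ci_method=method)


def compare_species_sets(
    counts: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    level: float = 0.95,
    method: str = "noncentral_t",
) -> EffectSizeResult:
    """Table-3-style workflow: total domain counts per species, then Hedges g.

    ``counts`` is a species x domain count table; each species' repertoire
    size is the row sum over domain columns, the two groups are summarized,
    and g with its CI is computed (group1 minus group2).
    """
    missing = [s for s in [*group1, *group2] if s not in counts.index]
    if missing:
        raise InputError(f"species not in count table: {missing}")
    overlap = set(group1) & set(group2)
    if overlap:
        raise InputError(f"groups overlap: {sorted(overlap)}")
    totals = counts.sum(axis=1)
    res = hedges_g(
        group_summary(totals.loc[list(group1)].to_numpy()),
        group_summary(totals.loc[list(group2)].to_numpy()),
    )
    return ci_hedges_g(res, level=level, method=method)
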