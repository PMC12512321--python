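"""Analytic design calculations for two independent proportions.

The chi-square-based (pooled-variance) normal approximation for the
per-arm sample size of a two-sided test of p0 vs p1:

    n = ( z_{1-a/2} * sqrt(2*pbar*qbar) + z_{1-b} * sqrt(p0*q0 + p1*q1) )^2
        / (p0 - p1)^2,        pbar = (p0 + p1)/2

rounded up to an integer per arm.  The optional Fleiss continuity
correction inflates the uncorrected real-valued n before the ceiling:

    n' = (n/4) * (1 + sqrt(1 + 4 / (n*|p0 - p1|)))^2

For the default design inputs (10% vs 4% event rates, two-sided 0.045,
80% power, no correction) the uncorrected formula gives 292 per arm, 584
in total — the effect size being equivalent to an odds ratio of 0.375.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["SampleSizeResult", "two_proportion_n", "odds_ratio_from_props"]


@dataclass(frozen=True)
class SampleSizeResult:
    """Per-arm and total sample size with the inputs that produced them."""

    n_per_arm: int
    n_total: int
    p0: float
    p1: float
    alpha: float
    power: float
    continuity_correction: bool


def two_proportion_n(
    p0: float,
    p1: float,
    alpha: float = 0.05,
    power: float = 0.80,
    continuity_correction: bool = False,
) -> SampleSizeResult:
    """Per-arm sample size to detect p0 vs p1 with a two-sided chi-square test.

    Parameters
    ----------
    p0, p1
        True event probabilities in the two arms, both in (0, 1) and
        distinct (equal probabilities would need an infinite trial).
    alpha
        Two-sided significance level.
    power
        Target power (1 - beta).
    continuity_correction
        Apply the Fleiss adjustment before rounding up.
    """
    for label, v in (("p0", p0), ("p1", p1), ("alpha", alpha), ("power", power)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{label} must lie in the open interval (0, 1)")
    if p0 == p1:
        raise ValueError("p0 and p1 must differ (required sample size is infinite)")

    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    pbar = (p0 + p1) / 2.0
    qbar = 1.0 - pbar
    num = z_a * math.sqrt(2.0 * pbar * qbar) + z_b * math.sqrt(
        p0 * (1.0 - p0) + p1 * (1.0 - p1)
    )
    n_real = (num / (p0 - p1)) ** 2
    if continuity_correction:
        n_real = (n_real / 4.0) * (1.0 + math.sqrt(1.0 + 4.0 / (n_real * abs(p0 - p1)))) ** 2
    n_per_arm = math.ceil(n_real)
    return SampleSizeResult(
        n_per_arm=n_per_arm,
        n_total=2 * n_per_arm,
        p0=p0,
        p1=p1,
        alpha=alpha,
        power=power,
        continuity_correction=continuity_correction,
    )


def odds_ratio_from_props(p0: float, p1: float) -> float:
    """Odds ratio (treatment vs control) implied by two event probabilities."""
    for label, p in (("p0", p0), ("p1", p1)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{label} must lie strictly inside (0, 1)")
    return (p1 / (1.0 - p1)) / (p0 / (1.0 - p0))
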