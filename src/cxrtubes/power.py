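"""Sample-size calculation for detecting an AUC above a null value.

Uses the Hanley-McNeil variance of a ROC AUC estimated from n_pos positive
and n_neg negative cases:

    V(A) = [ A(1-A) + (n_pos-1)(Q1 - A^2) + (n_neg-1)(Q2 - A^2) ]
           / (n_pos * n_neg),
    Q1 = A / (2 - A),       Q2 = 2 A^2 / (1 + A).

The study design question is the smallest case count for which a two-sided
level-alpha test of H0: AUC = auc_null rejects with the target power when
the true AUC is auc_alt, at a fixed prevalence of the rarer (positive)
class.  Achieved power is the normal approximation

    Phi( (A1 - A0 - z_{1-alpha/2} * sqrt(V0)) / sqrt(V1) ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

from scipy.stats import norm


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for the AUC sample-size calculation."""

    auc_alt: float
    auc_null: float
    alpha: float = 0.05
    power: float = 0.8
    positive_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0.5 <= self.auc_null < self.auc_alt < 1.0):
            raise ValueError("require 0.5 <= auc_null < auc_alt < 1")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise ValueError("alpha and power must lie in (0, 1)")
        if not (0.0 < self.positive_fraction < 0.5):
            raise ValueError("positive_fraction must be in (0, 0.5)")


def hanley_mcneil_variance(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil variance of an empirical AUC."""
    if not (0.0 < auc < 1.0):
        raise ValueError(f"AUC must be in (0, 1), got {auc}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    return (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)


def achieved_power(spec: PowerSpec, n_pos: int, n_neg: int) -> float:
    """Power of the two-sided level-alpha test at the given group sizes."""
    z_alpha = norm.ppf(1.0 - spec.alpha / 2.0)
    v0 = hanley_mcneil_variance(spec.auc_null, n_pos, n_neg)
    v1 = hanley_mcneil_variance(spec.auc_alt, n_pos, n_neg)
    z = (spec.auc_alt - spec.auc_null - z_alpha * math.sqrt(v0)) / math.sqrt(v1)
    return float(norm.cdf(z))


def auc_sample_size(
    spec: PowerSpec, max_n_pos: int = 10000
) -> Tuple[int, int, int]:
    """Smallest (n_pos, n_neg, n_total) reaching the target power.

    The negative:positive ratio is fixed at (1 - p) / p, rounded to the
    nearest integer count per positive; n_pos is incremented until the
    achieved power reaches the target.
    """
    ratio = (1.0 - spec.positive_fraction) / spec.positive_fraction
    for n_pos in range(1, max_n_pos + 1):
        n_neg = max(1, round(n_pos * ratio))
        if achieved_power(spec, n_pos, n_neg) >= spec.power:
            return n_pos, n_neg, n_pos + n_neg
    raise ValueError(
        f"no n_pos <= {max_n_pos} reaches power {spec.power}; "
        "the alternative AUC may be too close to the null"
    )
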