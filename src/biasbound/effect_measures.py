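"""Effect-measure types and conversions onto the risk-ratio scale.

Downstream stages (meta-analysis pooling, E-values, bounding factors)
operate exclusively on risk ratios.  This module houses the container
for a relative-scale effect estimate and the standard conversions:

* odds ratio -> risk ratio given the baseline (unexposed) outcome risk
  ``p0``:  ``RR = OR / (1 - p0 + p0 * OR)``;
* hazard ratio -> risk ratio, either a rare-outcome passthrough or the
  common-outcome approximation
  ``RR = (1 - 0.5**sqrt(HR)) / (1 - 0.5**sqrt(1/HR))``;
* Pearson correlation -> odds ratio via the standardized-mean-difference
  chain ``d = 2r / sqrt(1 - r**2)``, ``log OR = pi * d / sqrt(3)``;
* 95% (or other level) confidence limits -> standard error of the log
  effect.

All conversions are exact-arithmetic on full precision; rounding for
display is the report layer's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

from scipy.stats import norm

__all__ = [
    "Measure",
    "EffectEstimate",
    "COMMON_OUTCOME_THRESHOLD",
    "or_to_rr",
    "hr_to_rr",
    "r_to_or",
    "se_from_ci",
    "to_rr_scale",
]

#: Outcome proportion above which an outcome counts as "common", so that
#: OR and HR are no longer acceptable approximations to the RR.
COMMON_OUTCOME_THRESHOLD = 0.15


class Measure(str, Enum):
    """Relative effect scale of an estimate."""

    RR = "rr"
    OR = "or"
    HR = "hr"


@dataclass(frozen=True)
class EffectEstimate:
    """An exposure-outcome association on a relative scale with its 95% CI.

    Parameters
    ----------
    measure
        Scale of ``point`` and the CI limits: risk ratio, odds ratio or
        hazard ratio.
    point, ci_lower, ci_upper
        Point estimate and confidence limits, all strictly positive with
        ``ci_lower <= point <= ci_upper``.
    outcome_prevalence
        Baseline risk ``p0`` (outcome probability in the reference
        group), required to convert an OR for a common outcome.
    rare_outcome
        True when the outcome proportion is at or below
        :data:`COMMON_OUTCOME_THRESHOLD`, in which case OR and HR are
        taken as interchangeable with RR.
    """

    measure: Measure
    point: float
    ci_lower: float
    ci_upper: float
    outcome_prevalence: float | None = None
    rare_outcome: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "measure", Measure(self.measure))
        if not (self.ci_lower > 0 and self.point > 0 and self.ci_upper > 0):
            raise ValueError("effect estimate and CI limits must be positive")
        if not (self.ci_lower <= self.point <= self.ci_upper):
            raise ValueError(
                f"require ci_lower <= point <= ci_upper, got "
                f"({self.ci_lower}, {self.point}, {self.ci_upper})"
            )
        if self.outcome_prevalence is not None and not (0 < self.outcome_prevalence < 1):
            raise ValueError("outcome_prevalence must lie strictly in (0, 1)")


def or_to_rr(or_value: float, p0: float) -> float:
    """Convert an odds ratio to a risk ratio given the baseline risk ``p0``.

    ``RR = OR / (1 - p0 + p0 * OR)``.  As ``p0 -> 0`` the RR tends to
    the OR (rare-outcome limit); for ``OR > 1`` the result lies between
    1 and the OR.
    """
    if or_value <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    if not (0 < p0 < 1):
        raise ValueError(f"baseline risk p0 must lie in (0, 1), got {p0}")
    return or_value / (1.0 - p0 + p0 * or_value)


def hr_to_rr(hr: float, rare_outcome: bool) -> float:
    """Convert a hazard ratio to a risk ratio.

    With a rare outcome the HR approximates the RR and is passed
    through.  Otherwise the common-outcome approximation
    ``RR = (1 - 0.5**sqrt(HR)) / (1 - 0.5**sqrt(1/HR))`` is applied,
    which shrinks the HR toward the null.
    """
    if hr <= 0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    if rare_outcome or hr == 1.0:
        return hr
    return (1.0 - 0.5 ** math.sqrt(hr)) / (1.0 - 0.5 ** math.sqrt(1.0 / hr))


def r_to_or(r: float) -> float:
    """Convert a Pearson correlation to an odds ratio.

    Uses the standardized-mean-difference chain: ``d = 2r/sqrt(1-r^2)``
    then ``log OR = pi * d / sqrt(3)`` (the logistic-distribution
    scaling).  The log odds ratio carries the sign of ``r``.
    """
    if not -1.0 < r < 1.0:
        raise ValueError(f"correlation must lie strictly in (-1, 1), got {r}")
    d = 2.0 * r / math.sqrt(1.0 - r * r)
    return math.exp(math.pi * d / math.sqrt(3.0))


def se_from_ci(ci_lower: float, ci_upper: float, level: float = 0.95) -> float:
    """Standard error of the log effect recovered from CI limits.

    ``se = (ln ci_upper - ln ci_lower) / (2 z)`` with ``z`` the
    standard-normal quantile for the confidence level (full precision,
    1.959964... at 95%).
    """
    if not 0 < ci_lower < ci_upper:
        raise ValueError(
            f"require 0 < ci_lower < ci_upper, got ({ci_lower}, {ci_upper})"
        )
    if not 0 < level < 1:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    z = norm.ppf(0.5 + level / 2.0)
    return (math.log(ci_upper) - math.log(ci_lower)) / (2.0 * z)


def to_rr_scale(estimate: EffectEstimate) -> EffectEstimate:
    """Return the estimate converted to the risk-ratio scale.

    The matching conversion is applied to the point estimate and both
    confidence limits.  RR inputs are returned unchanged.  Converting a
    common-outcome OR requires ``outcome_prevalence``; an OR flagged
    ``rare_outcome`` passes through (OR ~ RR in the rare-outcome limit).
    """
    if estimate.measure is Measure.RR:
        return estimate
    if estimate.measure is Measure.HR:
        convert = lambda x: hr_to_rr(x, estimate.rare_outcome)  # noqa: E731
    else:  # OR
        if estimate.rare_outcome and estimate.outcome_prevalence is None:
            convert = lambda x: x  # noqa: E731
        elif estimate.outcome_prevalence is not None:
            p0 = estimate.outcome_prevalence
            convert = lambda x: or_to_rr(x, p0)  # noqa: E731
        else:
            raise ValueError(
                "converting an OR requires outcome_prevalence (p0) or the "
                "rare_outcome flag"
            )
    return replace(
        estimate,
        measure=Measure.RR,
        point=convert(estimate.point),
        ci_lower=convert(estimate.ci_lower),
        ci_upper=convert(estimate.ci_upper),
    )
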