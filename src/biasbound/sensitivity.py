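"""E-values, the joint bounding factor, and confounding-plausibility analysis.

The E-value of an observed risk ratio RR >= 1 is

    E = RR + sqrt(RR * (RR - 1)),

the minimum strength of association (risk-ratio scale) that an
unmeasured confounder would need with *both* exposure and outcome to
fully explain the association.  A confounder of known strengths is
assessed through the joint bounding factor

    B = (RR_UD * RR_EU) / (RR_UD + RR_EU - 1),

the maximum multiplicative bias it can induce in the observed RR, where
RR_UD is the confounder-outcome and RR_EU the confounder-exposure
association.  B >= RR_obs means the confounder could account for the
whole association ("total" confounding); otherwise it explains
100 * (B - 1) / (RR_obs - 1) percent of the excess relative risk.

Protective estimates (RR < 1) are handled by taking reciprocals before
applying the formulas, since all quantities are defined on the >= 1
side of the null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from biasbound.meta import MetaResult

__all__ = [
    "EValueResult",
    "ConfounderScenario",
    "BoundingResult",
    "BoundingCurve",
    "evalue_point",
    "invert_evalue",
    "evalue_ci",
    "evalue",
    "bounding_factor",
    "proportion_explained",
    "required_complementary_rr",
    "analyse_scenario",
    "bounding_curve",
]


@dataclass(frozen=True)
class EValueResult:
    """E-values for a point estimate and the CI limit closer to the null."""

    e_point: float
    e_ci: float
    rr_used: float

    def to_dict(self) -> dict:
        return {"e_point": self.e_point, "e_ci": self.e_ci, "rr_used": self.rr_used}


@dataclass(frozen=True)
class ConfounderScenario:
    """A named hypothetical confounder, pre-oriented to the >= 1 side.

    ``rr_eu`` is the confounder-exposure association and ``rr_ud`` the
    confounder-outcome association, both on the risk-ratio scale.
    """

    name: str
    rr_eu: float
    rr_ud: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.rr_eu < 1 or self.rr_ud < 1:
            raise ValueError(
                f"scenario '{self.name}': rr_eu and rr_ud must be >= 1 "
                "(orient associations away from the null first)"
            )


@dataclass(frozen=True)
class BoundingResult:
    """Outcome of confronting one confounder scenario with a pooled estimate."""

    scenario: ConfounderScenario
    b: float
    proportion_explained_point: float
    proportion_explained_lower_ci: float
    fully_explains_point: bool
    fully_explains_lower_ci: bool
    required_rr_eu_for_total: float | None

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.name,
            "rr_eu": self.scenario.rr_eu,
            "rr_ud": self.scenario.rr_ud,
            "b": self.b,
            "proportion_explained_point": self.proportion_explained_point,
            "proportion_explained_lower_ci": self.proportion_explained_lower_ci,
            "fully_explains_point": self.fully_explains_point,
            "fully_explains_lower_ci": self.fully_explains_lower_ci,
            "required_rr_eu_for_total": (
                self.required_rr_eu_for_total
                if self.required_rr_eu_for_total is not None
                else "unattainable"
            ),
        }


@dataclass(frozen=True)
class BoundingCurve:
    """Sampled contour ``B(rr_ud, rr_eu) = target_b``.

    Points are ordered by increasing ``rr_ud``; ``rr_eu`` decreases
    monotonically along the curve toward the ``rr_eu = target_b``
    asymptote.  The symmetric point ``rr_ud = rr_eu`` equals the E-value
    of the RR whose total-confounding bound is ``target_b`` and is
    always included.
    """

    target_b: float
    points: tuple[tuple[float, float], ...]


def _orient(rr: float) -> float:
    """Map a relative risk to the harmful (>= 1) side of the null."""
    if rr <= 0:
        raise ValueError(f"risk ratio must be positive, got {rr}")
    return rr if rr >= 1.0 else 1.0 / rr


def evalue_point(rr: float) -> float:
    """E-value of a risk ratio: ``E = RR + sqrt(RR * (RR - 1))``.

    Protective estimates are reciprocated first, so the result is always
    >= 1 and equals 1 exactly at the null.
    """
    r = _orient(rr)
    return r + math.sqrt(r * (r - 1.0))


def invert_evalue(e: float) -> float:
    """The risk ratio (>= 1) whose E-value equals ``e``.

    Closed form ``RR = E^2 / (2E - 1)``, the inverse of
    :func:`evalue_point` on the harmful side.
    """
    if e < 1.0:
        raise ValueError(f"an E-value cannot be below 1, got {e}")
    return e * e / (2.0 * e - 1.0)


def evalue_ci(rr_point: float, ci_lower: float, ci_upper: float) -> float:
    """E-value of the confidence limit closer to the null.

    Uses the lower limit for harmful estimates and the reciprocal of the
    upper limit for protective ones; an interval that contains the null
    needs no confounding to be explained, so the E-value is exactly 1.
    """
    if not ci_lower <= rr_point <= ci_upper:
        raise ValueError(
            f"require ci_lower <= point <= ci_upper, got "
            f"({ci_lower}, {rr_point}, {ci_upper})"
        )
    if ci_lower <= 1.0 <= ci_upper:
        return 1.0
    limit = ci_lower if rr_point >= 1.0 else ci_upper
    return evalue_point(limit)


def evalue(rr_point: float, ci_lower: float, ci_upper: float) -> EValueResult:
    """E-values for a point estimate and its CI, as one result object."""
    return EValueResult(
        e_point=evalue_point(rr_point),
        e_ci=evalue_ci(rr_point, ci_lower, ci_upper),
        rr_used=rr_point,
    )


def bounding_factor(rr_ud: float, rr_eu: float) -> float:
    """Joint bounding factor ``B = RR_UD * RR_EU / (RR_UD + RR_EU - 1)``.

    Symmetric in its arguments, bounded above by the smaller of the two,
    and equal to 1 whenever either association is null: a confounder
    unrelated to exposure or to outcome cannot bias at all.
    """
    if rr_ud < 1 or rr_eu < 1:
        raise ValueError(
            f"bounding factor requires rr_ud >= 1 and rr_eu >= 1, got "
            f"({rr_ud}, {rr_eu}); orient the scenario first"
        )
    return rr_ud * rr_eu / (rr_ud + rr_eu - 1.0)


def proportion_explained(rr_obs: float, b: float) -> float:
    """Percent of the excess relative risk a bounding factor can explain.

    ``100 * (B - 1) / (RR_obs - 1)``, capped at 100.  A null or
    protective observed RR has no harmful excess to explain and returns
    0 with a warning.
    """
    if b < 1:
        raise ValueError(f"bounding factor must be >= 1, got {b}")
    if rr_obs <= 1.0:
        warnings.warn(
            f"observed RR {rr_obs} is not above the null: nothing to explain",
            stacklevel=2,
        )
        return 0.0
    return min(100.0, 100.0 * (b - 1.0) / (rr_obs - 1.0))


def required_complementary_rr(rr_known: float, rr_obs_target: float) -> float | None:
    """Confounder strength needed on the other axis for total confounding.

    Solves ``B(rr_known, x) = rr_obs_target`` for ``x``:

        x = rr_obs_target * (rr_known - 1) / (rr_known - rr_obs_target).

    Because ``B <= min(RR_UD, RR_EU)``, no finite ``x`` exists when
    ``rr_known <= rr_obs_target``; ``None`` signals "unattainable".
    """
    if rr_obs_target <= 1.0:
        raise ValueError(f"target observed RR must exceed 1, got {rr_obs_target}")
    if rr_known < 1.0:
        raise ValueError(f"known association must be >= 1, got {rr_known}")
    if rr_known <= rr_obs_target:
        return None
    return rr_obs_target * (rr_known - 1.0) / (rr_known - rr_obs_target)


def analyse_scenario(scenario: ConfounderScenario, meta: MetaResult) -> BoundingResult:
    """Assess how much of a pooled association one scenario could explain.

    Computes the scenario's bounding factor and the proportion of the
    excess relative risk explained against both the pooled point
    estimate and the CI limit closer to the null, plus flags for total
    confounding (``B >= RR``) and the confounder-exposure strength that
    total confounding of the point estimate would require given the
    scenario's ``rr_ud``.
    """
    b = bounding_factor(scenario.rr_ud, scenario.rr_eu)
    rr_point = meta.pooled_rr
    rr_null_side = meta.ci_lower if rr_point >= 1.0 else meta.ci_upper

    if rr_point <= 1.0:
        warnings.warn(
            f"pooled RR {rr_point:.4f} is not above the null; scenario "
            f"'{scenario.name}' proportions reported as 0",
            stacklevel=2,
        )
        prop_point = prop_ci = 0.0
        required = None
    else:
        prop_point = proportion_explained(rr_point, b)
        prop_ci = proportion_explained(rr_null_side, b) if rr_null_side > 1.0 else 100.0
        required = required_complementary_rr(scenario.rr_ud, rr_point)

    return BoundingResult(
        scenario=scenario,
        b=b,
        proportion_explained_point=prop_point,
        proportion_explained_lower_ci=prop_ci,
        fully_explains_point=b >= rr_point > 1.0,
        fully_explains_lower_ci=rr_point > 1.0 and (rr_null_side <= 1.0 or b >= rr_null_side),
        required_rr_eu_for_total=required,
    )


def bounding_curve(
    target_b: float, n_points: int = 200, rr_ud_max: float | None = None
) -> BoundingCurve:
    """Sample the contour of (RR_UD, RR_EU) pairs with bounding factor ``target_b``.

    ``rr_ud`` is log-spaced on ``(target_b, rr_ud_max]`` (dense near the
    asymptote where ``rr_eu`` diverges); each ``rr_eu`` comes from the
    closed-form :func:`required_complementary_rr`.  The symmetric point
    ``(E, E)`` with ``E = evalue_point(target_b)`` — the E-value marker
    of the contour — is inserted explicitly.
    """
    if target_b <= 1.0:
        raise ValueError(f"target bounding factor must exceed 1, got {target_b}")
    if rr_ud_max is None:
        rr_ud_max = 10.0 * target_b
    if rr_ud_max <= target_b:
        raise ValueError(
            f"rr_ud_max ({rr_ud_max}) must exceed the target bounding factor "
            f"({target_b}): the contour has a vertical asymptote there"
        )
    if n_points < 2:
        raise ValueError("need at least 2 curve points")

    # Open at the asymptote: drop the first node of an (n+1)-point
    # log-spaced grid so every rr_ud is strictly above target_b.
    grid = np.geomspace(target_b, rr_ud_max, n_points + 1)[1:]
    e_sym = evalue_point(target_b)
    rr_ud_values = np.unique(np.append(grid, e_sym))
    pts = []
    for ud in rr_ud_values:
        eu = required_complementary_rr(float(ud), target_b)
        if eu is not None:
            pts.append((float(ud), eu))
    return BoundingCurve(target_b=target_b, points=tuple(pts))
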