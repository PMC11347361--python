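"""Synthetic-data generators with known ground truth.

Two generators mirror the two statistical structures the pipeline
assumes:

* ``generate_meta_sample`` draws study-level log risk ratios from the
  normal-normal random-effects model (true pooled effect ``theta``,
  between-study variance ``tau^2``, per-study sampling error), so the
  REML pooling stage can be checked by parameter recovery;
* ``generate_confounded_cohort`` draws an individual-level cohort with
  a binary unmeasured confounder U of specified strengths, using a
  log-linear (risk-ratio) parameterization so the generative parameters
  are exactly the RR_EU / RR_UD the bounding factor consumes — the
  crude (U-collapsed) risk ratio is then provably bounded by
  ``true_rr * B(rr_ud, rr_eu)``.

Seeds are explicit; identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from biasbound.effect_measures import EffectEstimate, Measure
from scipy.stats import norm

__all__ = [
    "MetaSimConfig",
    "CohortSimConfig",
    "SyntheticCohort",
    "generate_meta_sample",
    "generate_confounded_cohort",
    "crude_rr",
    "stratified_rr",
    "cohort_to_long_table",
]


@dataclass(frozen=True)
class MetaSimConfig:
    """Configuration for the study-level generator.

    ``theta`` is the true pooled log risk ratio, ``tau2`` the true
    between-study variance; each study's standard error is drawn
    uniformly from ``se_range``.
    """

    k: int
    theta: float
    tau2: float
    se_range: tuple[float, float] = (0.05, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("need at least one study")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        lo, hi = self.se_range
        if not (0 < lo <= hi):
            raise ValueError(f"se_range bounds must be positive and ordered, got {self.se_range}")


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration for the confounded-cohort generator.

    Risk-ratio parameterization: P(exposed | U=u) =
    ``p_exposure_base * rr_eu**u`` and P(outcome | U=u, E=e) =
    ``p_outcome_base * rr_ud**u * true_rr**e``.  All implied cell
    probabilities must stay below 1.
    """

    n: int
    p_u: float = 0.2
    rr_eu: float = 1.0
    rr_ud: float = 1.0
    true_rr: float = 1.0
    p_exposure_base: float = 0.2
    p_outcome_base: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be positive")
        if not 0 < self.p_u < 1:
            raise ValueError("confounder prevalence p_u must lie in (0, 1)")
        if self.rr_eu < 1 or self.rr_ud < 1:
            raise ValueError("rr_eu and rr_ud must be >= 1")
        if self.true_rr <= 0:
            raise ValueError("true_rr must be positive")
        p_exp_max = self.p_exposure_base * self.rr_eu
        if not 0 < p_exp_max < 1:
            raise ValueError(
                f"exposure probability p_exposure_base * rr_eu = {p_exp_max:.4g} "
                "must lie in (0, 1)"
            )
        p_out_max = self.p_outcome_base * self.rr_ud * max(1.0, self.true_rr)
        if not 0 < p_out_max < 1:
            raise ValueError(
                f"outcome probability p_outcome_base * rr_ud * true_rr = "
                f"{p_out_max:.4g} must lie in (0, 1)"
            )


@dataclass(frozen=True)
class SyntheticCohort:
    """A 2x2x2 count table indexed (U, exposure, outcome)."""

    counts: np.ndarray
    config: CohortSimConfig

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (2, 2, 2) or np.any(counts < 0):
            raise ValueError("counts must be a non-negative 2x2x2 table")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def generate_meta_sample(config: MetaSimConfig) -> list[tuple[float, float]]:
    """Draw ``k`` study-level (log RR, se) pairs under the random-effects model."""
    rng = np.random.default_rng(config.seed)
    se = rng.uniform(config.se_range[0], config.se_range[1], size=config.k)
    mu = rng.normal(config.theta, math.sqrt(config.tau2), size=config.k)
    y = rng.normal(mu, se)
    return list(zip(y.tolist(), se.tolist()))


def generate_confounded_cohort(config: CohortSimConfig) -> SyntheticCohort:
    """Sample a cohort with a binary unmeasured confounder.

    U ~ Bernoulli(p_u); exposure ~ Bernoulli(p_exposure_base * rr_eu^U);
    outcome ~ Bernoulli(p_outcome_base * rr_ud^U * true_rr^exposure).
    """
    rng = np.random.default_rng(config.seed)
    u = rng.binomial(1, config.p_u, size=config.n)
    p_e = config.p_exposure_base * config.rr_eu**u
    e = rng.binomial(1, p_e)
    p_d = config.p_outcome_base * config.rr_ud**u * config.true_rr**e
    d = rng.binomial(1, p_d)
    idx = u * 4 + e * 2 + d
    counts = np.bincount(idx, minlength=8).reshape(2, 2, 2)
    return SyntheticCohort(counts=counts, config=config)


def _collapsed_2x2(cohort: SyntheticCohort) -> tuple[float, float, float, float]:
    """(a, b, c, d) = exposed cases/non-cases, unexposed cases/non-cases."""
    t = cohort.counts.sum(axis=0)  # collapse over U -> (exposure, outcome)
    return float(t[1, 1]), float(t[1, 0]), float(t[0, 1]), float(t[0, 0])


def _rr_from_2x2(
    a: float, b: float, c: float, d: float, level: float = 0.95
) -> EffectEstimate:
    if a + b == 0 or c + d == 0:
        raise ValueError("both exposure margins must be non-empty")
    if min(a, c) == 0:
        warnings.warn(
            "zero case count in one exposure group: applying a 0.5 continuity "
            "correction to all cells",
            stacklevel=3,
        )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    rr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    z = norm.ppf(0.5 + level / 2.0)
    return EffectEstimate(
        measure=Measure.RR,
        point=rr,
        ci_lower=rr * math.exp(-z * se),
        ci_upper=rr * math.exp(z * se),
    )


def crude_rr(cohort: SyntheticCohort, level: float = 0.95) -> EffectEstimate:
    """Crude (confounder-collapsed) risk ratio with a log-scale Wald CI.

    A zero case count in either exposure group triggers a flagged 0.5
    continuity correction on all four cells.
    """
    a, b, c, d = _collapsed_2x2(cohort)
    return _rr_from_2x2(a, b, c, d, level)


def stratified_rr(cohort: SyntheticCohort) -> tuple[float | None, float | None]:
    """Risk ratio within each confounder stratum (U=0, U=1).

    Within strata the generator's exposure-outcome effect is exactly
    ``true_rr``, so each stratum RR converges to it as n grows.  A
    degenerate stratum (an empty exposure margin) yields None with a
    warning instead of an estimate.
    """
    out: list[float | None] = []
    for u in (0, 1):
        t = cohort.counts[u]
        a, b, c, d = float(t[1, 1]), float(t[1, 0]), float(t[0, 1]), float(t[0, 0])
        if a + b == 0 or c + d == 0:
            warnings.warn(f"stratum U={u} has an empty exposure margin; omitted", stacklevel=2)
            out.append(None)
        else:
            out.append(_rr_from_2x2(a, b, c, d).point)
    return out[0], out[1]


def cohort_to_long_table(cohort: SyntheticCohort):
    """Cohort counts as an 8-row long-format DataFrame (u, exposed, outcome, count)."""
    import pandas as pd

    rows = [
        {"u": u, "exposed": e, "outcome": d, "count": int(cohort.counts[u, e, d])}
        for u in (0, 1)
        for e in (0, 1)
        for d in (0, 1)
    ]
    return pd.DataFrame(rows)
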