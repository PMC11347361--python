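"""Random-effects meta-analysis with a REML between-study variance estimator.

Implements the normal-normal random-effects model for study-level log
risk ratios: each study's observed log RR ``y_i`` is
``N(mu_i, se_i^2)`` with study-specific true effects
``mu_i ~ N(theta, tau^2)``.  The between-study variance ``tau^2`` is
estimated by restricted maximum likelihood and the pooled effect is the
inverse-variance weighted mean with weights ``1/(se_i^2 + tau^2)``.
Confidence intervals are Wald intervals on the log scale.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from biasbound.effect_measures import EffectEstimate, se_from_ci, to_rr_scale

__all__ = ["StudyEstimate", "MetaResult", "fit_random_effects", "pool_by_quantile"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyEstimate:
    """One study x exposure-quantile input row."""

    study_id: str
    quantile: str
    estimate: EffectEstimate
    tag: str | None = None


@dataclass(frozen=True)
class MetaResult:
    """Pooled random-effects estimate with heterogeneity diagnostics.

    ``pooled_log_rr`` and ``se_pooled`` are on the log scale;
    ``ci_lower``/``ci_upper`` are exponentiated back to the RR scale.
    ``q_stat`` is Cochran's Q from fixed-effect weights and ``i2`` the
    derived I-squared proportion.
    """

    k: int
    pooled_log_rr: float
    se_pooled: float
    ci_lower: float
    ci_upper: float
    tau2: float
    q_stat: float
    i2: float
    warnings: tuple[str, ...] = field(default=())

    @property
    def pooled_rr(self) -> float:
        return math.exp(self.pooled_log_rr)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "pooled_rr": self.pooled_rr,
            "pooled_log_rr": self.pooled_log_rr,
            "se_pooled": self.se_pooled,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "tau2": self.tau2,
            "q_stat": self.q_stat,
            "i2": self.i2,
            "warnings": list(self.warnings),
        }


def _restricted_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Negative restricted log-likelihood of the normal-normal model."""
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
    )


def fit_random_effects(
    estimates: Sequence[tuple[float, float]],
    *,
    level: float = 0.95,
    tau2: float | None = None,
) -> MetaResult:
    """Pool (log RR, se) pairs under the random-effects model.

    ``tau^2`` maximises the restricted likelihood over ``[0, inf)`` by
    bounded scalar minimisation; pass ``tau2`` explicitly to fix it
    (``tau2=0`` gives the fixed/common-effect fit).  A single study is
    passed through with ``tau^2 = 0`` and a warning so sparse quantiles
    never crash a batch run.
    """
    if len(estimates) == 0:
        raise ValueError("cannot pool an empty list of estimates")
    y = np.asarray([e[0] for e in estimates], dtype=float)
    se = np.asarray([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    k = len(y)
    v = se**2
    z = norm.ppf(0.5 + level / 2.0)

    notes: list[str] = []
    if k == 1:
        msg = "single-study input: returning the study estimate with tau2=0"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
        theta, se_p, t2 = float(y[0]), float(se[0]), 0.0
        q, i2 = 0.0, 0.0
    else:
        if tau2 is None:
            # Bracket wide enough to hold any plausible optimum: the REML
            # tau2 cannot exceed the raw variance of y by much even when
            # the sampling variances are tiny.
            hi = 10.0 * float(np.max(v) + np.var(y) + 1e-12)
            res = minimize_scalar(
                _restricted_nll,
                bounds=(0.0, hi),
                args=(y, v),
                method="bounded",
                options={"xatol": 1e-10},
            )
            t2 = float(res.x)
            # The bounded optimiser never quite reaches the boundary;
            # snap to 0 when the boundary is at least as good.
            if _restricted_nll(0.0, y, v) <= res.fun:
                t2 = 0.0
        else:
            if tau2 < 0:
                raise ValueError("tau2 must be non-negative")
            t2 = float(tau2)
        w = 1.0 / (v + t2)
        theta = float(np.sum(w * y) / np.sum(w))
        se_p = float(1.0 / math.sqrt(np.sum(w)))
        w_fe = 1.0 / v
        mu_fe = np.sum(w_fe * y) / np.sum(w_fe)
        q = float(np.sum(w_fe * (y - mu_fe) ** 2))
        i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0

    return MetaResult(
        k=k,
        pooled_log_rr=theta,
        se_pooled=se_p,
        ci_lower=math.exp(theta - z * se_p),
        ci_upper=math.exp(theta + z * se_p),
        tau2=t2,
        q_stat=q,
        i2=i2,
        warnings=tuple(notes),
    )


def pool_by_quantile(
    table: Iterable[StudyEstimate],
    reference: str = "Q1",
    *,
    level: float = 0.95,
) -> dict[str, MetaResult]:
    """Run one random-effects meta-analysis per non-reference quantile.

    Each study estimate is converted to the RR scale first; the log RR
    and its standard error (from the CI width) feed the REML fit.  The
    reference quantile is excluded; quantiles with no studies are simply
    absent from the returned mapping.
    """
    rows = list(table)
    seen = Counter((r.study_id, r.quantile) for r in rows)
    dupes = [key for key, n in seen.items() if n > 1]
    if dupes:
        raise ValueError(
            f"duplicate study x quantile rows: {sorted(dupes)}; each study may "
            "contribute at most one estimate per quantile"
        )

    by_quantile: dict[str, list[tuple[float, float]]] = {}
    for row in rows:
        if row.quantile == reference:
            continue
        rr_est = to_rr_scale(row.estimate)
        pair = (math.log(rr_est.point), se_from_ci(rr_est.ci_lower, rr_est.ci_upper, level))
        by_quantile.setdefault(row.quantile, []).append(pair)

    results: dict[str, MetaResult] = {}
    for quantile in sorted(by_quantile):
        results[quantile] = fit_random_effects(by_quantile[quantile], level=level)
        logger.info(
            "pooled quantile %s: k=%d RR=%.4f tau2=%.5g",
            quantile,
            results[quantile].k,
            results[quantile].pooled_rr,
            results[quantile].tau2,
        )
    return results
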