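"""Full-analysis orchestration: study table -> pooling -> E-values -> scenarios.

``run_full_analysis`` ties the stages together: per-quantile REML
meta-analysis of the study table, E-values for the focus quantile
(by default the one with the largest pooled estimate), a bounding
analysis of every confounder scenario against the focus estimate, and
optionally the same pooling + E-values on a tagged subset of studies.
``emit_report`` writes the report as full-precision JSON, rounded CSV
tables, and per-scenario total-confounding contour CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from biasbound import io as bb_io
from biasbound.meta import MetaResult, StudyEstimate, pool_by_quantile
from biasbound.sensitivity import (
    BoundingResult,
    ConfounderScenario,
    EValueResult,
    analyse_scenario,
    bounding_curve,
    evalue,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "emit_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for a full pipeline run.

    ``focus_quantile=None`` selects the quantile with the largest pooled
    point estimate.  ``subset_tag`` restricts a secondary analysis to
    studies whose free-text ``tag`` column equals it.
    """

    reference_quantile: str = "Q1"
    focus_quantile: str | None = None
    confidence_level: float = 0.95
    subset_tag: str | None = None
    seed: int = 0
    rounding: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must lie in (0, 1)")
        if self.focus_quantile is not None and self.focus_quantile == self.reference_quantile:
            raise ValueError("focus quantile cannot equal the reference quantile")

    def to_dict(self) -> dict:
        return {
            "reference_quantile": self.reference_quantile,
            "focus_quantile": self.focus_quantile,
            "confidence_level": self.confidence_level,
            "subset_tag": self.subset_tag,
            "seed": self.seed,
            "rounding": self.rounding,
        }


@dataclass(frozen=True)
class AnalysisReport:
    """Everything a full run produced, JSON-serialisable via ``to_dict``."""

    per_quantile: dict[str, MetaResult]
    focus_quantile: str
    evalues: EValueResult
    scenarios: list[BoundingResult]
    subset_per_quantile: dict[str, MetaResult] | None
    subset_evalues: EValueResult | None
    subset_focus_quantile: str | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "per_quantile": {q: m.to_dict() for q, m in self.per_quantile.items()},
            "focus_quantile": self.focus_quantile,
            "evalues": self.evalues.to_dict(),
            "scenarios": [s.to_dict() for s in self.scenarios],
            "provenance": self.provenance,
        }
        if self.subset_per_quantile is not None:
            out["subset"] = {
                "per_quantile": {q: m.to_dict() for q, m in self.subset_per_quantile.items()},
                "focus_quantile": self.subset_focus_quantile,
                "evalues": self.subset_evalues.to_dict() if self.subset_evalues else None,
            }
        return out


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _pick_focus(results: dict[str, MetaResult], requested: str | None) -> str:
    if requested is not None:
        if requested not in results:
            raise ValueError(
                f"focus quantile {requested!r} has no pooled result; "
                f"available: {sorted(results)}"
            )
        return requested
    return max(results, key=lambda q: results[q].pooled_rr)


def _evalues_for(meta: MetaResult) -> EValueResult:
    return evalue(meta.pooled_rr, meta.ci_lower, meta.ci_upper)


def run_full_analysis(
    study_csv: str | Path,
    scenario_csv: str | Path | None,
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisReport:
    """Run the complete confounding-plausibility analysis.

    Deterministic: identical inputs and config give identical reports.
    Raises :class:`biasbound.io.ValidationError` with itemized row
    errors on malformed input, before any computation.
    """
    from biasbound import __version__

    studies = bb_io.read_study_csv(study_csv)
    scenarios = bb_io.read_scenario_csv(scenario_csv) if scenario_csv is not None else []
    if not scenarios and scenario_csv is not None:
        logger.warning("scenario file %s contains no scenarios", scenario_csv)

    per_quantile = pool_by_quantile(
        studies, reference=config.reference_quantile, level=config.confidence_level
    )
    if not per_quantile:
        raise ValueError("no non-reference quantiles to pool; nothing to analyse")
    focus = _pick_focus(per_quantile, config.focus_quantile)
    focus_meta = per_quantile[focus]
    evalues = _evalues_for(focus_meta)
    logger.info(
        "focus quantile %s: RR=%.4f (%.4f, %.4f), E=%.4f / %.4f",
        focus,
        focus_meta.pooled_rr,
        focus_meta.ci_lower,
        focus_meta.ci_upper,
        evalues.e_point,
        evalues.e_ci,
    )

    scenario_results = [analyse_scenario(s, focus_meta) for s in scenarios]

    subset_results = subset_evalues = subset_focus = None
    if config.subset_tag is not None:
        subset = [s for s in studies if s.tag == config.subset_tag]
        if not subset:
            raise ValueError(f"subset tag {config.subset_tag!r} matches no studies")
        subset_results = pool_by_quantile(
            subset, reference=config.reference_quantile, level=config.confidence_level
        )
        if subset_results:
            subset_focus = _pick_focus(subset_results, config.focus_quantile)
            subset_evalues = _evalues_for(subset_results[subset_focus])

    provenance = {
        "version": __version__,
        "study_csv_sha256": _sha256(study_csv),
        "scenario_csv_sha256": _sha256(scenario_csv) if scenario_csv is not None else None,
        "config": config.to_dict(),
        "n_studies": len({s.study_id for s in studies}),
        "n_rows": len(studies),
    }
    return AnalysisReport(
        per_quantile=per_quantile,
        focus_quantile=focus,
        evalues=evalues,
        scenarios=scenario_results,
        subset_per_quantile=subset_results,
        subset_evalues=subset_evalues,
        subset_focus_quantile=subset_focus,
        provenance=provenance,
    )


def _meta_table(results: dict[str, MetaResult], ndigits: int) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "quantile": q,
                "k": m.k,
                "pooled_rr": round(m.pooled_rr, ndigits),
                "ci_lower": round(m.ci_lower, ndigits),
                "ci_upper": round(m.ci_upper, ndigits),
                "tau2": round(m.tau2, max(4, ndigits)),
                "q_stat": round(m.q_stat, max(4, ndigits)),
                "i2": round(m.i2, max(4, ndigits)),
            }
            for q, m in sorted(results.items())
        ]
    )


def emit_report(
    report: AnalysisReport, output_dir: str | Path, *, rounding: int | None = None
) -> dict[str, Path]:
    """Write report.json, CSV tables, contour CSVs, and a run log.

    report.json keeps full precision; the CSV tables round for display.
    The output directory is checked up front so a failure never leaves a
    partial report.json behind.  Returns the paths written.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    ndigits = rounding if rounding is not None else report.provenance.get("config", {}).get("rounding", 2)
    paths: dict[str, Path] = {}

    paths["report"] = out / "report.json"
    paths["report"].write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")

    paths["meta_table"] = out / "meta_by_quantile.csv"
    _meta_table(report.per_quantile, ndigits).to_csv(paths["meta_table"], index=False)
    if report.subset_per_quantile is not None:
        paths["subset_meta_table"] = out / "meta_by_quantile_subset.csv"
        _meta_table(report.subset_per_quantile, ndigits).to_csv(
            paths["subset_meta_table"], index=False
        )

    scen_rows = []
    for res in report.scenarios:
        d = res.to_dict()
        d["b"] = round(d["b"], ndigits)
        for key in ("proportion_explained_point", "proportion_explained_lower_ci"):
            d[key] = round(d[key])
        if isinstance(d["required_rr_eu_for_total"], float):
            d["required_rr_eu_for_total"] = round(d["required_rr_eu_for_total"], ndigits)
        scen_rows.append(d)
    paths["scenarios"] = out / "scenarios.csv"
    pd.DataFrame(
        scen_rows,
        columns=[
            "scenario",
            "rr_eu",
            "rr_ud",
            "b",
            "proportion_explained_point",
            "proportion_explained_lower_ci",
            "fully_explains_point",
            "fully_explains_lower_ci",
            "required_rr_eu_for_total",
        ],
    ).to_csv(paths["scenarios"], index=False)

    # One total-confounding contour per scenario (target = the pooled RR
    # the scenario would have to explain), plus one for the focus estimate.
    focus_rr = report.per_quantile[report.focus_quantile].pooled_rr
    if focus_rr > 1.0:
        curve = bounding_curve(focus_rr)
        path = out / "curve_focus.csv"
        bb_io.write_curve_csv(curve, path)
        paths["curve_focus"] = path

    log_path = out / "run.log"
    with log_path.open("w") as fh:
        fh.write(json.dumps(report.provenance, indent=2, sort_keys=True) + "\n")
    paths["log"] = log_path
    return paths
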