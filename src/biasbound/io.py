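"""CSV readers and writers for study-estimate and confounder-scenario tables.

Validation is itemized: every malformed row is reported with its
(1-based, header-exclusive) row number so a batch of input errors can
be fixed in one pass.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from biasbound.effect_measures import EffectEstimate, or_to_rr, r_to_or
from biasbound.meta import StudyEstimate
from biasbound.sensitivity import BoundingCurve, ConfounderScenario

__all__ = [
    "ValidationError",
    "read_study_csv",
    "read_scenario_csv",
    "write_curve_csv",
]

STUDY_COLUMNS = {"study_id", "quantile", "measure", "point", "ci_lower", "ci_upper"}
SCENARIO_COLUMNS = {
    "name",
    "exposure_assoc_type",
    "exposure_assoc_value",
    "outcome_assoc_type",
    "outcome_assoc_value",
}
_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", ""}


class ValidationError(ValueError):
    """Input-table validation failure; carries one message per bad row."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("input validation failed:\n  " + "\n  ".join(errors))


def _parse_bool(value, row: int, column: str) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"row {row}: cannot interpret {column}={value!r} as a boolean")


def _optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return float(text) if text else None


def read_study_csv(path: str | Path) -> list[StudyEstimate]:
    """Read a study-estimate table.

    Required columns: study_id, quantile, measure {rr|or|hr}, point,
    ci_lower, ci_upper.  Optional: outcome_prevalence, rare_outcome,
    tag (free text used by subset filters).
    """
    df = pd.read_csv(path)
    missing = STUDY_COLUMNS - set(df.columns)
    if missing:
        raise ValidationError([f"{path}: missing columns {sorted(missing)}"])

    rows: list[StudyEstimate] = []
    errors: list[str] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            measure = str(rec["measure"]).strip().lower()
            estimate = EffectEstimate(
                measure=measure,
                point=float(rec["point"]),
                ci_lower=float(rec["ci_lower"]),
                ci_upper=float(rec["ci_upper"]),
                outcome_prevalence=_optional_float(rec.get("outcome_prevalence")),
                rare_outcome=_parse_bool(rec.get("rare_outcome"), i, "rare_outcome"),
            )
            tag = rec.get("tag")
            tag = None if tag is None or (isinstance(tag, float) and math.isnan(tag)) else str(tag)
            rows.append(
                StudyEstimate(
                    study_id=str(rec["study_id"]),
                    quantile=str(rec["quantile"]),
                    estimate=estimate,
                    tag=tag,
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(errors)
    return rows


def _assoc_to_rr(kind: str, value: float, p0: float | None, row: int, side: str) -> float:
    """Convert one scenario association (rr, or, or r) to the RR scale."""
    kind = kind.strip().lower()
    if kind == "rr":
        if value <= 0:
            raise ValueError(f"row {row}: {side} RR must be positive, got {value}")
        return value
    if kind in {"or", "r"}:
        if kind == "r":
            value = r_to_or(value)
        if p0 is None:
            raise ValueError(
                f"row {row}: {side} association of type '{kind}' requires "
                f"{side}_p0 (baseline risk) to convert to a risk ratio"
            )
        return or_to_rr(value, p0)
    raise ValueError(f"row {row}: unknown {side} association type {kind!r}")


def read_scenario_csv(path: str | Path) -> list[ConfounderScenario]:
    """Read a confounder-scenario table and convert each axis to RR.

    Columns: name, exposure_assoc_type {rr|or|r}, exposure_assoc_value,
    exposure_p0, outcome_assoc_type, outcome_assoc_value, outcome_p0.
    p0 columns may be blank for rows that do not need an OR conversion.
    Associations below the null are reciprocated (the bound depends only
    on strength, not direction).
    """
    df = pd.read_csv(path)
    if df.empty and set(df.columns) >= SCENARIO_COLUMNS:
        return []
    missing = SCENARIO_COLUMNS - set(df.columns)
    if missing:
        raise ValidationError([f"{path}: missing columns {sorted(missing)}"])

    scenarios: list[ConfounderScenario] = []
    errors: list[str] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            rr_eu = _assoc_to_rr(
                str(rec["exposure_assoc_type"]),
                float(rec["exposure_assoc_value"]),
                _optional_float(rec.get("exposure_p0")),
                i,
                "exposure",
            )
            rr_ud = _assoc_to_rr(
                str(rec["outcome_assoc_type"]),
                float(rec["outcome_assoc_value"]),
                _optional_float(rec.get("outcome_p0")),
                i,
                "outcome",
            )
            provenance = str(rec.get("provenance") or "")
            scenarios.append(
                ConfounderScenario(
                    name=str(rec["name"]),
                    rr_eu=rr_eu if rr_eu >= 1 else 1.0 / rr_eu,
                    rr_ud=rr_ud if rr_ud >= 1 else 1.0 / rr_ud,
                    provenance=provenance,
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(errors)
    return scenarios


def write_curve_csv(curve: BoundingCurve, path: str | Path) -> None:
    """Write contour coordinates as two-column CSV with the target recorded."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# target_b = {curve.target_b!r}\n")
        fh.write("rr_ud,rr_eu\n")
        for ud, eu in curve.points:
            fh.write(f"{ud!r},{eu!r}\n")
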