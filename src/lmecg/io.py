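"""Delimited cohort schema, evaluation configuration and the pipeline.

Cohort files are flat CSV tables, one record per row, with a mandatory
header. ST deviations are signed mm with a decimal point; flags are 0/1;
optional fields (age, group, collateral, outcome) are empty when absent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from .diagnostics import (
    DiagnosticMetrics,
    make_two_by_two,
    metrics,
    percent_round_half_up,
    roc_curve,
)
from .feature_model import (
    CollateralStatus,
    ConductionFlags,
    CulpritGroup,
    ECGFeatureRecord,
    LEADS,
    MM_PER_MV,
    STDeviationVector,
    Sex,
)
from .patterns import (
    CriterionRegistry,
    builtin_criteria,
    classify_fine,
    classify_main,
    criterion_from_expression,
)

__all__ = [
    "COLUMNS",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "load_criteria_config",
    "EvaluationConfig",
    "run_pipeline",
    "report_to_table",
    "report_lines",
]

_FLAG_COLS = ("lafb", "rbbb", "lbbb", "hdavb")
_ST_COLS = tuple(f"st_{ld.name}" for ld in LEADS)

#: Column order of the cohort table schema.
COLUMNS: tuple[str, ...] = (
    ("id", "group", "sex", "age", "qrs_ms") + _FLAG_COLS + _ST_COLS
    + ("collateral", "died_in_hospital")
)


class SchemaError(ValueError):
    """A cohort file violates the schema; the message names row/column."""


def _parse_flag(value, column: str, row: int) -> bool:
    if value in (0, 1):
        return bool(value)
    if isinstance(value, str) and value.strip() in ("0", "1"):
        return value.strip() == "1"
    raise SchemaError(f"row {row}: column {column!r} must be 0/1, got {value!r}")


def _parse_optional(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def read_cohort(path, unit: str = "mm") -> list:
    """Read a cohort CSV into validated feature records.

    ``unit`` is the unit of the st_* columns: "mm" (default) or "mV"
    (converted to mm on read, 1 mm = 0.1 mV).
    """
    if unit not in ("mm", "mV"):
        raise SchemaError(f"unknown ST unit: {unit!r}")
    scale = 1.0 if unit == "mm" else MM_PER_MV
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        r = row._asdict()
        try:
            group_s = _parse_optional(r["group"])
            coll_s = _parse_optional(r["collateral"])
            died_s = _parse_optional(r["died_in_hospital"])
            age_s = _parse_optional(r["age"])
            st = {
                ld: float(r[f"st_{ld.name}"]) * scale for ld in LEADS
            }
            record = ECGFeatureRecord(
                id=str(r["id"]),
                sex=Sex(str(r["sex"]).strip().lower()),
                st=STDeviationVector(st),
                qrs_ms=float(r["qrs_ms"]),
                conduction=ConductionFlags(
                    **{c: _parse_flag(r[c], c, i) for c in _FLAG_COLS}
                ),
                age=float(age_s) if age_s is not None else None,
                group=CulpritGroup(group_s) if group_s is not None else None,
                collateral=CollateralStatus(coll_s) if coll_s is not None else None,
                died_in_hospital=(died_s == "1") if died_s is not None else None,
            )
        except SchemaError:
            raise
        except (ValueError, KeyError, TypeError) as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
        records.append(record)
    return records


def records_to_frame(records: Sequence[ECGFeatureRecord],
                     classified: bool = False) -> pd.DataFrame:
    """Records -> schema-conformant DataFrame (optionally with patterns)."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "group": r.group.value if r.group else "",
            "sex": r.sex.value,
            "age": "" if r.age is None else f"{r.age:.0f}",
            "qrs_ms": f"{r.qrs_ms:.1f}",
        }
        for c in _FLAG_COLS:
            row[c] = int(getattr(r.conduction, c))
        for ld in LEADS:
            row[f"st_{ld.name}"] = f"{r.st[ld]:.2f}"
        row["collateral"] = r.collateral.value if r.collateral else ""
        row["died_in_hospital"] = (
            "" if r.died_in_hospital is None else int(r.died_in_hospital)
        )
        if classified:
            row["main_pattern"] = classify_main(r).value
            row["fine_pattern"] = classify_fine(r).value
        rows.append(row)
    cols = list(COLUMNS) + (["main_pattern", "fine_pattern"] if classified else [])
    return pd.DataFrame(rows, columns=cols)


def write_cohort(records: Sequence[ECGFeatureRecord], path) -> None:
    """Write records as a schema-conformant CSV (deterministic bytes)."""
    records_to_frame(records).to_csv(path, index=False, lineterminator="\n")


def load_criteria_config(path) -> CriterionRegistry:
    """Builtin registry extended with user-defined criteria from YAML.

    The file holds a ``criteria:`` mapping of name -> nested Boolean
    expression over the atoms {ste, no_ste, flag, main} and the
    connectives {and, or, not}, e.g.::

        criteria:
          wide_avr_avl:
            and:
              - {ste: aVR}
              - {ste: aVL}
              - {flag: lafb}
    """
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    registry = builtin_criteria()
    entries = payload.get("criteria") or {}
    if not isinstance(entries, dict):
        raise SchemaError("config 'criteria' must be a name -> expression mapping")
    for name, expr in entries.items():
        try:
            registry.register(criterion_from_expression(str(name), expr))
        except ValueError as exc:
            raise SchemaError(f"criterion {name!r}: {exc}") from exc
    return registry


# ---------------------------------------------------------------------------
# Evaluation pipeline

_CONTROL_SETS = {
    "all": [g for g in CulpritGroup if g is not CulpritGroup.LM_OCCLUSION],
    "subocclusion": [CulpritGroup.LM_SUBOCCLUSION],
    "lad": [CulpritGroup.PLAD, CulpritGroup.MLAD],
}


@dataclass(frozen=True)
class EvaluationConfig:
    """What to evaluate: criteria, positive group, control set, CI level."""

    criteria: tuple = ("model1", "model2")
    positive_group: CulpritGroup = CulpritGroup.LM_OCCLUSION
    #: "all" | "subocclusion" | "lad" | explicit sequence of CulpritGroup
    control_set: object = "all"
    confidence: float = 0.95
    include_roc_qrs: bool = False
    seed: int = 0

    def resolve_controls(self) -> list:
        if isinstance(self.control_set, str):
            try:
                controls = _CONTROL_SETS[self.control_set]
            except KeyError:
                raise ValueError(
                    f"unknown control set {self.control_set!r}; "
                    f"use one of {sorted(_CONTROL_SETS)} or an explicit list"
                ) from None
        else:
            controls = [CulpritGroup(g) for g in self.control_set]
        if self.positive_group in controls:
            raise ValueError("positive group must not be in the control set")
        return controls

    def digest(self) -> str:
        payload = {
            "criteria": list(self.criteria),
            "positive_group": self.positive_group.value,
            "control_set": (
                self.control_set if isinstance(self.control_set, str)
                else [CulpritGroup(g).value for g in self.control_set]
            ),
            "confidence": self.confidence,
            "include_roc_qrs": self.include_roc_qrs,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _metrics_payload(m: DiagnosticMetrics) -> dict:
    out = {}
    for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        est = getattr(m, name)
        if est.available:
            out[name] = {
                "value": est.value,
                "percent": est.percent,
                "ci95": [est.ci.lo, est.ci.hi],
                "fraction": f"{est.numerator}/{est.denominator}",
            }
        else:
            out[name] = {"value": None, "note": "undefined (zero denominator)"}
    return out


def run_pipeline(records: Sequence[ECGFeatureRecord],
                 config: EvaluationConfig,
                 registry: Optional[CriterionRegistry] = None) -> dict:
    """Evaluate the configured criteria on a labeled cohort.

    Returns a structured report: per-criterion 2x2 counts and metrics with
    CIs (full precision plus half-up-rounded integer percents), and
    optionally the QRS ROC. Records outside positive + control groups are
    excluded from the comparison. ``registry`` defaults to the builtin
    criteria; pass ``load_criteria_config(path)`` to add custom ones.
    """
    if not config.criteria:
        raise ValueError("empty criteria list")
    if registry is None:
        registry = builtin_criteria()
    unknown = [c for c in config.criteria if c not in registry]
    if unknown:
        raise ValueError(f"unregistered criteria: {unknown}")
    controls = config.resolve_controls()
    keep = [r for r in records
            if r.group is not None
            and (r.group is config.positive_group or r.group in controls)]
    if not keep:
        raise ValueError("no records in the positive or control groups")
    labels = [r.group is config.positive_group for r in keep]
    if not any(labels) or all(labels):
        raise ValueError("need records in both the positive and control groups")

    report: dict = {
        "config": {
            "positive_group": config.positive_group.value,
            "controls": [g.value for g in controls],
            "n_positive": int(sum(labels)),
            "n_control": int(len(labels) - sum(labels)),
            "confidence": config.confidence,
            "hash": config.digest(),
        },
        "criteria": {},
    }
    for name in config.criteria:
        preds = [registry[name](r) for r in keep]
        t = make_two_by_two(preds, labels)
        m = metrics(t, confidence=config.confidence)
        report["criteria"][name] = {
            "counts": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn},
            "metrics": _metrics_payload(m),
        }
    if config.include_roc_qrs:
        roc = roc_curve([r.qrs_ms for r in keep], labels)
        report["roc_qrs"] = {
            "auc": roc.auc,
            "youden_cutoff_ms": roc.youden_cutoff,
            "sensitivity_at_cutoff": roc.sens_at_cutoff,
            "specificity_at_cutoff": roc.spec_at_cutoff,
        }
    return report


def report_to_table(report: dict) -> pd.DataFrame:
    """Flatten a pipeline report into a delimited summary table."""
    rows = []
    for name, entry in report["criteria"].items():
        c = entry["counts"]
        row = {"criterion": name, **c}
        for metric, payload in entry["metrics"].items():
            row[metric] = payload["value"]
            row[f"{metric}_pct"] = payload.get("percent")
        rows.append(row)
    return pd.DataFrame(rows)


def report_lines(report: dict) -> list:
    """Human-readable report lines with half-up integer percents."""
    cfg = report["config"]
    lines = [
        f"positive: {cfg['positive_group']} (n={cfg['n_positive']}) "
        f"vs controls: {', '.join(cfg['controls'])} (n={cfg['n_control']})"
    ]
    for name, entry in report["criteria"].items():
        c = entry["counts"]
        m = entry["metrics"]

        def pct(key):
            p = m[key].get("percent")
            return "n/a" if p is None else f"{p}%"

        lines.append(
            f"  {name}: tp={c['tp']} fp={c['fp']} fn={c['fn']} tn={c['tn']}  "
            f"sens={pct('sensitivity')} spec={pct('specificity')} "
            f"ppv={pct('ppv')} npv={pct('npv')}"
        )
    if "roc_qrs" in report:
        r = report["roc_qrs"]
        lines.append(
            f"  QRS ROC: AUC={r['auc']:.3f} cutoff={r['youden_cutoff_ms']:.0f} ms "
            f"sens={percent_round_half_up(r['sensitivity_at_cutoff'])}% "
            f"spec={percent_round_half_up(r['specificity_at_cutoff'])}%"
        )
    return lines
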