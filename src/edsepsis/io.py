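"""Readers and writers for the plain-text interchange formats.

Formats:

* observations — CSV (RFC 4180, UTF-8, header required) or JSON-lines with
  fields ``encounter_id, timestamp, kind, value, unit``; timestamps are
  ISO-8601 and must carry a timezone offset.
* labels — CSV with ``encounter_id, sepsis, infection_categories,
  condition_categories, disposition``; category sets semicolon-delimited.
* alerts — CSV with ``encounter_id, activation_time, activation_index,
  satisfied_criteria``.
* accuracy report — loss-free JSON, or a text rendering shaped like the
  published tables.

Criteria configuration is a flat YAML mapping of threshold names to
values; unknown keys are rejected by name.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml

from .alerts import SepsisAlert
from .criteria import CriterionId, SHOCK_CRITERIA, SIRS_CRITERIA
from .evaluation import AccuracyReport, Group, ProportionCI, StudyDesign
from .model import (
    ChartReviewLabel,
    CriteriaConfig,
    Disposition,
    Encounter,
    Observation,
    ObservationKind,
    validate_encounter,
)

PathLike = Union[str, Path]

OBSERVATION_FIELDS = ["encounter_id", "timestamp", "kind", "value", "unit"]
LABEL_FIELDS = ["encounter_id", "sepsis", "infection_categories", "condition_categories", "disposition"]
ALERT_FIELDS = ["encounter_id", "activation_time", "activation_index", "satisfied_criteria"]


class FormatError(ValueError):
    """A malformed input row; the message carries the line number."""


def _parse_timestamp(raw: str, line: int) -> datetime:
    try:
        ts = datetime.fromisoformat(raw)
    except ValueError as exc:
        raise FormatError(f"line {line}: bad timestamp {raw!r}: {exc}") from None
    if ts.tzinfo is None:
        raise FormatError(f"line {line}: timestamp {raw!r} lacks a timezone offset")
    return ts


def _parse_observation_row(row: Mapping[str, str], line: int) -> Observation:
    missing = [f for f in OBSERVATION_FIELDS if not row.get(f)]
    if missing:
        raise FormatError(f"line {line}: missing field(s) {', '.join(missing)}")
    kind_raw = row["kind"].strip()
    try:
        kind = ObservationKind(kind_raw)
    except ValueError:
        raise FormatError(f"line {line}: unknown observation kind '{kind_raw}'") from None
    try:
        value = float(row["value"])
    except ValueError:
        raise FormatError(f"line {line}: non-numeric value {row['value']!r}") from None
    return Observation(
        encounter_id=row["encounter_id"].strip(),
        timestamp=_parse_timestamp(row["timestamp"].strip(), line),
        kind=kind,
        value=value,
        unit=row["unit"].strip(),
    )


def read_observations(path: PathLike, format: str = "csv") -> list[Encounter]:
    """Parse an observation file into validated, time-sorted Encounters.

    Rows are grouped by encounter_id (first-appearance order) and sorted
    stably by timestamp within each encounter; Fahrenheit temperatures are
    normalized to Celsius by the Observation constructor.
    """
    rows: list[Observation] = []
    path = Path(path)
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != OBSERVATION_FIELDS:
                raise FormatError(
                    f"line 1: expected header {','.join(OBSERVATION_FIELDS)}, got {reader.fieldnames}"
                )
            for line, row in enumerate(reader, start=2):
                rows.append(_parse_observation_row(row, line))
    elif format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line, text in enumerate(fh, start=1):
                if not text.strip():
                    continue
                try:
                    row = json.loads(text)
                except json.JSONDecodeError as exc:
                    raise FormatError(f"line {line}: invalid JSON: {exc}") from None
                rows.append(_parse_observation_row({k: str(v) for k, v in row.items()}, line))
    else:
        raise ValueError(f"unknown observation format '{format}' (expected csv or jsonl)")

    grouped: dict[str, list[Observation]] = {}
    for obs in rows:
        grouped.setdefault(obs.encounter_id, []).append(obs)
    encounters = [
        Encounter(encounter_id=eid, observations=obs_list).sorted()
        for eid, obs_list in grouped.items()
    ]
    for enc in encounters:
        violations = validate_encounter(enc)
        if violations:
            raise FormatError(f"encounter {enc.encounter_id}: " + "; ".join(violations))
    return encounters


def write_observations(encounters: Iterable[Encounter], path: PathLike, format: str = "csv") -> None:
    path = Path(path)
    records = [
        {
            "encounter_id": o.encounter_id,
            "timestamp": o.timestamp.isoformat(),
            "kind": o.kind.value,
            "value": o.value,
            "unit": o.unit,
        }
        for enc in encounters
        for o in enc.observations
    ]
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=OBSERVATION_FIELDS)
            writer.writeheader()
            writer.writerows(records)
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(rec) + "\n")
    else:
        raise ValueError(f"unknown observation format '{format}'")


def _split_set(raw: str) -> frozenset[str]:
    return frozenset(s for s in (part.strip() for part in raw.split(";")) if s)


def read_labels(path: PathLike) -> dict[str, ChartReviewLabel]:
    labels: dict[str, ChartReviewLabel] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != LABEL_FIELDS:
            raise FormatError(
                f"line 1: expected header {','.join(LABEL_FIELDS)}, got {reader.fieldnames}"
            )
        for line, row in enumerate(reader, start=2):
            sepsis_raw = row["sepsis"].strip().lower()
            if sepsis_raw not in ("true", "false"):
                raise FormatError(f"line {line}: sepsis must be true/false, got {row['sepsis']!r}")
            disposition_raw = row.get("disposition", "").strip()
            try:
                disposition = Disposition(disposition_raw) if disposition_raw else None
            except ValueError:
                raise FormatError(f"line {line}: unknown disposition '{disposition_raw}'") from None
            lab = ChartReviewLabel(
                encounter_id=row["encounter_id"].strip(),
                sepsis=sepsis_raw == "true",
                infection_categories=_split_set(row["infection_categories"]),
                condition_categories=_split_set(row["condition_categories"]),
                disposition=disposition,
            )
            labels[lab.encounter_id] = lab
    return labels


def write_labels(labels: Mapping[str, ChartReviewLabel], path: PathLike) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=LABEL_FIELDS)
        writer.writeheader()
        for eid in sorted(labels):
            lab = labels[eid]
            writer.writerow(
                {
                    "encounter_id": lab.encounter_id,
                    "sepsis": "true" if lab.sepsis else "false",
                    "infection_categories": ";".join(sorted(lab.infection_categories)),
                    "condition_categories": ";".join(sorted(lab.condition_categories)),
                    "disposition": lab.disposition.value if lab.disposition else "",
                }
            )


def write_alerts(alerts: Iterable[SepsisAlert], path: PathLike) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=ALERT_FIELDS)
        writer.writeheader()
        for a in alerts:
            writer.writerow(
                {
                    "encounter_id": a.encounter_id,
                    "activation_time": a.activation_time.isoformat(),
                    "activation_index": a.activation_index,
                    "satisfied_criteria": ";".join(sorted(c.value for c in a.satisfied_criteria)),
                }
            )


def read_alerts(path: PathLike) -> list[SepsisAlert]:
    alerts: list[SepsisAlert] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != ALERT_FIELDS:
            raise FormatError(
                f"line 1: expected header {','.join(ALERT_FIELDS)}, got {reader.fieldnames}"
            )
        for line, row in enumerate(reader, start=2):
            criteria = frozenset(CriterionId(c) for c in _split_set(row["satisfied_criteria"]))
            alerts.append(
                SepsisAlert(
                    encounter_id=row["encounter_id"].strip(),
                    activation_time=_parse_timestamp(row["activation_time"].strip(), line),
                    activation_index=int(row["activation_index"]),
                    satisfied_sirs=criteria & SIRS_CRITERIA,
                    satisfied_shock=criteria & SHOCK_CRITERIA,
                )
            )
    return alerts


def load_criteria_config(path: PathLike) -> CriteriaConfig:
    """Load thresholds from a flat YAML mapping; unknown keys are rejected."""
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError("criteria config must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(CriteriaConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise FormatError(f"unknown config key(s): {', '.join(unknown)}")
    return CriteriaConfig(**data)


def dump_criteria_config(cfg: CriteriaConfig, path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


# --- accuracy report serialization -----------------------------------------

def _ci_to_dict(ci: Optional[ProportionCI]) -> Optional[dict]:
    if ci is None:
        return None
    return {"point": ci.point, "lower": ci.lower, "upper": ci.upper, "level": ci.level}


def report_to_dict(report: AccuracyReport) -> dict:
    return {
        "design": report.design.value,
        "counts": {
            "tp": report.tp,
            "fp": report.fp,
            "fn_in_sample": report.fn_in_sample,
            "tn_in_sample": report.tn_in_sample,
        },
        "ppv": _ci_to_dict(report.ppv),
        "npv_estimated": _ci_to_dict(report.npv_estimated),
        "estimable_metrics": report.estimable_metrics,
        "non_estimable_metrics": report.non_estimable_metrics,
        "infection_table_tp": {c: list(v) for c, v in report.infection_table_tp.items()},
        "condition_table_fp": {c: list(v) for c, v in report.condition_table_fp.items()},
        "condition_table_tn": {c: list(v) for c, v in report.condition_table_tn.items()},
        "dispositions": {
            g.value: {d.value: list(v) for d, v in col.items()}
            for g, col in report.dispositions.items()
        },
    }


def report_from_dict(data: Mapping) -> AccuracyReport:
    def _ci(d: Optional[Mapping]) -> Optional[ProportionCI]:
        return None if d is None else ProportionCI(d["point"], d["lower"], d["upper"], d["level"])

    return AccuracyReport(
        tp=data["counts"]["tp"],
        fp=data["counts"]["fp"],
        fn_in_sample=data["counts"]["fn_in_sample"],
        tn_in_sample=data["counts"]["tn_in_sample"],
        ppv=_ci(data["ppv"]),
        npv_estimated=_ci(data["npv_estimated"]),
        design=StudyDesign(data["design"]),
        estimable_metrics=list(data["estimable_metrics"]),
        non_estimable_metrics=list(data["non_estimable_metrics"]),
        infection_table_tp={c: (v[0], v[1]) for c, v in data["infection_table_tp"].items()},
        condition_table_fp={c: (v[0], v[1]) for c, v in data["condition_table_fp"].items()},
        condition_table_tn={c: (v[0], v[1]) for c, v in data["condition_table_tn"].items()},
        dispositions={
            Group(g): {Disposition(d): (v[0], v[1]) for d, v in col.items()}
            for g, col in data["dispositions"].items()
        },
    )


def render_report_text(report: AccuracyReport) -> str:
    """Render the report as plain text shaped like the published tables."""
    lines: list[str] = []
    lines.append("Sepsis alert diagnostic accuracy")
    lines.append(f"Design: {report.design.value}")
    lines.append("")
    lines.append("Alert vs chart-review sepsis (reviewed encounters)")
    lines.append("  Alert     Sepsis  No sepsis  Total")
    lines.append(f"  Yes    {report.tp:>7d}  {report.fp:>9d}  {report.n_alerted:>5d}")
    lines.append(
        f"  No     {report.fn_in_sample:>7d}  {report.tn_in_sample:>9d}  {report.n_nonalert_reviewed:>5d}"
    )
    lines.append("")
    if report.ppv is not None:
        p, lo, hi = report.ppv.as_percent()
        lines.append(f"PPV {p:.1f}% (95% CI {lo:.1f}–{hi:.1f}%)")
    if report.npv_estimated is not None:
        p, lo, hi = report.npv_estimated.as_percent()
        lines.append(f"Estimated NPV {p:.1f}% (95% CI {lo:.1f}–{hi:.1f}%)")
    if report.non_estimable_metrics:
        lines.append(
            "Not estimable under this design: " + ", ".join(report.non_estimable_metrics)
        )
    for title, table in (
        ("Infection types, true-positive alerts", report.infection_table_tp),
        ("Medical conditions, false-positive alerts", report.condition_table_fp),
        ("Medical conditions, reviewed non-alerts", report.condition_table_tn),
    ):
        if not table:
            continue
        lines.append("")
        lines.append(title)
        for cat, (n, pct) in table.items():
            lines.append(f"  {cat:<28s} {n:>4d} ({pct:.1f})")
    if report.dispositions:
        lines.append("")
        lines.append("ED disposition by group")
        for g, col in report.dispositions.items():
            cells = ", ".join(f"{d.value}: {n} ({pct:.1f})" for d, (n, pct) in col.items())
            lines.append(f"  {g.value}: {cells}")
    return "\n".join(lines) + "\n"


def write_report(report: AccuracyReport, path: PathLike, format: str = "json") -> None:
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=2) + "\n", encoding="utf-8")
    elif format == "text":
        path.write_text(render_report_text(report), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format '{format}' (expected json or text)")


def read_report(path: PathLike) -> AccuracyReport:
    return report_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
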