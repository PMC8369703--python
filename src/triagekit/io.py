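"""Casualty record readers/writers and tabular report serialization.

All tabular outputs are plain CSV (the consumers are emergency-medicine
researchers, not another program); the casualty column contract ships as
``data/casualty_schema.json``.
"""

from __future__ import annotations

import csv
import io as _io
import json
from importlib import resources
from pathlib import Path
from typing import Sequence, TextIO, Union

import pandas as pd
from pydantic import ValidationError

from .errors import SchemaError
from .model import FIELD_ORDER, TERNARY_FIELDS, Assessment
from .cohort import PerformanceReport

Source = Union[str, Path, TextIO]

_NUMERIC_FIELDS = {
    "airway_positioning_attempts": int,
    "respiratory_rate": float,
    "capillary_refill_seconds": float,
    "heart_rate": float,
    "gcs": int,
}

_TRUE_TOKENS = {"true", "yes", "1"}
_FALSE_TOKENS = {"false", "no", "0", ""}


def casualty_schema() -> dict:
    """The documented casualty column contract."""
    return json.loads(
        (resources.files("triagekit") / "data" / "casualty_schema.json").read_text()
    )


def _coerce(field: str, raw, row: int):
    where = f"row {row}, column '{field}'"
    if field in TERNARY_FIELDS:
        token = "" if raw is None else str(raw).strip().lower()
        if token in ("", "unknown", "na", "nan"):
            return "unknown"
        if token in ("yes", "no"):
            return token
        raise SchemaError(f"bad ternary token '{raw}' at {where} (expect yes/no/unknown)")
    if field == "cold_environment":
        token = "" if raw is None else str(raw).strip().lower()
        if isinstance(raw, bool):
            return raw
        if token in _TRUE_TOKENS:
            return True
        if token in _FALSE_TOKENS:
            return False
        raise SchemaError(f"bad boolean token '{raw}' at {where}")
    caster = _NUMERIC_FIELDS[field]
    if raw is None or (isinstance(raw, str) and raw.strip() == ""):
        return None
    try:
        value = caster(float(raw))
    except (TypeError, ValueError):
        raise SchemaError(f"non-numeric value '{raw}' at {where}") from None
    return value


def _record_to_assessment(record: dict, row: int, lax: bool) -> Assessment:
    extra = set(record) - set(FIELD_ORDER)
    if extra and not lax:
        raise SchemaError(
            f"unknown column(s) {sorted(extra)} at row {row} (use lax mode to ignore)"
        )
    data = {}
    for field in FIELD_ORDER:
        if field in record:
            value = _coerce(field, record[field], row)
            if value is not None:  # empty numerics fall back to field defaults
                data[field] = value
    # attempts default must not contradict resumed-breathing observations
    if (
        data.get("breathing_after_airway_positioning") == "yes"
        and not data.get("airway_positioning_attempts")
    ):
        data["airway_positioning_attempts"] = 1
    try:
        return Assessment(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        col = ".".join(str(p) for p in first["loc"]) or "record"
        raise SchemaError(f"invalid value at row {row}, column '{col}': {first['msg']}") from exc


def _open_text(source: Source):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", newline=""), True


def read_casualties(source: Source, fmt: str = None, lax: bool = False) -> list[Assessment]:
    """Load casualty assessments from CSV or JSON.

    Format is inferred from the filename suffix unless ``fmt`` is given.
    Row numbers in error messages are 1-based data rows (header excluded)
    for CSV, array indices for JSON.
    """
    if fmt is None:
        name = getattr(source, "name", source)
        fmt = "json" if str(name).lower().endswith(".json") else "csv"
    handle, close = _open_text(source)
    try:
        if fmt == "json":
            try:
                payload = json.load(handle)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"invalid JSON: {exc}") from exc
            if not isinstance(payload, list):
                raise SchemaError("JSON casualty file must be an array of objects")
            return [
                _record_to_assessment(rec, row, lax) for row, rec in enumerate(payload, 1)
            ]
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError("CSV casualty file has no header")
        return [_record_to_assessment(rec, row, lax) for row, rec in enumerate(reader, 1)]
    finally:
        if close:
            handle.close()


def write_casualties(assessments: Sequence[Assessment], destination: Source, fmt: str = None) -> None:
    if fmt is None:
        name = getattr(destination, "name", destination)
        fmt = "json" if str(name).lower().endswith(".json") else "csv"
    records = [a.to_record() for a in assessments]
    if fmt == "json":
        text = json.dumps(records, indent=1)
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text)
        return
    buffer = _io.StringIO()
    writer = csv.DictWriter(buffer, fieldnames=list(FIELD_ORDER))
    writer.writeheader()
    for rec in records:
        writer.writerow({k: ("" if v is None else v) for k, v in rec.items()})
    if hasattr(destination, "write"):
        destination.write(buffer.getvalue())
    else:
        Path(destination).write_text(buffer.getvalue())


# ---------------------------------------------------------------------------
# Reports


def performance_to_frame(report: PerformanceReport) -> pd.DataFrame:
    """Flat one-row-per-metric table that round-trips to full precision."""
    rows = [
        ("system", report.system_id),
        ("n", report.n),
        ("n_rankable", report.n_rankable),
        ("under_triage_rate", repr(report.under_triage_rate)),
        ("over_triage_rate", repr(report.over_triage_rate)),
        ("correct_rate", repr(report.correct_rate)),
        ("kappa_vs_reference", repr(report.kappa_vs_reference)),
    ]
    for tier, value in report.sensitivity.items():
        rows.append((f"sensitivity.{tier}", repr(value)))
    for tier, value in report.specificity.items():
        rows.append((f"specificity.{tier}", repr(value)))
    for t in report.confusion.index:
        for a in report.confusion.columns:
            rows.append((f"confusion.{t}.{a}", int(report.confusion.loc[t, a])))
    return pd.DataFrame(rows, columns=["metric", "value"])


def write_frame(frame: pd.DataFrame, destination: Source, index: bool = False) -> None:
    frame.to_csv(destination, index=index)


def read_performance(source: Source) -> dict[str, float]:
    """Re-read a performance CSV into a metric -> value mapping."""
    frame = pd.read_csv(source, dtype=str)
    out: dict[str, float] = {}
    for _, row in frame.iterrows():
        key, value = row["metric"], row["value"]
        if key == "system":
            out[key] = value
            continue
        out[key] = float(value)
    return out
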