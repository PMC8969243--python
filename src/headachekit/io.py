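"""Reading and writing diary records as JSONL and CSV.

Two on-disk layouts are supported:

* **JSONL** — one record per line with a ``"kind"`` discriminator
  (``attack`` | ``event`` | ``location`` | ``daily``); mixed kinds may share
  one file.
* **CSV** — one file per record kind, same field names; set-valued cells
  (locations, symptoms, triggers) are semicolon-delimited.

Parsing is validating and never drops a record silently: every rejected line
is reported with its line number and reason alongside the accepted records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, time
from pathlib import Path
from typing import Any, Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd

from .records import (
    ActivityType,
    AppVersion,
    AttackRegistration,
    ContextEvent,
    DailyRecord,
    EventKind,
    EventSource,
    Intensity,
    Interaction,
    Location,
    LocationSample,
    MealRecord,
    Symptom,
    Treatment,
    Trigger,
)

__all__ = [
    "Record",
    "ParseError",
    "ParseResult",
    "to_record",
    "from_record",
    "parse_records",
    "read_jsonl",
    "write_jsonl",
    "read_csv",
    "write_csv",
]

Record = Union[AttackRegistration, ContextEvent, LocationSample, DailyRecord]

_MEALS = ("breakfast", "lunch", "dinner")


@dataclass(frozen=True)
class ParseError:
    line: int
    reason: str
    raw: Optional[str] = None


@dataclass
class ParseResult:
    records: List[Record]
    errors: List[ParseError] = field(default_factory=list)

    def raise_on_errors(self) -> "ParseResult":
        if self.errors:
            first = self.errors[0]
            raise ValueError(
                f"{len(self.errors)} invalid record(s); first at line {first.line}: {first.reason}"
            )
        return self


def _enum_set(values: Iterable, sort_key=lambda e: e.value) -> str:
    return ";".join(sorted((v.value for v in values)))


def to_record(obj: Record) -> Dict[str, Any]:
    """Flatten one record into a JSON-serializable dict with a kind tag."""
    if isinstance(obj, AttackRegistration):
        return {
            "kind": "attack",
            "patient_id": obj.patient_id,
            "start": obj.start.isoformat(),
            "end": obj.end.isoformat(),
            "intensity": int(obj.intensity),
            "locations": ";".join(sorted(z.code for z in obj.locations)),
            "unilateral": obj.unilateral,
            "symptoms": _enum_set(obj.symptoms),
            "triggers": _enum_set(obj.triggers),
            "treatment": obj.treatment.value,
            "app_version": obj.app_version.value,
        }
    if isinstance(obj, ContextEvent):
        return {
            "kind": "event",
            "patient_id": obj.patient_id,
            "event_kind": obj.kind.value,
            "start": obj.start.isoformat(),
            "end": obj.end.isoformat(),
            "activity_type": obj.activity_type.value if obj.activity_type else None,
            "stress_level": obj.stress_level,
            "source": obj.source.value,
            "interaction": obj.interaction.value,
            "flagged": obj.flagged,
        }
    if isinstance(obj, LocationSample):
        return {
            "kind": "location",
            "patient_id": obj.patient_id,
            "time": obj.time.isoformat(),
            "latitude": obj.latitude,
            "longitude": obj.longitude,
            "accuracy": obj.accuracy,
        }
    if isinstance(obj, DailyRecord):
        rec: Dict[str, Any] = {
            "kind": "daily",
            "patient_id": obj.patient_id,
            "date": obj.day.isoformat(),
            "stress_level": obj.stress_level,
            "mood": obj.mood,
        }
        for name in _MEALS:
            meal = getattr(obj, name)
            rec[f"{name}_taken"] = meal.taken if meal else None
            rec[f"{name}_time"] = meal.at.isoformat() if meal and meal.at else None
        return rec
    raise TypeError(f"not a diary record: {type(obj).__name__}")


def _parse_dt(value: str) -> datetime:
    dt = datetime.fromisoformat(value)
    if dt.tzinfo is None:
        raise ValueError(f"timestamp lacks a timezone offset: {value!r}")
    return dt


def _split_set(cell: Any) -> List[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return str(cell).split(";")


def from_record(rec: Dict[str, Any]) -> Record:
    """Rebuild one record from its flattened form; raises on any invalid field."""
    kind = rec.get("kind")
    if kind == "attack":
        return AttackRegistration(
            patient_id=str(rec["patient_id"]),
            start=_parse_dt(rec["start"]),
            end=_parse_dt(rec["end"]),
            intensity=Intensity(int(rec["intensity"])),
            locations=frozenset(Location.from_code(c) for c in _split_set(rec.get("locations"))),
            unilateral=_as_bool(rec["unilateral"]),
            symptoms=frozenset(Symptom(c) for c in _split_set(rec.get("symptoms"))),
            triggers=frozenset(Trigger(c) for c in _split_set(rec.get("triggers"))),
            treatment=Treatment(rec["treatment"]),
            app_version=AppVersion(rec["app_version"]),
        )
    if kind == "event":
        stress = rec.get("stress_level")
        return ContextEvent(
            patient_id=str(rec["patient_id"]),
            kind=EventKind(rec["event_kind"]),
            start=_parse_dt(rec["start"]),
            end=_parse_dt(rec["end"]),
            activity_type=ActivityType(rec["activity_type"]) if _present(rec.get("activity_type")) else None,
            stress_level=int(stress) if _present(stress) else None,
            source=EventSource(rec["source"]),
            interaction=Interaction(rec["interaction"]),
            flagged=_as_bool(rec.get("flagged", False)),
        )
    if kind == "location":
        return LocationSample(
            patient_id=str(rec["patient_id"]),
            time=_parse_dt(rec["time"]),
            latitude=float(rec["latitude"]),
            longitude=float(rec["longitude"]),
            accuracy=float(rec.get("accuracy") or 0.0),
        )
    if kind == "daily":
        meals = {}
        for name in _MEALS:
            taken = rec.get(f"{name}_taken")
            if not _present(taken):
                meals[name] = None
                continue
            at = rec.get(f"{name}_time")
            meals[name] = MealRecord(
                taken=_as_bool(taken), at=time.fromisoformat(at) if _present(at) else None
            )
        return DailyRecord(
            patient_id=str(rec["patient_id"]),
            day=date.fromisoformat(rec["date"]),
            stress_level=int(rec["stress_level"]) if _present(rec.get("stress_level")) else None,
            mood=int(rec["mood"]) if _present(rec.get("mood")) else None,
            breakfast=meals["breakfast"],
            lunch=meals["lunch"],
            dinner=meals["dinner"],
        )
    raise ValueError(f"unknown record kind: {kind!r}")


def _present(value: Any) -> bool:
    if value is None:
        return False
    if isinstance(value, float) and pd.isna(value):
        return False
    return value != ""


def _as_bool(value: Any) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(value)
    if str(value).lower() in ("true", "1"):
        return True
    if str(value).lower() in ("false", "0"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def parse_records(lines: Iterable[str]) -> ParseResult:
    """Parse line-delimited JSON records, validating each against its type.

    Invalid lines never abort the parse and are reported individually with
    line number and reason.
    """
    records: List[Record] = []
    errors: List[ParseError] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            records.append(from_record(json.loads(line)))
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(ParseError(line=lineno, reason=str(exc), raw=line))
    return ParseResult(records=records, errors=errors)


def read_jsonl(path: Union[str, Path]) -> ParseResult:
    with open(path, "r", encoding="utf-8") as handle:
        return parse_records(handle)


def write_jsonl(records: Iterable[Record], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for obj in records:
            handle.write(json.dumps(to_record(obj), sort_keys=True) + "\n")


def write_csv(records: Sequence[Record], path: Union[str, Path]) -> None:
    """Write records of a single kind to CSV (field names as in JSONL)."""
    rows = [to_record(obj) for obj in records]
    kinds = {row["kind"] for row in rows}
    if len(kinds) > 1:
        raise ValueError(f"CSV files hold one record kind, got {sorted(kinds)}")
    pd.DataFrame(rows).to_csv(path, index=False)


def read_csv(path: Union[str, Path]) -> ParseResult:
    """Read one CSV file of records (kind column included), validating rows."""
    frame = pd.read_csv(path)
    records: List[Record] = []
    errors: List[ParseError] = []
    for idx, row in enumerate(frame.to_dict(orient="records"), start=2):  # header is line 1
        try:
            records.append(from_record(row))
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(ParseError(line=idx, reason=str(exc)))
    return ParseResult(records=records, errors=errors)
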