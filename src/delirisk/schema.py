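"""Risk-factor schema, patient records and cohort I/O.

A cohort is a flat table of categorical/binary risk factors per resident of a
long-term care facility, with an optional binary outcome label
(``delirium`` / ``non-delirium``).  Missing entries are first-class: the app
collects only a subset of the algorithm's factors at the bedside, so any
factor may be absent and downstream inference must tolerate that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MISSING",
    "RiskFactor",
    "RiskFactorSchema",
    "PatientRecord",
    "Cohort",
    "SchemaError",
    "RecordError",
    "default_schema",
    "validate_record",
    "load_cohort",
    "save_cohort",
    "load_schema",
    "save_schema",
]

DELIRIUM = "delirium"
NON_DELIRIUM = "non-delirium"
TARGET_VALUES = (DELIRIUM, NON_DELIRIUM)

BINARY_VALUES = ("no", "yes")


class _Missing:
    """Singleton sentinel for an unrecorded factor value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __bool__(self) -> bool:
        return False


#: Sentinel stored in :class:`PatientRecord` for factors that were not entered.
MISSING = _Missing()


class SchemaError(ValueError):
    """A file or object does not conform to the governing schema."""


class RecordError(ValueError):
    """A single record carries an illegal value; reports row and column."""


@dataclass(frozen=True)
class RiskFactor:
    """One risk factor: a name plus its closed set of legal values."""

    name: str
    kind: str = "binary"  # "binary" | "categorical"
    allowed_values: tuple[str, ...] = BINARY_VALUES

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("factor name must be non-empty")
        if self.kind not in ("binary", "categorical"):
            raise SchemaError(f"unknown factor kind {self.kind!r}")
        values = tuple(self.allowed_values)
        if self.kind == "binary" and len(values) != 2:
            raise SchemaError(f"binary factor {self.name!r} needs exactly 2 values")
        if len(values) < 2:
            raise SchemaError(f"categorical factor {self.name!r} needs >=2 values")
        if len(set(values)) != len(values):
            raise SchemaError(f"factor {self.name!r} has duplicate allowed values")
        object.__setattr__(self, "allowed_values", values)


@dataclass(frozen=True)
class RiskFactorSchema:
    """Ordered declaration of the risk factors and the decision attribute."""

    factors: tuple[RiskFactor, ...]
    target_name: str = "label"
    target_values: tuple[str, ...] = TARGET_VALUES

    def __post_init__(self) -> None:
        factors = tuple(self.factors)
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise SchemaError("factor names must be unique")
        if not self.target_name:
            raise SchemaError("target name must be non-empty")
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "target_values", tuple(self.target_values))

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def factor(self, name: str) -> RiskFactor:
        for f in self.factors:
            if f.name == name:
                return f
        raise SchemaError(f"unknown factor {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.factor_names

    def __len__(self) -> int:
        return len(self.factors)

    def to_dict(self) -> dict:
        return {
            "factors": [
                {"name": f.name, "kind": f.kind, "allowed_values": list(f.allowed_values)}
                for f in self.factors
            ],
            "target_name": self.target_name,
            "target_values": list(self.target_values),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RiskFactorSchema":
        try:
            factors = tuple(
                RiskFactor(f["name"], f.get("kind", "binary"), tuple(f["allowed_values"]))
                for f in data["factors"]
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed schema document: {exc}") from exc
        return cls(
            factors=factors,
            target_name=data.get("target_name", "label"),
            target_values=tuple(data.get("target_values", TARGET_VALUES)),
        )


# Clinically named factors cover the documented head of the 24-factor set;
# the tail ships as replaceable placeholders and the whole schema can be
# overridden from a JSON file.
_NAMED_FACTORS = (
    "age_65_or_older",
    "disease_severity",
    "abnormal_bun",
    "dehydration",
    "water_electrolyte_imbalance",
    "nutritional_imbalance",
    "hypoxia",
    "infection",
    "sleep_disorder",
    "surgery_general_anaesthesia",
    "oedema",
    "multiple_comorbidities",
    "pain",
    "pain_medicine_use",
)


def default_schema() -> RiskFactorSchema:
    """The shipped 24-factor binary schema (named head + placeholder tail)."""
    names = _NAMED_FACTORS + tuple(
        f"factor_{i}" for i in range(len(_NAMED_FACTORS) + 1, 25)
    )
    return RiskFactorSchema(factors=tuple(RiskFactor(n) for n in names))


@dataclass(frozen=True)
class PatientRecord:
    """One resident's factor vector; ``patient_id`` is a pseudonym only."""

    patient_id: str
    values: Mapping[str, object] = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    def value(self, factor: str):
        return self.values.get(factor, MISSING)


def validate_record(record: PatientRecord, schema: RiskFactorSchema) -> list[str]:
    """Return all schema violations for ``record`` (empty list = valid).

    Missing values are always legal; inference treats them as unmatched.
    """
    violations: list[str] = []
    for name, value in record.values.items():
        if name not in schema:
            violations.append(f"unknown factor {name!r}")
            continue
        if value is MISSING:
            continue
        factor = schema.factor(name)
        if value not in factor.allowed_values:
            violations.append(
                f"illegal value {value!r} for factor {name!r} "
                f"(allowed: {', '.join(factor.allowed_values)})"
            )
    if record.label is not None and record.label not in schema.target_values:
        violations.append(
            f"illegal label {record.label!r} (allowed: {', '.join(schema.target_values)})"
        )
    return violations


@dataclass(frozen=True)
class Cohort:
    """A validated set of patient records under one schema."""

    schema: RiskFactorSchema
    records: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if not records:
            raise SchemaError("a cohort must contain at least one record")
        for i, rec in enumerate(records):
            problems = validate_record(rec, self.schema)
            if problems:
                raise RecordError(f"record {i} ({rec.patient_id!r}): " + "; ".join(problems))
        object.__setattr__(self, "records", records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labelled(self) -> bool:
        return all(rec.label is not None for rec in self.records)

    @property
    def labels(self) -> tuple[str | None, ...]:
        return tuple(rec.label for rec in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Factor table with one row per record; MISSING rendered as ``None``."""
        rows = []
        for rec in self.records:
            row = {"patient_id": rec.patient_id}
            for name in self.schema.factor_names:
                v = rec.value(name)
                row[name] = None if v is MISSING else v
            row[self.schema.target_name] = rec.label
            rows.append(row)
        return pd.DataFrame(rows)

    def with_records(self, records: Iterable[PatientRecord]) -> "Cohort":
        return replace(self, records=tuple(records))


def _record_from_row(
    row: Mapping[str, object], schema: RiskFactorSchema, index: int
) -> PatientRecord:
    values: dict[str, object] = {}
    for name in schema.factor_names:
        raw = row.get(name)
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
            values[name] = MISSING
        else:
            raw = str(raw)
            if raw not in schema.factor(name).allowed_values:
                raise RecordError(
                    f"row {index}, column {name!r}: illegal value {raw!r}"
                )
            values[name] = raw
    label = row.get(schema.target_name)
    if label is None or (isinstance(label, float) and pd.isna(label)) or label == "":
        label = None
    else:
        label = str(label)
        if label not in schema.target_values:
            raise RecordError(
                f"row {index}, column {schema.target_name!r}: illegal label {label!r}"
            )
    pid = row.get("patient_id")
    pid = str(pid) if pid not in (None, "") else f"record_{index}"
    return PatientRecord(patient_id=pid, values=values, label=label)


def load_cohort(path: str | Path, schema: RiskFactorSchema, format: str | None = None) -> Cohort:
    """Load a cohort from CSV or JSON, validating every cell against ``schema``.

    CSV: comma-separated UTF-8 with a header of factor names plus optional
    ``patient_id`` and label columns; empty cells become MISSING.
    JSON: the document written by :func:`save_cohort`.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        known = set(schema.factor_names) | {"patient_id", schema.target_name}
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise SchemaError(f"unknown column(s) in {path.name}: {', '.join(unknown)}")
        rows = df.to_dict(orient="records")
    elif format == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        file_schema = RiskFactorSchema.from_dict(doc["schema"]) if "schema" in doc else schema
        if file_schema != schema:
            raise SchemaError(f"schema embedded in {path.name} differs from the declared schema")
        rows = doc["records"]
    else:
        raise ValueError(f"unknown cohort format {format!r}")
    records = [_record_from_row(row, schema, i) for i, row in enumerate(rows)]
    return Cohort(schema=schema, records=tuple(records))


def save_cohort(cohort: Cohort, path: str | Path, format: str | None = None) -> Path:
    """Write a cohort as CSV (MISSING = empty cell) or JSON (with schema)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = cohort.to_frame()
        df.to_csv(path, index=False)
    elif format == "json":
        doc = {
            "schema": cohort.schema.to_dict(),
            "records": cohort.to_frame().to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise ValueError(f"unknown cohort format {format!r}")
    return path


def load_schema(path: str | Path) -> RiskFactorSchema:
    with open(path, encoding="utf-8") as fh:
        return RiskFactorSchema.from_dict(json.load(fh))


def save_schema(schema: RiskFactorSchema, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(schema.to_dict(), fh, indent=1)
    return path
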