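"""Coded evidence table: record schema, validated I/O, and unit-level aggregation.

The evidence table is the backbone of the analysis: one row per published
classifier study, carrying design metadata (year, disorder, country, modality,
cross-validation scheme, validation type), sample composition (patient and
control counts), reported performance (accuracy and optional secondary
metrics), and transparency/availability flags.  Everything downstream —
inequality indices, precision-weighted synthesis, quality scoring — consumes
either :class:`EvidenceTable` or the per-unit totals in :class:`GroupedSample`.

Dialect: UTF-8 delimited text, comma by default, tab accepted (sniffed).
Missing values are empty cells or ``NA``.  Unknown columns are preserved as
passthrough so user-specific codings survive a round trip.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "StudyRecord",
    "EvidenceTable",
    "GroupedSample",
    "Violation",
    "SchemaError",
    "EmptyAggregationError",
    "read_evidence_table",
    "write_evidence_table",
    "read_units_csv",
    "write_units_csv",
    "aggregate_sample_by_unit",
]

FIRST_AUTHOR_FIELDS = ("computer_data_science", "neuroscience", "psychiatry", "psychology", "other")
ECONOMIC_BLOCS = ("MEDC", "LEDC")
DATA_SOURCES = ("self_collected", "open_dataset")
MODALITIES = ("MRI_fMRI", "EEG_ERP", "fNIRS", "MEG", "PET", "multimodal")
MODEL_FAMILIES = ("shallow", "deep")
FEATURE_SELECTION = ("pre_engineered", "algorithmic", "none")
CV_SCHEMES = ("none", "LOOCV", "kfold", "nested_kfold", "other")
EXTERNAL_VALIDATION = ("none", "within_country", "cross_country")
SECONDARY_METRICS = ("sensitivity", "specificity", "balanced_accuracy", "auc")

#: columns that must be present and parseable for a row to be accepted
MANDATORY_COLUMNS = ("study_id", "year", "sample_country", "n_patients", "n_controls", "accuracy", "cv_scheme")


class SchemaError(ValueError):
    """The file-level schema is unusable (e.g. a mandatory column is missing)."""


class EmptyAggregationError(ValueError):
    """An aggregation produced no units (filter removed every record)."""


def _enum(*values: str):
    from typing import Literal

    return Literal[values]  # type: ignore[valid-type]


class StudyRecord(BaseModel):
    """One coded classifier study."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    study_id: str
    year: int = Field(ge=1990, le=2030)
    disorder: str = "unspecified"
    first_author_field: str = "other"
    sample_country: str
    sample_region: Optional[str] = None
    economic_bloc: Optional[str] = None
    data_source: Optional[str] = None
    modality: Optional[str] = None
    model_family: Optional[str] = None
    feature_selection: Optional[str] = None
    cv_scheme: str = "none"
    external_validation: str = "none"
    n_patients: int = Field(ge=0)
    n_controls: int = Field(ge=0)
    n_total: Optional[int] = Field(default=None, ge=0)
    n_test: Optional[int] = Field(default=None, ge=0)
    accuracy: float = Field(ge=0.0, le=1.0)
    sensitivity: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    specificity: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    balanced_accuracy: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    auc: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    reported_metrics: frozenset[str] = frozenset()
    n_sites: int = Field(default=1, ge=0)
    data_claimed: bool = False
    data_verified: bool = False
    model_claimed: bool = False
    model_verified: bool = False

    @model_validator(mode="after")
    def _check_consistency(self) -> "StudyRecord":
        if self.n_total is None:
            object.__setattr__(self, "n_total", self.n_patients + self.n_controls)
        elif self.n_patients or self.n_controls:
            if self.n_total != self.n_patients + self.n_controls:
                raise ValueError(
                    f"n_total ({self.n_total}) != n_patients + n_controls "
                    f"({self.n_patients + self.n_controls})"
                )
        for name, universe in (
            ("first_author_field", FIRST_AUTHOR_FIELDS),
            ("economic_bloc", ECONOMIC_BLOCS),
            ("data_source", DATA_SOURCES),
            ("modality", MODALITIES),
            ("model_family", MODEL_FAMILIES),
            ("feature_selection", FEATURE_SELECTION),
            ("cv_scheme", CV_SCHEMES),
            ("external_validation", EXTERNAL_VALIDATION),
        ):
            val = getattr(self, name)
            if val is not None and val not in universe:
                raise ValueError(f"{name} {val!r} not one of {universe}")
        bad = set(self.reported_metrics) - set(SECONDARY_METRICS)
        if bad:
            raise ValueError(f"unknown reported_metrics {sorted(bad)}")
        if self.data_verified and not self.data_claimed:
            raise ValueError("data_verified implies data_claimed")
        if self.model_verified and not self.model_claimed:
            raise ValueError("model_verified implies model_claimed")
        return self


@dataclass(frozen=True)
class Violation:
    """A rejected row with a human-readable reason."""

    row: int
    study_id: Optional[str]
    reason: str

    def to_dict(self) -> dict:
        return {"row": self.row, "study_id": self.study_id, "reason": self.reason}


@dataclass
class EvidenceTable:
    """Ordered, validated collection of :class:`StudyRecord`."""

    records: list[StudyRecord]
    schema_version: str = "1.0"
    provenance: str = ""
    violations: list[Violation] = field(default_factory=list)
    #: unknown input columns, preserved per study_id for round-tripping
    passthrough: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.study_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate study_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter(self, predicate: Callable[[StudyRecord], bool]) -> "EvidenceTable":
        kept = [r for r in self.records if predicate(r)]
        return EvidenceTable(kept, self.schema_version, self.provenance,
                             passthrough={r.study_id: self.passthrough.get(r.study_id, {}) for r in kept})

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = r.model_dump()
            d["reported_metrics"] = ";".join(sorted(r.reported_metrics))
            d.update(self.passthrough.get(r.study_id, {}))
            rows.append(d)
        return pd.DataFrame(rows)

    def violation_report(self) -> dict:
        return {
            "n_records": len(self.records),
            "n_violations": len(self.violations),
            "violations": [v.to_dict() for v in self.violations],
        }


@dataclass
class GroupedSample:
    """Per-unit nonnegative values (e.g. total sampled N per country),
    each unit tagged with a module label (e.g. MEDC/LEDC bloc)."""

    units: list[tuple[str, float, str]]

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("GroupedSample needs at least one unit")
        ids = [u[0] for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValueError("unit_id values must be unique")
        vals = np.asarray([u[1] for u in self.units], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("unit values must be finite")
        if np.any(vals < 0):
            raise ValueError("unit values must be nonnegative")

    @property
    def unit_ids(self) -> list[str]:
        return [u[0] for u in self.units]

    @property
    def values(self) -> np.ndarray:
        return np.asarray([u[1] for u in self.units], dtype=float)

    @property
    def modules(self) -> list[str]:
        return [u[2] for u in self.units]

    def by_module(self) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for _, v, m in self.units:
            out.setdefault(m, []).append(v)
        return {m: np.asarray(v, dtype=float) for m, v in out.items()}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], module: str = "all",
                     module_map: Optional[Mapping[str, str]] = None) -> "GroupedSample":
        units = [(k, float(v), (module_map or {}).get(k, module)) for k, v in mapping.items()]
        return cls(units)


# ---------------------------------------------------------------------------
# I/O

_BOOL_MAP = {"true": True, "1": True, "yes": True, "t": True,
             "false": False, "0": False, "no": False, "f": False}


def _parse_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("", "na", "nan"):
        return None
    if s not in _BOOL_MAP:
        raise ValueError(f"unparseable boolean {v!r}")
    return _BOOL_MAP[s]


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    return isinstance(v, str) and v.strip().lower() in ("", "na", "nan")


_INT_FIELDS = ("year", "n_patients", "n_controls", "n_total", "n_test", "n_sites")
_FLOAT_FIELDS = ("accuracy", "sensitivity", "specificity", "balanced_accuracy", "auc")
_BOOL_FIELDS = ("data_claimed", "data_verified", "model_claimed", "model_verified")
_KNOWN_COLUMNS = set(StudyRecord.model_fields)


def _row_to_kwargs(row: Mapping) -> dict:
    kw: dict = {}
    for key, raw in row.items():
        if key not in _KNOWN_COLUMNS:
            continue
        if _is_missing(raw):
            continue
        if key in _INT_FIELDS:
            try:
                f = float(raw)
            except ValueError:
                raise ValueError(f"unparseable numeric cell in {key}: {raw!r}") from None
            if not f.is_integer():
                raise ValueError(f"{key} must be an integer, got {raw!r}")
            kw[key] = int(f)
        elif key in _FLOAT_FIELDS:
            try:
                kw[key] = float(raw)
            except ValueError:
                raise ValueError(f"unparseable numeric cell in {key}: {raw!r}") from None
        elif key in _BOOL_FIELDS:
            b = _parse_bool(raw)
            if b is not None:
                kw[key] = b
        elif key == "reported_metrics":
            toks = [t.strip() for t in str(raw).replace(",", ";").split(";") if t.strip()]
            kw[key] = frozenset(toks)
        else:
            kw[key] = str(raw).strip()
    # derive reported_metrics from present secondary-metric columns if not coded
    if "reported_metrics" not in kw:
        kw["reported_metrics"] = frozenset(m for m in SECONDARY_METRICS if m in kw)
    return kw


def read_evidence_table(path, strict: bool = False,
                        aliases: Optional[Mapping[str, str]] = None) -> EvidenceTable:
    """Read a delimited evidence table into a validated :class:`EvidenceTable`.

    Parameters
    ----------
    path : str or file-like
        CSV (comma) or TSV (tab) file with a header row.
    strict : bool
        If True, the first violation aborts with an exception.  Otherwise
        invalid rows are dropped and recorded in ``table.violations``.
    aliases : mapping, optional
        Input-column → schema-column renames applied before validation.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=object,
                     keep_default_na=False, na_values=[])
    if aliases:
        df = df.rename(columns=dict(aliases))
    df.columns = [str(c).strip() for c in df.columns]

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    extra_cols = [c for c in df.columns if c not in _KNOWN_COLUMNS]
    records: list[StudyRecord] = []
    violations: list[Violation] = []
    passthrough: dict[str, dict] = {}
    seen: set[str] = set()

    for i, row in enumerate(df.to_dict(orient="records")):
        sid = None if _is_missing(row.get("study_id")) else str(row["study_id"]).strip()
        try:
            if sid is None:
                raise ValueError("missing study_id")
            if sid in seen:
                raise ValueError(f"duplicate study_id {sid!r}")
            for col in MANDATORY_COLUMNS:
                if _is_missing(row.get(col)):
                    raise ValueError(f"missing mandatory value in column {col!r}")
            rec = StudyRecord(**_row_to_kwargs(row))
        except (ValueError, ValidationError) as exc:
            reason = _first_error_message(exc)
            if strict:
                raise SchemaError(f"row {i}: {reason}") from exc
            violations.append(Violation(row=i, study_id=sid, reason=reason))
            continue
        seen.add(sid)
        records.append(rec)
        if extra_cols:
            passthrough[sid] = {c: row.get(c) for c in extra_cols if not _is_missing(row.get(c))}

    table = EvidenceTable(records, provenance=str(getattr(path, "name", path)),
                          violations=violations, passthrough=passthrough)
    if violations:
        logger.warning("dropped %d invalid row(s) while reading %s", len(violations), path)
    return table


def _first_error_message(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        err = exc.errors()[0]
        loc = ".".join(str(p) for p in err["loc"]) or "record"
        msg = err["msg"]
        # normalise pydantic range messages into domain language
        if loc in _FLOAT_FIELDS and ("less than or equal" in msg or "greater than or equal" in msg):
            return f"{loc} out of [0,1]"
        return f"{loc}: {msg}"
    return str(exc)


def write_evidence_table(table: EvidenceTable, path) -> None:
    """Write the table back to CSV; a read of the output round-trips all fields."""
    table.to_dataframe().to_csv(path, index=False)


def read_units_csv(path, default_module: str = "all") -> GroupedSample:
    """Read a unit-level sample table: ``unit,value[,module]`` with header."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "unit" not in cols or "value" not in cols:
        raise SchemaError("units file needs 'unit' and 'value' columns")
    mods = df["module"].astype(str).tolist() if "module" in cols else [default_module] * len(df)
    units = [(str(u), float(v), m) for u, v, m in zip(df["unit"], df["value"], mods)]
    return GroupedSample(units)


def write_units_csv(grouped: GroupedSample, path) -> None:
    pd.DataFrame(grouped.units, columns=["unit", "value", "module"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Aggregation

def aggregate_sample_by_unit(
    table: EvidenceTable,
    unit_field: str = "sample_country",
    module_map: Optional[Mapping[str, str]] = None,
    where: Optional[Callable[[StudyRecord], bool]] = None,
    include_zero_units: Optional[Iterable[str]] = None,
    default_module: str = "all",
) -> GroupedSample:
    """Sum ``n_total`` over records per unit (country, region, ...).

    Units observed with zero total are excluded unless listed in
    ``include_zero_units``, which injects a supplied universe (e.g. all 251
    countries) at value 0 — both conventions matter when the unit universe
    itself is part of the inequality question.
    """
    if unit_field not in StudyRecord.model_fields:
        raise ValueError(f"{unit_field!r} is not a StudyRecord field")
    totals: dict[str, float] = {}
    n_kept = 0
    for rec in table.records:
        if where is not None and not where(rec):
            continue
        unit = getattr(rec, unit_field)
        if unit is None:
            continue
        totals[str(unit)] = totals.get(str(unit), 0.0) + float(rec.n_total or 0)
        n_kept += 1
    if n_kept == 0:
        raise EmptyAggregationError("no records left after filtering")
    if include_zero_units:
        for u in include_zero_units:
            totals.setdefault(str(u), 0.0)
    else:
        totals = {u: v for u, v in totals.items() if v > 0}
    if not totals:
        raise EmptyAggregationError("aggregation produced no units with positive totals")

    def module_of(u: str) -> str:
        if module_map is None:
            return default_module
        if u not in module_map:
            raise KeyError(f"unit {u!r} missing from module_map")
        return str(module_map[u])

    return GroupedSample([(u, v, module_of(u)) for u, v in sorted(totals.items())])
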