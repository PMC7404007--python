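"""Declarative staging configuration: parse, validate, serialize, EAV expansion.

The configuration is a single YAML document that maps an entity-relationship
model onto delimited input files. Users declare *what* the target
representation is (entities anchored to patients or visits, attributes bound
to columns, meta-attributes qualifying values) — never *how* to load it. An
entity may instead carry an EAV specification, in which case the concrete
attribute catalog is generated automatically from the distinct parameter
labels observed in the data (:func:`expand_eav_entities`).

Document layout::

    study:
      label: DEMO
      code: S1            # optional; prefix of canonical subject/visit ids
    sources:
      patients: {path: patients.csv, role: patient-file, key: [patient_id]}
      visits:   {path: visits.csv, role: visit-file,
                 key: [patient_id, visit_id], timestamp: start_date, end: end_date}
      labs:     {path: labs.csv, role: data-file,
                 key: [patient_id, visit_id], timestamp: sample_date}
    entities:
      - name: Labs
        anchor: visit
        source: labs
        eav: {parameters: [Parameter], value: Result, meta: [Unit, Norm range]}
    options: {day_first: true, transmart_aggregation: latest}
"""

from __future__ import annotations

import copy
from typing import TYPE_CHECKING, Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import ConfigParseError, ConfigSchemaError
from ._util import normalize_label

if TYPE_CHECKING:  # pragma: no cover
    from .ingest import SourceTable
    from .report import AnomalyLog

#: Cells equal to one of these (outer-trimmed, case-insensitive) are missing.
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "N/A", "NULL", "-", "."})

Role = Literal["patient-file", "visit-file", "data-file"]
Anchor = Literal["patient", "visit", "encounter"]
DeclaredType = Literal["auto", "numeric", "categorical", "date", "text"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KeySpec(_Model):
    columns: list[str] = Field(min_length=1)


class MetaAttributeDef(_Model):
    name: str
    column: str


class AttributeDef(_Model):
    name: str
    column: str
    declared_type: DeclaredType = "auto"
    meta_attributes: list[MetaAttributeDef] = Field(default_factory=list)
    generated: bool = False

    @model_validator(mode="after")
    def _unique_meta(self) -> "AttributeDef":
        names = [m.name for m in self.meta_attributes]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate meta-attribute names on attribute {self.name!r}")
        return self


class EavSpec(_Model):
    parameter_columns: list[str] = Field(min_length=1)
    value_column: str
    meta_columns: list[MetaAttributeDef] = Field(default_factory=list)
    label_join: str = "|"

    @model_validator(mode="after")
    def _disjoint(self) -> "EavSpec":
        if self.value_column in self.parameter_columns:
            raise ValueError("EAV value column must not be a parameter column")
        meta = {m.column for m in self.meta_columns}
        if meta & set(self.parameter_columns):
            raise ValueError("EAV parameter columns and meta columns must be disjoint")
        return self


class EntityDef(_Model):
    name: str
    anchor: Anchor
    source: str
    attributes: list[AttributeDef] = Field(default_factory=list)
    eav: Optional[EavSpec] = None

    @model_validator(mode="after")
    def _nonempty(self) -> "EntityDef":
        if not self.attributes and self.eav is None:
            raise ValueError(f"entity {self.name!r} declares neither attributes nor an EAV spec")
        names = [a.name for a in self.attributes]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate attribute names in entity {self.name!r}")
        return self

    def declared_attributes(self) -> list[AttributeDef]:
        return [a for a in self.attributes if not a.generated]

    def generated_attributes(self) -> list[AttributeDef]:
        return [a for a in self.attributes if a.generated]


class SourceBinding(_Model):
    logical_name: str
    path: str
    role: Role
    key_columns: list[str] = Field(default_factory=list)
    timestamp_column: Optional[str] = None
    #: visit files only: column holding the end of the visit window
    end_column: Optional[str] = None

    @model_validator(mode="after")
    def _keys_required(self) -> "SourceBinding":
        if self.role in ("patient-file", "visit-file") and not self.key_columns:
            raise ValueError(f"{self.role} source {self.logical_name!r} needs key columns")
        return self


class FilterSpec(_Model):
    source: str
    column: str
    predicate: Literal["equals", "in-set", "numeric-range", "non-missing"]
    action: Literal["keep", "drop"] = "keep"
    value: Optional[str] = None
    values: Optional[list[str]] = None
    minimum: Optional[float] = None
    maximum: Optional[float] = None

    @model_validator(mode="after")
    def _args(self) -> "FilterSpec":
        if self.predicate == "equals" and self.value is None:
            raise ValueError("equals filter needs 'value'")
        if self.predicate == "in-set" and not self.values:
            raise ValueError("in-set filter needs 'values'")
        if self.predicate == "numeric-range" and self.minimum is None and self.maximum is None:
            raise ValueError("numeric-range filter needs 'minimum' and/or 'maximum'")
        return self


class CleansingOptions(_Model):
    duplicate_policy: Literal["keep-first"] = "keep-first"
    day_first: bool = True
    date_formats: list[str] = Field(default_factory=list)
    transmart_aggregation: Literal["latest", "first", "mean"] = "latest"
    strict: bool = False


class StagingConfig(_Model):
    study_label: str
    study_code: str
    sources: list[SourceBinding]
    entities: list[EntityDef]
    subject_key: KeySpec
    visit_key: Optional[KeySpec] = None
    missing_tokens: list[str] = Field(default_factory=lambda: sorted(DEFAULT_MISSING_TOKENS))
    filters: list[FilterSpec] = Field(default_factory=list)
    options: CleansingOptions = Field(default_factory=CleansingOptions)

    @field_validator("missing_tokens")
    @classmethod
    def _sort_tokens(cls, v: list[str]) -> list[str]:
        return sorted(set(v))

    @model_validator(mode="after")
    def _invariants(self) -> "StagingConfig":
        lowered = [e.name.casefold() for e in self.entities]
        dupes = sorted({n for n in lowered if lowered.count(n) > 1})
        if dupes:
            raise ValueError(f"duplicate entity names (case-insensitive): {', '.join(dupes)}")
        names = [s.logical_name for s in self.sources]
        if len(names) != len(set(names)):
            raise ValueError("duplicate source logical names")
        patients = [s for s in self.sources if s.role == "patient-file"]
        if len(patients) != 1:
            raise ValueError(f"exactly one patient-file source required, found {len(patients)}")
        visit_files = [s for s in self.sources if s.role == "visit-file"]
        if len(visit_files) > 1:
            raise ValueError("at most one visit-file source allowed")
        return self

    # -- convenience lookups -------------------------------------------------

    def source(self, logical_name: str) -> SourceBinding:
        for s in self.sources:
            if s.logical_name == logical_name:
                return s
        raise KeyError(logical_name)

    def patient_source(self) -> SourceBinding:
        return next(s for s in self.sources if s.role == "patient-file")

    def visit_source(self) -> SourceBinding | None:
        return next((s for s in self.sources if s.role == "visit-file"), None)


class ValidationFinding(_Model):
    code: str
    message: str


class ValidationReport(_Model):
    findings: list[ValidationFinding] = Field(default_factory=list)

    def add(self, code: str, message: str) -> None:
        self.findings.append(ValidationFinding(code=code, message=message))

    @property
    def ok(self) -> bool:
        return not self.findings

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "\n".join(f"[{f.code}] {f.message}" for f in self.findings) or "OK"


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------


def _meta_list(raw: Any, where: str) -> list[dict[str, str]]:
    """Meta entries may be plain column names or {name, column} mappings."""
    out = []
    for item in raw or []:
        if isinstance(item, str):
            out.append({"name": item, "column": item})
        elif isinstance(item, dict):
            out.append({"name": item.get("name", item.get("column")), "column": item.get("column", item.get("name"))})
        else:
            raise ConfigSchemaError(f"bad meta-attribute entry in {where}: {item!r}")
    return out


def parse_config(document: str) -> StagingConfig:
    """Parse a YAML configuration document into a validated :class:`StagingConfig`.

    Defaults (missing tokens, cleansing policies, label join) are filled in;
    unknown keys are rejected. Malformed YAML raises :class:`ConfigParseError`
    with line/column; schema violations raise :class:`ConfigSchemaError`.
    """
    try:
        raw = yaml.safe_load(document)
    except yaml.MarkedYAMLError as exc:
        mark = exc.problem_mark
        raise ConfigParseError(
            str(exc.problem or exc),
            line=None if mark is None else mark.line + 1,
            column=None if mark is None else mark.column + 1,
        ) from exc
    except yaml.YAMLError as exc:  # pragma: no cover - unmarked errors are rare
        raise ConfigParseError(str(exc)) from exc
    if not isinstance(raw, dict):
        raise ConfigSchemaError("configuration document must be a mapping")

    allowed = {"study", "sources", "entities", "options", "missing_tokens", "filters"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigSchemaError(f"unknown top-level keys: {', '.join(sorted(unknown))}")

    study = raw.get("study") or {}
    if not isinstance(study, dict) or "label" not in study:
        raise ConfigSchemaError("missing study.label")
    bad = set(study) - {"label", "code"}
    if bad:
        raise ConfigSchemaError(f"unknown keys under study: {', '.join(sorted(bad))}")

    sources_raw = raw.get("sources") or {}
    if not isinstance(sources_raw, dict) or not sources_raw:
        raise ConfigSchemaError("sources must be a non-empty mapping")
    sources: list[dict[str, Any]] = []
    for lname in sources_raw:  # YAML mapping order is preserved
        body = sources_raw[lname] or {}
        if not isinstance(body, dict):
            raise ConfigSchemaError(f"source {lname!r} must be a mapping")
        bad = set(body) - {"path", "role", "key", "timestamp", "end"}
        if bad:
            raise ConfigSchemaError(f"unknown keys under source {lname!r}: {', '.join(sorted(bad))}")
        sources.append(
            {
                "logical_name": lname,
                "path": body.get("path"),
                "role": body.get("role", "data-file"),
                "key_columns": body.get("key", []),
                "timestamp_column": body.get("timestamp"),
                "end_column": body.get("end"),
            }
        )

    entities: list[dict[str, Any]] = []
    for ent in raw.get("entities") or []:
        if not isinstance(ent, dict):
            raise ConfigSchemaError(f"entity entry must be a mapping: {ent!r}")
        bad = set(ent) - {"name", "anchor", "source", "attributes", "eav"}
        if bad:
            raise ConfigSchemaError(
                f"unknown keys under entity {ent.get('name')!r}: {', '.join(sorted(bad))}"
            )
        attrs = []
        for a in ent.get("attributes") or []:
            if isinstance(a, str):
                a = {"name": a, "column": a}
            bad = set(a) - {"name", "column", "type", "meta"}
            if bad:
                raise ConfigSchemaError(
                    f"unknown keys under attribute {a.get('name')!r}: {', '.join(sorted(bad))}"
                )
            attrs.append(
                {
                    "name": a.get("name", a.get("column")),
                    "column": a.get("column", a.get("name")),
                    "declared_type": a.get("type", "auto"),
                    "meta_attributes": _meta_list(a.get("meta"), f"attribute {a.get('name')!r}"),
                }
            )
        eav = ent.get("eav")
        if eav is not None:
            bad = set(eav) - {"parameters", "value", "meta", "label_join"}
            if bad:
                raise ConfigSchemaError(
                    f"unknown keys under eav of entity {ent.get('name')!r}: {', '.join(sorted(bad))}"
                )
            eav = {
                "parameter_columns": eav.get("parameters", []),
                "value_column": eav.get("value"),
                "meta_columns": _meta_list(eav.get("meta"), f"entity {ent.get('name')!r} eav"),
                "label_join": eav.get("label_join", "|"),
            }
        entities.append(
            {
                "name": ent.get("name"),
                "anchor": ent.get("anchor", "patient"),
                "source": ent.get("source"),
                "attributes": attrs,
                "eav": eav,
            }
        )

    patient = [s for s in sources if s["role"] == "patient-file"]
    visit = [s for s in sources if s["role"] == "visit-file"]
    payload: dict[str, Any] = {
        "study_label": str(study["label"]),
        "study_code": str(study.get("code", study["label"])),
        "sources": sources,
        "entities": entities,
        "subject_key": {"columns": patient[0]["key_columns"]} if patient and patient[0]["key_columns"] else None,
        "visit_key": {"columns": visit[0]["key_columns"]} if visit else None,
        "options": raw.get("options") or {},
        "filters": raw.get("filters") or [],
    }
    if payload["subject_key"] is None:
        raise ConfigSchemaError("the patient-file source must declare key columns")
    if "missing_tokens" in raw:
        payload["missing_tokens"] = [str(t) for t in raw["missing_tokens"]]
    try:
        return StagingConfig.model_validate(payload)
    except Exception as exc:
        raise ConfigSchemaError(str(exc)) from exc


def serialize_config(cfg: StagingConfig) -> str:
    """Render a :class:`StagingConfig` back to YAML; inverse of :func:`parse_config`."""
    doc: dict[str, Any] = {"study": {"label": cfg.study_label, "code": cfg.study_code}}
    sources: dict[str, Any] = {}
    for s in cfg.sources:
        body: dict[str, Any] = {"path": s.path, "role": s.role}
        if s.key_columns:
            body["key"] = list(s.key_columns)
        if s.timestamp_column:
            body["timestamp"] = s.timestamp_column
        if s.end_column:
            body["end"] = s.end_column
        sources[s.logical_name] = body
    doc["sources"] = sources
    ents = []
    for e in cfg.entities:
        body = {"name": e.name, "anchor": e.anchor, "source": e.source}
        attrs = []
        for a in e.declared_attributes():
            ab: dict[str, Any] = {"name": a.name, "column": a.column}
            if a.declared_type != "auto":
                ab["type"] = a.declared_type
            if a.meta_attributes:
                ab["meta"] = [{"name": m.name, "column": m.column} for m in a.meta_attributes]
            attrs.append(ab)
        if attrs:
            body["attributes"] = attrs
        if e.eav is not None:
            body["eav"] = {
                "parameters": list(e.eav.parameter_columns),
                "value": e.eav.value_column,
                "meta": [{"name": m.name, "column": m.column} for m in e.eav.meta_columns],
                "label_join": e.eav.label_join,
            }
        ents.append(body)
    doc["entities"] = ents
    doc["missing_tokens"] = list(cfg.missing_tokens)
    if cfg.filters:
        doc["filters"] = [f.model_dump(exclude_none=True) for f in cfg.filters]
    doc["options"] = cfg.options.model_dump()
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# validation against ingested headers
# ---------------------------------------------------------------------------


def validate_config(cfg: StagingConfig, headers: dict[str, list[str]]) -> ValidationReport:
    """Check every column/source reference against the ingested headers.

    Never raises: all findings are collected into the report, which is empty
    iff the configuration is executable against these sources.
    """
    report = ValidationReport()

    for s in cfg.sources:
        if s.logical_name not in headers:
            report.add("missing-source", f"source {s.logical_name!r} was not ingested")
            continue
        cols = set(headers[s.logical_name])
        for k in s.key_columns:
            if k not in cols:
                report.add("unresolved-column", f"key column {k!r} not in source {s.logical_name!r}")
        if s.timestamp_column and s.timestamp_column not in cols:
            report.add(
                "unresolved-column",
                f"timestamp column {s.timestamp_column!r} not in source {s.logical_name!r}",
            )
        if s.end_column and s.end_column not in cols:
            report.add(
                "unresolved-column",
                f"end column {s.end_column!r} not in source {s.logical_name!r}",
            )
    if not any(s.role == "patient-file" for s in cfg.sources):
        report.add("no-patient-file", "no source has role patient-file; one file must describe the patients")
    visit_file = cfg.visit_source()
    if visit_file is not None and visit_file.timestamp_column is None:
        report.add("missing-visit-start", f"visit-file {visit_file.logical_name!r} needs a timestamp (start) column")

    for e in cfg.entities:
        try:
            binding = cfg.source(e.source)
        except KeyError:
            report.add("unresolved-source", f"entity {e.name!r} references unknown source {e.source!r}")
            continue
        cols = set(headers.get(e.source, []))
        if not cols:
            continue
        for a in e.declared_attributes():
            if a.column not in cols:
                report.add(
                    "unresolved-column",
                    f"attribute {e.name}.{a.name} references column {a.column!r} absent from {e.source!r}",
                )
            for m in a.meta_attributes:
                if m.column not in cols:
                    report.add(
                        "unresolved-column",
                        f"meta-attribute {e.name}.{a.name}.{m.name} references column {m.column!r} absent from {e.source!r}",
                    )
        if e.eav is not None:
            for c in [*e.eav.parameter_columns, e.eav.value_column]:
                if c not in cols:
                    report.add(
                        "unresolved-column",
                        f"EAV column {c!r} of entity {e.name!r} absent from {e.source!r}",
                    )
            for m in e.eav.meta_columns:
                if m.column not in cols:
                    report.add(
                        "unresolved-column",
                        f"EAV meta column {m.column!r} of entity {e.name!r} absent from {e.source!r}",
                    )
        if e.anchor in ("visit", "encounter"):
            if cfg.visit_source() is None and binding.timestamp_column is None:
                report.add(
                    "unanchorable-entity",
                    f"entity {e.name!r} is visit-anchored but there is no visit-file and "
                    f"source {e.source!r} has no timestamp column for window linkage",
                )

    for f in cfg.filters:
        if f.source not in headers:
            report.add("unresolved-source", f"filter references unknown source {f.source!r}")
        elif f.column not in set(headers[f.source]):
            report.add(
                "unresolved-column", f"filter column {f.column!r} not in source {f.source!r}"
            )
    return report


# ---------------------------------------------------------------------------
# EAV expansion
# ---------------------------------------------------------------------------


def observed_parameter_labels(
    table: "SourceTable", eav: EavSpec, missing_tokens: set[str] | None = None
) -> tuple[list[str], int]:
    """Distinct normalized parameter labels observed in ``table``.

    Returns the sorted labels plus the number of rows excluded because at
    least one parameter cell was empty/missing. Labels combine the values of
    all parameter columns joined by ``eav.label_join``; each component is
    whitespace-normalized (case-sensitively) before distinctness.
    """
    tokens = {t.casefold() for t in (missing_tokens or DEFAULT_MISSING_TOKENS)}
    idx = [table.columns.index(c) for c in eav.parameter_columns]
    seen: set[str] = set()
    skipped = 0
    for row in table.rows:
        parts = []
        ok = True
        for i in idx:
            cell = row[i]
            if cell is None or cell.strip().casefold() in tokens:
                ok = False
                break
            parts.append(normalize_label(cell))
        if not ok:
            skipped += 1
            continue
        seen.add(eav.label_join.join(parts))
    return sorted(seen), skipped


def expand_eav_entities(
    cfg: StagingConfig,
    table: "SourceTable",
    log: "AnomalyLog | None" = None,
) -> StagingConfig:
    """Expand EAV specifications bound to ``table`` into generated attributes.

    Each distinct observed parameter-label combination yields one generated
    :class:`AttributeDef` carrying the EAV spec's meta columns. Declared
    attributes are untouched; generated attributes are sorted by name, so the
    result does not depend on row order, and re-running the expansion is a
    no-op. A generated name colliding with a declared attribute name is a
    hard error (silent overwrite would corrupt the ontology).
    """
    cfg = copy.deepcopy(cfg)
    tokens = set(cfg.missing_tokens)
    for entity in cfg.entities:
        if entity.eav is None or entity.source != table.logical_name:
            continue
        labels, skipped = observed_parameter_labels(table, entity.eav, tokens)
        if skipped and log is not None:
            log.add(
                "expand_eav",
                "empty-parameter",
                f"{skipped} row(s) of {table.logical_name!r} excluded from EAV expansion "
                f"of entity {entity.name!r} (empty parameter cell)",
                rows_skipped=skipped,
                entity=entity.name,
            )
        declared = {a.name for a in entity.declared_attributes()}
        collisions = sorted(set(labels) & declared)
        if collisions:
            raise ConfigSchemaError(
                f"generated EAV attribute(s) collide with declared attributes in "
                f"entity {entity.name!r}: {', '.join(collisions)}"
            )
        existing_generated = {a.name for a in entity.generated_attributes()}
        for label in labels:
            if label in existing_generated:
                continue
            entity.attributes.append(
                AttributeDef(
                    name=label,
                    column=entity.eav.value_column,
                    declared_type="auto",
                    meta_attributes=[m.model_copy() for m in entity.eav.meta_columns],
                    generated=True,
                )
            )
        entity.attributes = entity.declared_attributes() + sorted(
            entity.generated_attributes(), key=lambda a: a.name
        )
    return cfg
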