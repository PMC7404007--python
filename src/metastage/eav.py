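"""Denormalize EAV-shaped tables into per-parameter attribute records.

An EAV ("long") table names a parameter in each row and carries its value —
the layout laboratory systems use when many possible observations apply
sparsely. Staging pivots each such row into one record for the generated
attribute matching the row's (combined) parameter label, carrying any
meta-attribute values present on the same row. Declared ("wide") entities
are handled by the dual operation: one record per row and attribute column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import EntityDef, SourceBinding, StagingConfig
from .report import AnomalyLog
from ._util import normalize_label
from .ingest import SourceTable


@dataclass
class AttributeRecord:
    entity: str
    attribute: str
    subject_key_values: tuple[str, ...] | None
    visit_key_values: tuple[str, ...] | None
    value: str
    meta_values: dict[str, str] = field(default_factory=dict)
    timestamp_token: str | None = None
    provenance: tuple[str, int] = ("", 0)


def _key_tuples(
    table: SourceTable,
    binding: SourceBinding,
    cfg: StagingConfig,
    entity: EntityDef,
    row: list[str | None],
) -> tuple[tuple[str, ...] | None, tuple[str, ...] | None]:
    """Extract (subject_key_values, visit_key_values) for one row.

    A visit-anchored entity's binding keys identify the visit; the subject is
    resolved through the visit later (or directly when the subject key
    columns also appear in this table). A patient-anchored entity's binding
    keys identify the subject.
    """
    def grab(columns: list[str]) -> tuple[str, ...] | None:
        vals = []
        for c in columns:
            if c not in table.columns:
                return None
            v = row[table.column_index(c)]
            if v is None:
                return None
            vals.append(v)
        return tuple(vals)

    if entity.anchor in ("visit", "encounter"):
        visit = grab(binding.key_columns) if binding.key_columns else None
        subject = grab(cfg.subject_key.columns)
        return subject, visit
    return grab(binding.key_columns or cfg.subject_key.columns), None


def denormalize_eav(
    table: SourceTable,
    entity: EntityDef,
    cfg: StagingConfig,
    log: AnomalyLog | None = None,
) -> tuple[list[AttributeRecord], dict[str, int]]:
    """Pivot an EAV table: one record per row with parameter and value present.

    Rows whose parameter or value cell is missing are skipped and counted by
    reason. Meta cells that are missing simply leave the meta key absent. A
    parameter label not in the expanded attribute catalog (possible when
    expansion sampled a different file) is admitted on the fly and logged —
    agility over strictness.
    """
    assert entity.eav is not None, "entity has no EAV spec"
    eav = entity.eav
    binding = cfg.source(entity.source)
    catalog = {a.name for a in entity.attributes if a.generated}
    param_idx = [table.column_index(c) for c in eav.parameter_columns]
    value_idx = table.column_index(eav.value_column)
    meta_idx = [(m.name, table.column_index(m.column)) for m in eav.meta_columns]
    ts_idx = (
        table.column_index(binding.timestamp_column)
        if binding.timestamp_column and binding.timestamp_column in table.columns
        else None
    )

    records: list[AttributeRecord] = []
    skipped = {"missing_parameter": 0, "missing_value": 0}
    for row, row_id in zip(table.rows, table.row_ids):
        parts = [row[i] for i in param_idx]
        if any(p is None for p in parts):
            skipped["missing_parameter"] += 1
            continue
        value = row[value_idx]
        if value is None:
            skipped["missing_value"] += 1
            continue
        label = eav.label_join.join(normalize_label(p) for p in parts)  # type: ignore[arg-type]
        if label not in catalog:
            catalog.add(label)
            if log is not None:
                log.add(
                    "eav",
                    "unlisted-parameter",
                    f"parameter {label!r} observed in {table.logical_name!r} row {row_id} "
                    f"but absent from the expanded catalog; admitted on the fly",
                    entity=entity.name,
                    row_id=row_id,
                )
        subject, visit = _key_tuples(table, binding, cfg, entity, row)
        meta = {name: row[i] for name, i in meta_idx if row[i] is not None}
        records.append(
            AttributeRecord(
                entity=entity.name,
                attribute=label,
                subject_key_values=subject,
                visit_key_values=visit,
                value=value,
                meta_values=meta,  # type: ignore[arg-type]
                timestamp_token=row[ts_idx] if ts_idx is not None else None,
                provenance=(table.logical_name, row_id),
            )
        )
    return records, skipped


def widen_declared(
    table: SourceTable,
    entity: EntityDef,
    cfg: StagingConfig,
) -> list[AttributeRecord]:
    """One record per (row, declared attribute with a non-missing cell)."""
    binding = cfg.source(entity.source)
    ts_idx = (
        table.column_index(binding.timestamp_column)
        if binding.timestamp_column and binding.timestamp_column in table.columns
        else None
    )
    records: list[AttributeRecord] = []
    for row, row_id in zip(table.rows, table.row_ids):
        subject, visit = _key_tuples(table, binding, cfg, entity, row)
        for attr in entity.attributes:
            if attr.generated:
                continue
            value = row[table.column_index(attr.column)]
            if value is None:
                continue
            meta = {}
            for m in attr.meta_attributes:
                v = row[table.column_index(m.column)]
                if v is not None:
                    meta[m.name] = v
            records.append(
                AttributeRecord(
                    entity=entity.name,
                    attribute=attr.name,
                    subject_key_values=subject,
                    visit_key_values=visit,
                    value=value,
                    meta_values=meta,
                    timestamp_token=row[ts_idx] if ts_idx is not None else None,
                    provenance=(table.logical_name, row_id),
                )
            )
    return records
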