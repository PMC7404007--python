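"""End-to-end staging orchestration.

``run_staging`` drives the whole staging phase in memory — extraction
(ingest + validation), transformation (missing-value normalization,
filtering, EAV expansion, record building, profiling, subject/visit/fact
assembly, deduplication) — and returns a :class:`StagingResult` that the
emitters compile into back-end bundles. ``stage`` adds the writing phase
and the machine-readable run report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .backends import (
    AggregationReport,
    StagingBundle,
    emit_i2b2_bundle,
    emit_transmart_bundle,
    write_bundle,
)
from .cleanse import (
    ColumnProfile,
    apply_filters,
    normalize_table_missing,
    profile_column,
)
from .config import StagingConfig, expand_eav_entities, parse_config, validate_config
from .eav import AttributeRecord, denormalize_eav, widen_declared
from .errors import ConfigSchemaError, StrictModeError
from .facts import DedupReport, Fact, Subject, Visit, assemble_facts, build_subjects, build_visits
from .ingest import SourceTable, read_table
from .ontology import OntologyTree, assign_codes, build_ontology
from .report import AnomalyLog

TARGETS = ("i2b2", "transmart")


@dataclass
class StagingResult:
    cfg: StagingConfig  # EAV-expanded
    tables: dict[str, SourceTable]
    subjects: list[Subject]
    subject_ids: dict[tuple[str, ...], str]
    visits: list[Visit]
    facts: list[Fact]
    dedup: DedupReport
    tree: OntologyTree
    profiles: dict[tuple[str, str], ColumnProfile]
    log: AnomalyLog
    counts: dict[str, int] = field(default_factory=dict)


def ingest_sources(
    cfg: StagingConfig, base_dir: str | Path, log: AnomalyLog, strict: bool = False
) -> dict[str, SourceTable]:
    base_dir = Path(base_dir)
    tables: dict[str, SourceTable] = {}
    for binding in cfg.sources:
        tables[binding.logical_name] = read_table(
            base_dir / binding.path, binding, log=log, strict=strict
        )
    return tables


def run_staging(
    cfg: StagingConfig,
    base_dir: str | Path,
    log: AnomalyLog | None = None,
    strict: bool = False,
) -> StagingResult:
    """Run extraction and transformation; raise on validation findings."""
    log = log if log is not None else AnomalyLog()
    tables = ingest_sources(cfg, base_dir, log, strict=strict)

    report = validate_config(cfg, {name: t.columns for name, t in tables.items()})
    if not report.ok:
        raise ConfigSchemaError("configuration is not executable:\n" + str(report))

    rows_read = sum(len(t.rows) for t in tables.values())
    missing_total = 0
    tokens = set(cfg.missing_tokens)
    for name in tables:
        tables[name], n = normalize_table_missing(tables[name], tokens)
        missing_total += n

    rows_filtered = 0
    if cfg.filters:
        for name in tables:
            relevant_cols = [f.column for f in cfg.filters if f.source == name]
            col_profiles = {
                c: profile_column(tables[name].column_values(c), cfg.options)
                for c in relevant_cols
                if c in tables[name].columns
            }
            tables[name], removed = apply_filters(tables[name], cfg.filters, col_profiles)
            rows_filtered += removed
            if removed:
                log.add("filter", "rows-removed", f"{removed} row(s) removed from {name!r} by filters",
                        severity="info", source=name, removed=removed)

    for entity in cfg.entities:
        if entity.eav is not None:
            cfg = expand_eav_entities(cfg, tables[entity.source], log)

    records: list[AttributeRecord] = []
    skip_counts: dict[str, int] = {}
    for entity in cfg.entities:
        table = tables[entity.source]
        if entity.eav is not None:
            recs, skipped = denormalize_eav(table, entity, cfg, log)
            for reason, n in skipped.items():
                skip_counts[reason] = skip_counts.get(reason, 0) + n
        else:
            recs = widen_declared(table, entity, cfg)
        records.extend(recs)

    # per-attribute value profiles (EAV attributes are profiled per parameter,
    # not per raw column — a lab table's Result column mixes all parameters)
    values: dict[tuple[str, str], list] = {}
    for rec in records:
        values.setdefault((rec.entity, rec.attribute), []).append(rec.value)
    profiles: dict[tuple[str, str], ColumnProfile] = {
        key: profile_column(cells, cfg.options) for key, cells in values.items()
    }
    for entity in cfg.entities:
        for attr in entity.attributes:
            if attr.declared_type != "auto":
                key = (entity.name, attr.name)
                if key in profiles:
                    profiles[key].inferred_type = attr.declared_type
                else:
                    profiles[key] = ColumnProfile(attr.declared_type, 0.0, 0.0)

    patient_binding = cfg.patient_source()
    subjects, subject_ids = build_subjects(
        tables[patient_binding.logical_name], cfg.subject_key, cfg.study_code, log
    )
    visits: list[Visit] = []
    visit_binding = cfg.visit_source()
    if visit_binding is not None and cfg.visit_key is not None:
        visits = build_visits(
            tables[visit_binding.logical_name],
            cfg.visit_key,
            cfg.subject_key,
            subject_ids,
            cfg.study_code,
            cfg.options,
            start_column=visit_binding.timestamp_column,
            end_column=visit_binding.end_column,
            log=log,
        )

    tree = assign_codes(build_ontology(cfg, profiles), log)
    facts = assemble_facts(records, subject_ids, visits, profiles, cfg, log)
    facts, dedup = deduplicate(facts, cfg, log)

    counts = {
        "rows_read": rows_read,
        "rows_filtered": rows_filtered,
        "missing_cells": missing_total,
        "records": len(records),
        "subjects": len(subjects),
        "visits": len(visits),
        "facts": len(facts),
        "duplicates_dropped": dedup.exact_duplicates_dropped,
        "conflicts": len(dedup.conflicts),
        **{f"skipped_{k}": v for k, v in skip_counts.items()},
    }
    return StagingResult(
        cfg=cfg, tables=tables, subjects=subjects, subject_ids=subject_ids,
        visits=visits, facts=facts, dedup=dedup, tree=tree, profiles=profiles,
        log=log, counts=counts,
    )


def deduplicate(facts, cfg, log):
    from .facts import deduplicate_facts

    return deduplicate_facts(facts, cfg.options.duplicate_policy, log)


def emit(
    result: StagingResult, target: str
) -> tuple[StagingBundle, AggregationReport | None]:
    if target == "i2b2":
        return (
            emit_i2b2_bundle(
                result.subjects, result.visits, result.facts, result.tree, result.cfg, result.log
            ),
            None,
        )
    if target == "transmart":
        bundle, agg = emit_transmart_bundle(
            result.subjects, result.facts, result.tree, result.cfg, log=result.log
        )
        return bundle, agg
    raise ValueError(f"unknown target {target!r} (expected one of {TARGETS})")


def stage(
    config_path: str | Path,
    targets: tuple[str, ...] = TARGETS,
    out_dir: str | Path = "staged",
    force: bool = False,
    strict: bool = False,
) -> dict:
    """Full staging run: parse config, stage, write bundles, return the run report.

    Nothing is written if validation fails or (in strict mode) any
    warning-level anomaly was logged.
    """
    config_path = Path(config_path)
    cfg = parse_config(config_path.read_text(encoding="utf-8"))
    strict = strict or cfg.options.strict
    log = AnomalyLog()
    # strict mode fails on *logged* warnings after the run, so one invocation
    # reports every anomaly instead of dying on the first
    result = run_staging(cfg, config_path.parent, log=log)
    if strict and log.warnings():
        raise StrictModeError(
            f"{len(log.warnings())} warning(s) in strict mode; first: "
            f"{log.warnings()[0].message}"
        )

    out_dir = Path(out_dir)
    run_report: dict = {
        "version": __version__,
        "config": str(config_path.name),
        "targets": list(targets),
        "counts": result.counts,
        "warnings": len(log.warnings()),
        "bundles": {},
    }
    for target in targets:
        bundle, agg = emit(result, target)
        manifest_path = write_bundle(bundle, out_dir / target, force=force)
        run_report["bundles"][target] = {
            "manifest": str(Path(target) / "manifest.json"),
            "counts": bundle.manifest["counts"],
        }
        if agg is not None:
            run_report["bundles"][target]["aggregation"] = {
                "policy": agg.policy,
                "collapsed": agg.total,
            }
        del manifest_path
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(run_report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out_dir / "anomalies.jsonl").write_text(log.to_jsonl(), encoding="utf-8")
    return run_report
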