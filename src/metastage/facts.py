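"""Canonical subject/visit/fact model: keys, linkage, typing, deduplication.

Subjects come from the mandatory patient file, visits from the optional
visit file. Attribute records are then resolved into facts: the subject by
key, the visit by key when present or else by timestamp containment within
exactly one of the subject's visit windows (never guessing among several
candidates), and the value typed according to its attribute's profile.
Exact duplicate facts collapse to one; facts sharing a key but disagreeing
in value are resolved keep-first with a logged conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import CleansingOptions, KeySpec, StagingConfig
from .cleanse import ColumnProfile, Timestamp, parse_timestamp
from .errors import TimestampError
from .eav import AttributeRecord
from .ontology import concept_path
from .report import AnomalyLog
from ._util import canonical_number, sanitize_id


@dataclass
class Subject:
    subject_id: str
    key_values: tuple[str, ...]
    attributes: dict[str, str] = field(default_factory=dict)


@dataclass
class Visit:
    visit_id: str
    subject_id: str
    start: Timestamp
    end: Optional[Timestamp] = None
    key_values: tuple[str, ...] = ()


@dataclass
class Fact:
    subject_id: str
    visit_id: Optional[str]
    concept_path: str
    value: str
    value_type: str
    timestamp: Optional[Timestamp] = None
    modifiers: dict[str, str] = field(default_factory=dict)
    provenance: tuple[str, int] = ("", 0)

    def dedup_key(self) -> tuple:
        """Identity *excluding* the value: two facts with this key equal are
        either exact duplicates or a conflict."""
        return (
            self.subject_id,
            self.visit_id,
            self.concept_path,
            self.timestamp.render() if self.timestamp else None,
            tuple(sorted(self.modifiers.items())),
        )

    def exact_key(self) -> tuple:
        return self.dedup_key() + (self.value_type, self.value)


@dataclass
class DedupReport:
    exact_duplicates_dropped: int = 0
    conflicts: list[tuple] = field(default_factory=list)
    policy: str = "keep-first"


def canonical_id(study_code: str, key_values: tuple[str, ...]) -> str:
    """Stable id: sanitized source keys joined by "_", prefixed by the study code."""
    return "_".join([sanitize_id(study_code), *(sanitize_id(v) for v in key_values)])


# ---------------------------------------------------------------------------
# subjects / visits
# ---------------------------------------------------------------------------


def build_subjects(
    patient_table,
    key: KeySpec,
    study_code: str,
    log: AnomalyLog | None = None,
) -> tuple[list[Subject], dict[tuple[str, ...], str]]:
    """One subject per distinct key tuple of the patient file.

    Rows with a missing key cell are rejected. Duplicate key rows are merged:
    contradictory non-key cells keep the first value and log a conflict.
    """
    idx = [patient_table.column_index(c) for c in key.columns]
    other = [
        (c, j) for j, c in enumerate(patient_table.columns) if j not in idx
    ]
    subjects: dict[tuple[str, ...], Subject] = {}
    for row, row_id in zip(patient_table.rows, patient_table.row_ids):
        key_vals = tuple(row[i] for i in idx)
        if any(v is None for v in key_vals):
            if log is not None:
                log.add(
                    "subjects", "missing-key",
                    f"{patient_table.logical_name} row {row_id}: missing subject key cell; row rejected",
                    row_id=row_id,
                )
            continue
        key_vals = tuple(str(v) for v in key_vals)
        attrs = {c: row[j] for c, j in other if row[j] is not None}
        existing = subjects.get(key_vals)
        if existing is None:
            subjects[key_vals] = Subject(
                subject_id=canonical_id(study_code, key_vals),
                key_values=key_vals,
                attributes=attrs,
            )
            continue
        for c, v in attrs.items():
            if c not in existing.attributes:
                existing.attributes[c] = v
            elif existing.attributes[c] != v and log is not None:
                log.add(
                    "subjects", "conflict",
                    f"subject {existing.subject_id}: contradictory {c!r} "
                    f"({existing.attributes[c]!r} kept, {v!r} from row {row_id} discarded)",
                    row_id=row_id,
                )
    id_map = {k: s.subject_id for k, s in subjects.items()}
    return list(subjects.values()), id_map


def build_visits(
    visit_table,
    key: KeySpec,
    subject_key: KeySpec,
    subject_ids: dict[tuple[str, ...], str],
    study_code: str,
    options: CleansingOptions | None = None,
    start_column: str | None = None,
    end_column: str | None = None,
    log: AnomalyLog | None = None,
) -> list[Visit]:
    """Build visits linked to existing subjects.

    A visit whose end precedes its start is rejected as an inconsistent
    timestamp; a visit referencing an unknown subject is an orphan and also
    rejected. Duplicate visit keys keep the first occurrence.
    """
    options = options or CleansingOptions()
    idx = [visit_table.column_index(c) for c in key.columns]
    sub_idx = [
        visit_table.column_index(c) for c in subject_key.columns if c in visit_table.columns
    ]
    start_i = visit_table.column_index(start_column) if start_column else None
    end_i = visit_table.column_index(end_column) if end_column and end_column in visit_table.columns else None

    visits: dict[tuple[str, ...], Visit] = {}
    for row, row_id in zip(visit_table.rows, visit_table.row_ids):
        key_vals = tuple(row[i] for i in idx)
        if any(v is None for v in key_vals):
            _log(log, "visits", "missing-key", visit_table, row_id, "missing visit key cell")
            continue
        key_vals = tuple(str(v) for v in key_vals)
        subj_vals = tuple(str(row[i]) for i in sub_idx) if sub_idx else None
        if subj_vals is None or any(v is None for v in subj_vals) or subj_vals not in subject_ids:
            _log(log, "visits", "orphan-visit", visit_table, row_id,
                 f"visit references unknown subject {subj_vals!r}")
            continue
        start = end = None
        if start_i is not None and row[start_i] is not None:
            try:
                start = parse_timestamp(row[start_i], options)
            except TimestampError as exc:
                _log(log, "visits", "bad-timestamp", visit_table, row_id, str(exc))
                continue
        if start is None:
            _log(log, "visits", "missing-start", visit_table, row_id, "visit has no start timestamp")
            continue
        if end_i is not None and row[end_i] is not None:
            try:
                end = parse_timestamp(row[end_i], options)
            except TimestampError as exc:
                _log(log, "visits", "bad-timestamp", visit_table, row_id, str(exc))
                continue
        if end is not None and end.instant < start.instant:
            _log(log, "visits", "inconsistent-timestamp", visit_table, row_id,
                 f"visit end {end.original!r} precedes start {start.original!r}; visit rejected")
            continue
        if key_vals in visits:
            _log(log, "visits", "duplicate-visit", visit_table, row_id,
                 f"duplicate visit key {key_vals!r}; first occurrence kept")
            continue
        visits[key_vals] = Visit(
            visit_id=canonical_id(study_code, key_vals),
            subject_id=subject_ids[subj_vals],
            start=start,
            end=end,
            key_values=key_vals,
        )
    return list(visits.values())


def _log(log, stage, kind, table, row_id, message):
    if log is not None:
        log.add(stage, kind, f"{table.logical_name} row {row_id}: {message}", row_id=row_id)


# ---------------------------------------------------------------------------
# facts
# ---------------------------------------------------------------------------


def _type_value(value: str, profile: ColumnProfile | None, options: CleansingOptions) -> tuple[str, str]:
    """Return (canonical value, value_type) under the attribute's profile."""
    if profile is not None and profile.inferred_type == "numeric":
        try:
            return canonical_number(value, profile.decimal_separator), "numeric"
        except ValueError:
            return value, "text"
    if profile is not None and profile.inferred_type == "date":
        try:
            return parse_timestamp(value, options).render(), "date"
        except TimestampError:
            return value, "text"
    if profile is not None and profile.inferred_type == "categorical":
        return value, "categorical"
    return value, "text"


def assemble_facts(
    records: list[AttributeRecord],
    subjects: dict[tuple[str, ...], str],
    visits: list[Visit],
    profiles: dict[tuple[str, str], ColumnProfile],
    cfg: StagingConfig,
    log: AnomalyLog | None = None,
) -> list[Fact]:
    """Resolve attribute records into typed facts.

    Visit linkage: by visit key when the record carries one; otherwise by
    timestamp containment in exactly one of the subject's visit windows
    (zero or several candidate windows leave the fact unlinked, logged). A
    record whose subject cannot be resolved is rejected.
    """
    options = cfg.options
    visit_by_key = {v.key_values: v for v in visits}
    visits_by_subject: dict[str, list[Visit]] = {}
    for v in visits:
        visits_by_subject.setdefault(v.subject_id, []).append(v)

    facts: list[Fact] = []
    for rec in records:
        visit: Visit | None = None
        if rec.visit_key_values is not None:
            visit = visit_by_key.get(rec.visit_key_values)
            if visit is None:
                if log is not None:
                    log.add(
                        "facts", "unknown-visit",
                        f"{rec.provenance[0]} row {rec.provenance[1]}: visit key "
                        f"{rec.visit_key_values!r} unknown; fact left unlinked",
                        row_id=rec.provenance[1],
                    )
        subject_id: str | None = None
        if rec.subject_key_values is not None:
            subject_id = subjects.get(rec.subject_key_values)
        if subject_id is None and visit is not None:
            subject_id = visit.subject_id
        if subject_id is None:
            if log is not None:
                log.add(
                    "facts", "unknown-subject",
                    f"{rec.provenance[0]} row {rec.provenance[1]}: subject key "
                    f"{rec.subject_key_values!r} unknown; record rejected",
                    row_id=rec.provenance[1],
                )
            continue

        timestamp: Timestamp | None = None
        if rec.timestamp_token is not None:
            try:
                timestamp = parse_timestamp(rec.timestamp_token, options)
            except TimestampError as exc:
                if log is not None:
                    log.add(
                        "facts", "bad-timestamp",
                        f"{rec.provenance[0]} row {rec.provenance[1]}: {exc}; "
                        "fact kept without timestamp",
                        row_id=rec.provenance[1],
                    )

        if visit is None and rec.visit_key_values is None and timestamp is not None:
            candidates = [
                v
                for v in visits_by_subject.get(subject_id, [])
                if v.start.instant <= timestamp.instant
                and (v.end is None or timestamp.instant <= v.end.instant)
            ]
            if len(candidates) == 1:
                visit = candidates[0]
            elif len(candidates) > 1 and log is not None:
                log.add(
                    "facts", "ambiguous-visit",
                    f"{rec.provenance[0]} row {rec.provenance[1]}: timestamp falls in "
                    f"{len(candidates)} visit windows; fact left unlinked",
                    row_id=rec.provenance[1],
                )
        elif (
            visit is not None
            and timestamp is not None
            and log is not None
            and (
                timestamp.instant < visit.start.instant
                or (visit.end is not None and timestamp.instant > visit.end.instant)
            )
        ):
            # key-based linkage stands, but the timestamp disagrees with the window
            log.add(
                "facts", "timestamp-outside-visit",
                f"{rec.provenance[0]} row {rec.provenance[1]}: timestamp "
                f"{timestamp.original!r} outside visit window of {visit.visit_id}",
                row_id=rec.provenance[1],
            )

        value, value_type = _type_value(rec.value, profiles.get((rec.entity, rec.attribute)), options)
        facts.append(
            Fact(
                subject_id=subject_id,
                visit_id=visit.visit_id if visit is not None else None,
                concept_path=concept_path(cfg.study_label, rec.entity, rec.attribute),
                value=value,
                value_type=value_type,
                timestamp=timestamp,
                modifiers=dict(rec.meta_values),
                provenance=rec.provenance,
            )
        )
    return facts


def deduplicate_facts(
    facts: list[Fact], policy: str = "keep-first", log: AnomalyLog | None = None
) -> tuple[list[Fact], DedupReport]:
    """Collapse exact duplicates; resolve same-key/different-value conflicts.

    The duplicate key includes the modifiers: two lab results differing only
    in their unit are distinct facts. Idempotent, and conserving:
    ``len(in) == len(out) + dropped + len(conflicts)``.
    """
    report = DedupReport(policy=policy)
    kept: dict[tuple, Fact] = {}
    for fact in facts:
        exact = fact.exact_key()
        key = fact.dedup_key()
        prior = kept.get(key)
        if prior is None:
            kept[key] = fact
        elif prior.exact_key() == exact:
            report.exact_duplicates_dropped += 1
        else:
            report.conflicts.append((key, prior.value, fact.value))
            if log is not None:
                log.add(
                    "dedup", "value-conflict",
                    f"conflicting values for {fact.concept_path} of {fact.subject_id}: "
                    f"{prior.value!r} kept, {fact.value!r} discarded (keep-first)",
                )
    return list(kept.values()), report
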