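"""Subject/visit building, fact assembly, linkage, deduplication."""

import pytest

from metastage.cleanse import ColumnProfile, parse_timestamp
from metastage.config import CleansingOptions, KeySpec, parse_config
from metastage.eav import AttributeRecord
from metastage.facts import (
    Fact,
    assemble_facts,
    build_subjects,
    build_visits,
    canonical_id,
    deduplicate_facts,
)
from metastage.report import AnomalyLog

from conftest import make_table

import textwrap

CFG = parse_config(textwrap.dedent("""
    study: {label: S, code: S}
    sources:
      patients: {path: p.csv, role: patient-file, key: [pid]}
      visits: {path: v.csv, role: visit-file, key: [pid, vid],
               timestamp: start, end: end}
      obs: {path: o.csv, role: data-file, key: [pid], timestamp: date}
    entities:
      - name: Obs
        anchor: patient
        source: obs
        attributes: [{name: score, column: score}]
    """))


class TestBuildSubjects:
    def test_distinct_keys_make_distinct_subjects(self):
        table = make_table("patients", ["pid", "sex"], [[f"P{i}", "M"] for i in range(5)])
        subjects, id_map = build_subjects(table, KeySpec(columns=["pid"]), "S")
        assert len(subjects) == 5 and len(id_map) == 5
        assert id_map[("P0",)] == "S_P0"

    def test_identical_duplicate_rows_merge_silently(self):
        table = make_table("patients", ["pid", "sex"], [["P1", "M"], ["P1", "M"]])
        log = AnomalyLog()
        subjects, _ = build_subjects(table, KeySpec(columns=["pid"]), "S", log)
        assert len(subjects) == 1 and log.count(kind="conflict") == 0

    def test_contradictory_demographics_keep_first_and_log(self):
        table = make_table("patients", ["pid", "birth"], [["P1", "1960"], ["P1", "1961"]])
        log = AnomalyLog()
        subjects, _ = build_subjects(table, KeySpec(columns=["pid"]), "S", log)
        assert subjects[0].attributes["birth"] == "1960"
        assert log.count(kind="conflict") == 1

    def test_missing_key_row_rejected(self):
        table = make_table("patients", ["pid", "sex"], [[None, "M"], ["P1", "F"]])
        log = AnomalyLog()
        subjects, _ = build_subjects(table, KeySpec(columns=["pid"]), "S", log)
        assert len(subjects) == 1 and log.count(kind="missing-key") == 1

    def test_canonical_ids_sanitized_and_prefixed(self):
        assert canonical_id("ST", ("P 1/A",)) == "ST_P_1_A"


def _subjects():
    table = make_table("patients", ["pid"], [["P1"], ["P2"], ["P3"]])
    return build_subjects(table, KeySpec(columns=["pid"]), "S")


class TestBuildVisits:
    def _visits(self, rows, log=None):
        _, ids = _subjects()
        table = make_table("visits", ["pid", "vid", "start", "end"], rows)
        return build_visits(table, KeySpec(columns=["pid", "vid"]), KeySpec(columns=["pid"]),
                            ids, "S", start_column="start", end_column="end", log=log)

    def test_visits_linked_to_known_subjects(self):
        visits = self._visits([["P1", "V1", "2020-01-01", "2020-01-05"],
                               ["P2", "V1", "2020-02-01", None],
                               ["P3", "V1", "2020-03-01", "2020-03-02"]])
        assert len(visits) == 3
        assert {v.subject_id for v in visits} == {"S_P1", "S_P2", "S_P3"}

    def test_end_before_start_rejected_as_inconsistent(self):
        log = AnomalyLog()
        visits = self._visits([["P1", "V1", "2020-01-05", "2020-01-01"]], log)
        assert visits == [] and log.count(kind="inconsistent-timestamp") == 1

    def test_orphan_visit_rejected(self):
        log = AnomalyLog()
        visits = self._visits([["P9", "V1", "2020-01-01", None]], log)
        assert visits == [] and log.count(kind="orphan-visit") == 1

    def test_no_visit_table_means_empty_list(self):
        # pipeline proceeds with an empty visit list; facts stay unlinked
        _, ids = _subjects()
        record = AttributeRecord("Obs", "score", ("P1",), None, "5", provenance=("o.csv", 2))
        facts = assemble_facts([record], ids, [], {}, CFG)
        assert facts[0].visit_id is None


class TestAssembleFacts:
    def _setup(self):
        subjects, ids = _subjects()
        table = make_table("visits", ["pid", "vid", "start", "end"],
                           [["P1", "V1", "2020-01-01", "2020-01-05"],
                            ["P1", "V2", "2020-02-01", "2020-02-05"]])
        visits = build_visits(table, KeySpec(columns=["pid", "vid"]), KeySpec(columns=["pid"]),
                              ids, "S", start_column="start", end_column="end")
        return ids, visits

    def test_visit_key_linkage(self):
        ids, visits = self._setup()
        rec = AttributeRecord("Obs", "score", ("P1",), ("P1", "V2"), "5")
        facts = assemble_facts([rec], ids, visits, {}, CFG)
        assert facts[0].visit_id == "S_P1_V2"

    def test_timestamp_containment_links_unique_window(self):
        ids, visits = self._setup()
        rec = AttributeRecord("Obs", "score", ("P1",), None, "5", timestamp_token="2020-01-03")
        facts = assemble_facts([rec], ids, visits, {}, CFG)
        assert facts[0].visit_id == "S_P1_V1"
        # exhaustive oracle: windows containing the instant
        instant = parse_timestamp("2020-01-03").instant
        containing = [v for v in visits if v.subject_id == "S_P1"
                      and v.start.instant <= instant <= v.end.instant]
        assert [facts[0].visit_id] == [v.visit_id for v in containing]

    @pytest.mark.parametrize("token", ["2020-03-15", "2020-01-05"])
    def test_zero_or_multiple_windows_leave_fact_unlinked(self, token):
        ids, visits = self._setup()
        # second case: make windows overlap so the timestamp is ambiguous
        if token == "2020-01-05":
            table = make_table("visits", ["pid", "vid", "start", "end"],
                               [["P1", "V1", "2020-01-01", "2020-01-10"],
                                ["P1", "V2", "2020-01-04", "2020-01-12"]])
            visits = build_visits(table, KeySpec(columns=["pid", "vid"]),
                                  KeySpec(columns=["pid"]), ids, "S",
                                  start_column="start", end_column="end")
        log = AnomalyLog()
        rec = AttributeRecord("Obs", "score", ("P1",), None, "5", timestamp_token=token)
        facts = assemble_facts([rec], ids, visits, {}, CFG, log)
        assert facts[0].visit_id is None
        if token == "2020-01-05":
            assert log.count(kind="ambiguous-visit") == 1

    def test_unknown_subject_rejected(self):
        ids, visits = self._setup()
        log = AnomalyLog()
        rec = AttributeRecord("Obs", "score", ("P9",), None, "5")
        facts = assemble_facts([rec], ids, visits, {}, CFG, log)
        assert facts == [] and log.count(kind="unknown-subject") == 1

    def test_value_typed_by_profile(self):
        ids, visits = self._setup()
        profiles = {("Obs", "score"): ColumnProfile("numeric", 1.0, 0.0, decimal_separator=",")}
        rec = AttributeRecord("Obs", "score", ("P1",), None, "7,5")
        facts = assemble_facts([rec], ids, visits, profiles, CFG)
        assert facts[0].value == "7.5" and facts[0].value_type == "numeric"


def _fact(value="140", ts="2020-01-01", mods=None, subject="S_P1"):
    return Fact(
        subject_id=subject, visit_id=None, concept_path="\\S\\Obs\\score\\",
        value=value, value_type="numeric",
        timestamp=parse_timestamp(ts) if ts else None,
        modifiers=mods or {},
    )


class TestDeduplicateFacts:
    def test_injected_exact_duplicates_all_dropped(self):
        clean = [_fact(value=str(i), ts=f"2020-01-{i + 1:02d}") for i in range(10)]
        for k in (1, 5):
            facts = clean + [clean[0]] * k
            out, report = deduplicate_facts(facts)
            assert len(out) == len(clean)
            assert report.exact_duplicates_dropped == k

    def test_same_key_different_value_keeps_first(self):
        out, report = deduplicate_facts([_fact("140"), _fact("141")])
        assert [f.value for f in out] == ["140"]
        assert len(report.conflicts) == 1

    def test_differing_modifiers_are_distinct_facts(self):
        a = _fact(mods={"Unit": "mg/dL"})
        b = _fact(mods={"Unit": "mmol/L"})
        out, report = deduplicate_facts([a, b])
        assert len(out) == 2 and report.exact_duplicates_dropped == 0

    def test_no_duplicates_is_identity(self):
        facts = [_fact(value=str(i), ts=f"2020-01-{i + 1:02d}") for i in range(5)]
        out, report = deduplicate_facts(facts)
        assert out == facts
        assert report.exact_duplicates_dropped == 0 and report.conflicts == []

    def test_idempotence_and_conservation(self):
        facts = [_fact("1"), _fact("1"), _fact("2", ts="2020-02-02"),
                 _fact("3", ts="2020-02-02")]
        once, report = deduplicate_facts(facts)
        twice, report2 = deduplicate_facts(once)
        assert twice == once
        assert report2.exact_duplicates_dropped == 0 and report2.conflicts == []
        assert len(facts) == len(once) + report.exact_duplicates_dropped + len(report.conflicts)
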