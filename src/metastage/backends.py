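"""Compile the canonical model into the two back-end staging dialects.

The engine never talks to a database: it *stages*. For the i2b2-oriented
loader it writes subjects, a separate visit file, one coded fact file per
entity, column/word mapping files and the ontology, plus an invocation
descriptor reminding the operator that ontology loading precedes fact
loading. For the tranSMART-oriented loader it writes the directory-structure
convention that tool expects: a study folder with a wide clinical data file
and a column mapping file. tranSMART has no modifiers and little time-axis
support, so meta-attributes are flattened into variant variables
("LDL (mg/dL)") and repeated measurements per (subject, visit, variable)
are collapsed under an explicit, reported policy.

All staging files are tab-separated, UTF-8, LF.
"""

from __future__ import annotations

import csv
import io
import json
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .config import StagingConfig
from .errors import BundleExistsError, EmitError
from .facts import Fact, Subject, Visit
from .ontology import OntologyTree
from .report import AnomalyLog
from ._util import sanitize_segment, sha256_hex

I2B2_DIALECT = "i2b2-batch"
TRANSMART_DIALECT = "transmart-dir"

#: modifier_cd of the base (unmodified) observation row in a fact file
BASE_MODIFIER = "@"


@dataclass
class StagingBundle:
    dialect: str
    files: dict[str, str]
    manifest: dict
    invocation: str


@dataclass
class AggregationReport:
    policy: str
    collapsed: dict[tuple, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.collapsed.values())


def _tsv(rows: list[list[str]]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerows(rows)
    return buf.getvalue()


def _fact_sort_key(f: Fact) -> tuple:
    return (
        f.subject_id,
        f.visit_id or "",
        f.concept_path,
        f.timestamp.render() if f.timestamp else "",
        f.value_type,
        f.value,
        tuple(sorted(f.modifiers.items())),
    )


# ---------------------------------------------------------------------------
# i2b2 dialect
# ---------------------------------------------------------------------------


def emit_i2b2_bundle(
    subjects: list[Subject],
    visits: list[Visit],
    facts: list[Fact],
    tree: OntologyTree,
    cfg: StagingConfig,
    log: AnomalyLog | None = None,
) -> StagingBundle:
    """Emit the i2b2-oriented staging bundle.

    All facts are preserved, including modifiers and repeated timestamped
    values. Fact rows are annotated with ontology node codes; each fact gets
    an instance number so several observations of one concept at one
    timestamp stay distinguishable, with modifier rows attached to their
    instance. Deterministic: identical model -> byte-identical bundle.
    """
    if not subjects:
        raise EmitError("no subjects: nothing loadable")
    if not facts and log is not None:
        log.add("emit", "no-facts", "no facts to emit; writing metadata-only bundle")

    files: dict[str, str] = {}
    subj_rows = [["subject_id", *cfg.subject_key.columns]]
    for s in sorted(subjects, key=lambda s: s.subject_id):
        subj_rows.append([s.subject_id, *s.key_values])
    files["subjects.tsv"] = _tsv(subj_rows)

    if visits:
        visit_rows = [["visit_id", "subject_id", "start", "start_precision", "end", "end_precision"]]
        for v in sorted(visits, key=lambda v: v.visit_id):
            visit_rows.append(
                [
                    v.visit_id,
                    v.subject_id,
                    v.start.render(),
                    v.start.precision,
                    v.end.render() if v.end else "",
                    v.end.precision if v.end else "",
                ]
            )
        files["visits.tsv"] = _tsv(visit_rows)

    code_of = {n.full_path: n.code for n in tree.nodes}
    fact_header = [
        "subject_id", "visit_id", "concept_cd", "instance_num",
        "modifier_cd", "value_type", "value", "timestamp", "timestamp_precision",
    ]
    by_entity: dict[str, list[Fact]] = {}
    for f in facts:
        entity_seg = f.concept_path.strip("\\").split("\\")[1]
        by_entity.setdefault(entity_seg, []).append(f)

    fact_files: list[str] = []
    for entity_seg in sorted(by_entity):
        rows = [list(fact_header)]
        instance_counter: dict[tuple, int] = {}
        for f in sorted(by_entity[entity_seg], key=_fact_sort_key):
            code = code_of.get(f.concept_path)
            if code is None:
                raise EmitError(f"fact concept path missing from ontology: {f.concept_path!r}")
            group = (f.subject_id, f.visit_id or "", code)
            instance = instance_counter.get(group, 0) + 1
            instance_counter[group] = instance
            ts = f.timestamp.render() if f.timestamp else ""
            prec = f.timestamp.precision if f.timestamp else ""
            rows.append(
                [f.subject_id, f.visit_id or "", code, str(instance),
                 BASE_MODIFIER, f.value_type, f.value, ts, prec]
            )
            for mod_name in sorted(f.modifiers):
                mod_path = f.concept_path + sanitize_segment(mod_name) + "\\"
                mod_code = code_of.get(mod_path)
                if mod_code is None:
                    raise EmitError(
                        f"modifier {mod_name!r} of {f.concept_path!r} missing from ontology"
                    )
                rows.append(
                    [f.subject_id, f.visit_id or "", code, str(instance),
                     mod_code, "text", f.modifiers[mod_name], ts, prec]
                )
        name = f"facts_{entity_seg}.tsv"
        files[name] = _tsv(rows)
        fact_files.append(name)

    ont_rows = [["level", "full_path", "name", "kind", "value_type", "code"]]
    for n in tree.nodes:  # already lexicographically sorted
        ont_rows.append([str(n.level), n.full_path, n.name, n.kind, n.value_type, n.code])
    files["ontology.tsv"] = _tsv(ont_rows)

    colmap = [["filename", "category_path", "column_index", "label"]]
    for name in fact_files:
        for i, col in enumerate(fact_header, start=1):
            colmap.append([name, "\\" + sanitize_segment(cfg.study_label) + "\\", str(i), col])
    files["column_mapping.tsv"] = _tsv(colmap)
    files["word_mapping.tsv"] = _tsv([["filename", "column_index", "original", "replacement"]])

    invocation = "\n".join(
        [
            f"# Back-end loader invocation descriptor ({I2B2_DIALECT})",
            "# Step 1: load ontology.tsv into the i2b2 metadata tables",
            "#         (ontology loading MUST precede fact loading).",
            "# Step 2: load subjects.tsv" + (", visits.tsv" if visits else ""),
            "# Step 3: load fact files: " + ", ".join(fact_files),
            "# Fact rows reference ontology node codes (column concept_cd/modifier_cd).",
            "",
        ]
    )
    files["invocation.txt"] = invocation

    modifier_rows = sum(len(f.modifiers) for f in facts)
    manifest = {
        "dialect": I2B2_DIALECT,
        "study": cfg.study_label,
        "counts": {
            "subjects": len(subjects),
            "visits": len(visits),
            "facts": len(facts),
            "modifier_rows": modifier_rows,
        },
        "files": {name: sha256_hex(text.encode("utf-8")) for name, text in sorted(files.items())},
    }
    return StagingBundle(I2B2_DIALECT, files, manifest, invocation)


# ---------------------------------------------------------------------------
# tranSMART dialect
# ---------------------------------------------------------------------------


def variant_label(fact: Fact, meta_order: list[str]) -> str:
    """Flatten a fact's modifiers into a variable-variant label.

    The attribute name is suffixed with the meta values in the attribute's
    declared meta order, a missing value rendered as "n/a". An attribute
    without declared meta keeps its plain name.
    """
    attribute = fact.concept_path.strip("\\").split("\\")[2]
    if not meta_order:
        return attribute
    parts = [fact.modifiers.get(m, "n/a") for m in meta_order]
    return f"{attribute} ({', '.join(parts)})"


def _meta_orders(cfg: StagingConfig) -> dict[tuple[str, str], list[str]]:
    out: dict[tuple[str, str], list[str]] = {}
    for e in cfg.entities:
        entity_seg = sanitize_segment(e.name)
        for a in e.attributes:
            out[(entity_seg, sanitize_segment(a.name))] = [m.name for m in a.meta_attributes]
    return out


def emit_transmart_bundle(
    subjects: list[Subject],
    facts: list[Fact],
    tree: OntologyTree,
    cfg: StagingConfig,
    policy: str | None = None,
    log: AnomalyLog | None = None,
) -> tuple[StagingBundle, AggregationReport]:
    """Emit the tranSMART-oriented staging bundle (directory convention).

    Multiple values per (subject, visit, variant variable) are collapsed per
    ``policy``: "latest" (default; highest timestamp, untimestamped facts
    sort earliest, ties keep the first by input order), "first", or "mean"
    (numeric variables only; others fall back to first). Every collapse is
    counted in the :class:`AggregationReport`.
    """
    if not subjects:
        raise EmitError("no subjects: nothing loadable")
    policy = policy or cfg.options.transmart_aggregation
    meta_orders = _meta_orders(cfg)
    study_seg = sanitize_segment(cfg.study_label)

    # group facts by (subject, visit, entity, variant label)
    groups: dict[tuple[str, str, str, str], list[Fact]] = {}
    for f in facts:
        _, entity_seg, attr_seg = f.concept_path.strip("\\").split("\\")
        label = variant_label(f, meta_orders.get((entity_seg, attr_seg), []))
        groups.setdefault((f.subject_id, f.visit_id or "", entity_seg, label), []).append(f)

    report = AggregationReport(policy=policy)
    chosen: dict[tuple[str, str, str, str], str] = {}
    for key, members in groups.items():
        if len(members) > 1:
            report.collapsed[key] = len(members) - 1
        if policy == "first" or len(members) == 1:
            pick = members[0].value
        elif policy == "latest":
            best = max(
                range(len(members)),
                key=lambda i: (
                    members[i].timestamp.sort_key().isoformat() if members[i].timestamp else "",
                    -i,  # tie -> earliest input order
                ),
            )
            pick = members[best].value
        else:  # mean
            try:
                values = [float(m.value) for m in members]
            except ValueError:
                pick = members[0].value
            else:
                mean = sum(values) / len(values)
                pick = str(int(mean)) if mean == int(mean) else repr(mean)
        chosen[key] = pick

    variables = sorted({(k[2], k[3]) for k in groups})
    row_keys = sorted({(k[0], k[1]) for k in groups})
    header = ["SUBJ_ID", "VISIT_ID", *(label for _, label in variables)]
    data_rows = [header]
    for subj, visit in row_keys:
        row = [subj, visit]
        for entity_seg, label in variables:
            row.append(chosen.get((subj, visit, entity_seg, label), ""))
        data_rows.append(row)

    data_name = f"{study_seg}/clinical/data.tsv"
    files = {data_name: _tsv(data_rows)}

    colmap = [["filename", "category_path", "column_number", "data_label"]]
    colmap.append(["data.tsv", "", "1", "SUBJ_ID"])
    colmap.append(["data.tsv", "", "2", "VISIT_ID"])
    for i, (entity_seg, label) in enumerate(variables, start=3):
        colmap.append(["data.tsv", f"\\{entity_seg}\\", str(i), label])
    files[f"{study_seg}/clinical/column_mapping.tsv"] = _tsv(colmap)

    invocation = "\n".join(
        [
            f"# Back-end loader invocation descriptor ({TRANSMART_DIALECT})",
            f"# Point the loader at the study directory '{study_seg}/'",
            "# (convention-over-configuration layout: clinical/ holds the data",
            "#  and its column mapping file).",
            f"# Repeated-measure collapse policy: {policy}.",
            "",
        ]
    )
    files["invocation.txt"] = invocation

    manifest = {
        "dialect": TRANSMART_DIALECT,
        "study": cfg.study_label,
        "counts": {
            "subjects": len(subjects),
            "facts_in": len(facts),
            "facts_emitted": len(facts) - report.total,
            "collapsed": report.total,
        },
        "aggregation_policy": policy,
        "files": {name: sha256_hex(text.encode("utf-8")) for name, text in sorted(files.items())},
    }
    return StagingBundle(TRANSMART_DIALECT, files, manifest, invocation), report


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_bundle(bundle: StagingBundle, out_dir: str | Path, force: bool = False) -> Path:
    """Write a bundle atomically (temp dir + rename); returns the manifest path.

    Refuses a non-empty existing ``out_dir`` unless ``force`` is set. The
    manifest records per-file checksums so a re-read can verify integrity.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise BundleExistsError(f"output directory {out_dir} exists and is not empty (use force)")
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".metastage-", dir=out_dir.parent))
    try:
        for rel, text in bundle.files.items():
            target = tmp / rel
            target.parent.mkdir(parents=True, exist_ok=True)
            target.write_text(text, encoding="utf-8", newline="")
        manifest_path = tmp / "manifest.json"
        manifest_path.write_text(
            json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        if out_dir.exists():
            shutil.rmtree(out_dir)
        os.replace(tmp, out_dir)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return out_dir / "manifest.json"
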