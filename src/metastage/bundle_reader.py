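"""Independent reader for written staging bundles.

Parses bundles back from disk using only the documented file layout (never
the emitter's in-memory objects), reconstructing the fact multiset. This is
the round-trip oracle: ``stage -> write -> read`` must recover exactly the
facts the ground truth predicts.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from pathlib import Path

#: Canonical fact tuple:
#: (subject_id, visit_id, concept_path, timestamp, precision, value_type,
#:  value, frozenset of (modifier name, value))
FactTuple = tuple


def fact_tuple(
    subject_id: str,
    visit_id: str,
    concept_path: str,
    timestamp: str,
    precision: str,
    value_type: str,
    value: str,
    modifiers: frozenset,
) -> FactTuple:
    return (subject_id, visit_id, concept_path, timestamp, precision, value_type, value, modifiers)


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    header = rows[0]
    return [dict(zip(header, r)) for r in rows[1:]]


def read_i2b2_bundle(bundle_dir: str | Path) -> Counter:
    """Reconstruct the fact multiset from a written i2b2-dialect bundle.

    Joins the coded fact files against the ontology file to recover concept
    paths and modifier names, groups modifier rows with their base row via
    (subject, visit, concept, instance).
    """
    bundle_dir = Path(bundle_dir)
    path_of_code: dict[str, str] = {}
    name_of_code: dict[str, str] = {}
    for row in _read_tsv(bundle_dir / "ontology.tsv"):
        path_of_code[row["code"]] = row["full_path"]
        name_of_code[row["code"]] = row["name"]

    facts: Counter = Counter()
    for fact_file in sorted(bundle_dir.glob("facts_*.tsv")):
        base: dict[tuple, dict] = {}
        mods: dict[tuple, dict[str, str]] = {}
        for row in _read_tsv(fact_file):
            key = (row["subject_id"], row["visit_id"], row["concept_cd"], row["instance_num"])
            if row["modifier_cd"] == "@":
                base[key] = row
            else:
                mods.setdefault(key, {})[name_of_code[row["modifier_cd"]]] = row["value"]
        for key, row in base.items():
            facts[
                fact_tuple(
                    row["subject_id"],
                    row["visit_id"],
                    path_of_code[row["concept_cd"]],
                    row["timestamp"],
                    row["timestamp_precision"],
                    row["value_type"],
                    row["value"],
                    frozenset(mods.get(key, {}).items()),
                )
            ] += 1
    return facts


def read_transmart_bundle(bundle_dir: str | Path) -> Counter:
    """Reconstruct the (subject, visit, entity, variable, value) multiset
    from a written tranSMART-dialect bundle's wide clinical data file."""
    bundle_dir = Path(bundle_dir)
    manifest = json.loads((bundle_dir / "manifest.json").read_text(encoding="utf-8"))
    study_dirs = [p for p in bundle_dir.iterdir() if (p / "clinical").is_dir()]
    assert len(study_dirs) == 1, "expected exactly one study directory"
    clinical = study_dirs[0] / "clinical"

    category: dict[str, str] = {}
    for row in _read_tsv(clinical / "column_mapping.tsv"):
        if row["data_label"] not in ("SUBJ_ID", "VISIT_ID"):
            category[row["data_label"]] = row["category_path"].strip("\\")

    cells: Counter = Counter()
    rows = _read_tsv(clinical / "data.tsv")
    for row in rows:
        subj, visit = row["SUBJ_ID"], row["VISIT_ID"]
        for label, value in row.items():
            if label in ("SUBJ_ID", "VISIT_ID") or value == "":
                continue
            cells[(subj, visit, category.get(label, ""), label, value)] += 1
    emitted = manifest["counts"]["facts_emitted"]
    assert sum(cells.values()) == emitted, "manifest fact count disagrees with data file"
    return cells


def verify_checksums(bundle_dir: str | Path) -> bool:
    """Check every file against the manifest's recorded checksum."""
    from ._util import sha256_hex

    bundle_dir = Path(bundle_dir)
    manifest = json.loads((bundle_dir / "manifest.json").read_text(encoding="utf-8"))
    for rel, digest in manifest["files"].items():
        if sha256_hex((bundle_dir / rel).read_bytes()) != digest:
            return False
    return True
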