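"""Back-end bundle emission, aggregation, atomic writing."""

import pytest

from metastage.backends import (
    emit_i2b2_bundle,
    emit_transmart_bundle,
    variant_label,
    write_bundle,
)
from metastage.bundle_reader import read_i2b2_bundle, verify_checksums
from metastage.errors import BundleExistsError, EmitError
from metastage.pipeline import emit, run_staging
from metastage.synthetic import MessinessSpec, generate_study


@pytest.fixture(scope="module")
def staged(tmp_path_factory):
    study = generate_study(6, 2, MessinessSpec(repeat_rate=0.3), seed=11)
    d = tmp_path_factory.mktemp("study")
    study.write(d)
    return study, run_staging(study.config, d)


class TestI2b2Emitter:
    def test_visit_file_written_separately_with_all_visits(self, staged):
        study, result = staged
        bundle, _ = emit(result, "i2b2")
        assert "visits.tsv" in bundle.files
        n_rows = bundle.files["visits.tsv"].count("\n") - 1
        assert n_rows == len(study.ground_truth.visits)

    def test_modifiers_attached_via_coded_modifier_nodes(self, staged, tmp_path):
        _, result = staged
        bundle, _ = emit(result, "i2b2")
        write_bundle(bundle, tmp_path / "b")
        facts = read_i2b2_bundle(tmp_path / "b")
        with_mods = [f for f in facts if f[7]]
        assert with_mods, "expected facts carrying modifier values"
        names = {name for f in with_mods for name, _ in f[7]}
        assert names == {"Unit", "Norm range"}

    def test_emission_is_deterministic(self, staged):
        _, result = staged
        b1, _ = emit(result, "i2b2")
        b2, _ = emit(result, "i2b2")
        assert b1.files == b2.files and b1.manifest == b2.manifest

    def test_zero_subjects_is_an_error(self, staged):
        _, result = staged
        with pytest.raises(EmitError):
            emit_i2b2_bundle([], result.visits, result.facts, result.tree, result.cfg)

    def test_mapping_file_closure(self, staged):
        # every file a mapping row references exists; every concept code in a
        # fact file exists in the ontology file
        _, result = staged
        bundle, _ = emit(result, "i2b2")
        import csv, io

        colmap = list(csv.DictReader(io.StringIO(bundle.files["column_mapping.tsv"]), delimiter="\t"))
        assert {r["filename"] for r in colmap} <= set(bundle.files)
        ont = list(csv.DictReader(io.StringIO(bundle.files["ontology.tsv"]), delimiter="\t"))
        codes = {r["code"] for r in ont}
        for name, text in bundle.files.items():
            if not name.startswith("facts_"):
                continue
            for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
                assert row["concept_cd"] in codes
                assert row["modifier_cd"] == "@" or row["modifier_cd"] in codes


class TestTransmartEmitter:
    def test_meta_values_become_attribute_variants(self, staged):
        _, result = staged
        bundle, _ = emit(result, "transmart")
        data = bundle.files["SYNTH/clinical/data.tsv"]
        header = data.splitlines()[0].split("\t")
        assert any("(" in h and "mg/dL" in h for h in header)

    def test_variant_label_uses_declared_meta_order_with_na(self):
        from metastage.facts import Fact

        f = Fact("s", None, "\\S\\Labs\\LDL\\", "1", "numeric",
                 modifiers={"Norm range": "<130"})
        assert variant_label(f, ["Unit", "Norm range"]) == "LDL (n/a, <130)"
        assert variant_label(f, []) == "LDL"

    def test_repeats_collapse_to_latest_and_are_counted(self, staged):
        study, result = staged
        bundle, agg = emit(result, "transmart")
        repeats = sum(1 for e in study.ground_truth.ledger if e["event"] == "repeat")
        assert agg.total == repeats > 0
        assert bundle.manifest["counts"]["facts_emitted"] == len(result.facts) - agg.total
        # policy check on one collapsed group: emitted value is the latest
        key, _ = next(iter(agg.collapsed.items()))
        members = [f for f in result.facts
                   if (f.subject_id, f.visit_id or "") == key[:2]
                   and f.concept_path.strip("\\").split("\\")[2] == key[3].split(" (")[0]]
        latest = max(members, key=lambda f: f.timestamp.instant)
        import csv, io

        rows = list(csv.DictReader(io.StringIO(bundle.files["SYNTH/clinical/data.tsv"]),
                                   delimiter="\t"))
        row = next(r for r in rows if r["SUBJ_ID"] == key[0] and r["VISIT_ID"] == key[1])
        assert row[key[3]] == latest.value

    def test_mean_policy_for_numeric_repeats(self, staged):
        _, result = staged
        bundle, agg = emit_transmart_bundle(
            result.subjects, result.facts, result.tree, result.cfg, policy="mean")
        assert agg.policy == "mean"
        assert bundle.manifest["counts"]["facts_emitted"] == len(result.facts) - agg.total


class TestWriteBundle:
    def test_checksums_verify_after_write(self, staged, tmp_path):
        _, result = staged
        bundle, _ = emit(result, "i2b2")
        write_bundle(bundle, tmp_path / "out")
        assert verify_checksums(tmp_path / "out")

    def test_refuses_nonempty_dir_without_force(self, staged, tmp_path):
        _, result = staged
        bundle, _ = emit(result, "i2b2")
        target = tmp_path / "out"
        target.mkdir()
        (target / "keep.txt").write_text("precious")
        with pytest.raises(BundleExistsError):
            write_bundle(bundle, target)
        assert (target / "keep.txt").read_text() == "precious"  # nothing written
        write_bundle(bundle, target, force=True)
        assert not (target / "keep.txt").exists()

    def test_two_writes_identical_checksums(self, staged, tmp_path):
        _, result = staged
        bundle, _ = emit(result, "i2b2")
        p1 = write_bundle(bundle, tmp_path / "a")
        p2 = write_bundle(bundle, tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()
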