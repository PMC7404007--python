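"""EAV denormalization against an independent pandas group-by/pivot oracle."""

import random

import pandas as pd
import pytest

from metastage.config import expand_eav_entities, parse_config
from metastage.eav import denormalize_eav, widen_declared
from metastage.report import AnomalyLog

from conftest import FIG4_YAML, make_table


def pivot_oracle(df, parameter_columns, value_column, meta_columns, label_join="|"):
    """Brute-force expected records via pandas, independent of the resolver:
    one (label, value, meta dict) per row with all parameter cells and the
    value cell present."""
    out = []
    for _, row in df.iterrows():
        parts = [row[c] for c in parameter_columns]
        if any(p is None for p in parts) or row[value_column] is None:
            continue
        label = label_join.join(" ".join(str(p).split()) for p in parts)
        meta = {m: row[m] for m in meta_columns if m in df.columns and row[m] is not None}
        out.append((label, row[value_column], tuple(sorted(meta.items()))))
    return sorted(out)


def _cfg(parameter_columns=("Parameter",), meta=("Unit", "Norm range")):
    cfg = parse_config(FIG4_YAML).model_copy(deep=True)
    eav = cfg.entities[0].eav
    eav.parameter_columns = list(parameter_columns)
    eav.meta_columns = [m.model_copy(update={"name": c, "column": c}) for c in meta
                       for m in [eav.meta_columns[0]]]
    return cfg


class TestDenormalizeEav:
    def test_lab_rows_become_records_with_meta(self, fig4_cfg):
        table = make_table(
            "labs", ["pid", "date", "Parameter", "Result", "Unit", "Norm range"],
            [
                ["P1", "2020-01-01", "LDL", "140", "mg/dL", "<130"],
                ["P1", "2020-01-01", "CRP", "0.5", "mg/L", None],
            ],
        )
        cfg = expand_eav_entities(fig4_cfg, table)
        records, skipped = denormalize_eav(table, cfg.entities[0], cfg)
        assert len(records) == 2 and skipped == {"missing_parameter": 0, "missing_value": 0}
        ldl = next(r for r in records if r.attribute == "LDL")
        assert ldl.value == "140"
        assert ldl.meta_values == {"Unit": "mg/dL", "Norm range": "<130"}
        crp = next(r for r in records if r.attribute == "CRP")
        assert crp.value == "0.5" and crp.meta_values == {"Unit": "mg/L"}

    def test_missing_value_rows_skipped_with_reason(self, fig4_cfg):
        table = make_table(
            "labs", ["pid", "date", "Parameter", "Result", "Unit", "Norm range"],
            [["P1", "2020-01-01", "LDL", None, "mg/dL", "<130"]],
        )
        cfg = expand_eav_entities(fig4_cfg, table)
        records, skipped = denormalize_eav(table, cfg.entities[0], cfg)
        assert records == [] and skipped["missing_value"] == 1

    def test_two_column_parameter_label(self):
        cfg = _cfg(parameter_columns=("Analyte", "Material"), meta=())
        table = make_table("labs", ["pid", "date", "Analyte", "Material", "Result"],
                           [["P1", "2020-01-01", "Glucose", "Serum", "5.1"]])
        cfg = expand_eav_entities(cfg, table)
        records, _ = denormalize_eav(table, cfg.entities[0], cfg)
        assert records[0].attribute == "Glucose|Serum"

    def test_unlisted_parameter_admitted_on_the_fly(self, fig4_cfg):
        # expansion saw one file of a pattern; the data carries another label
        seen = make_table("labs", ["pid", "date", "Parameter", "Result", "Unit", "Norm range"],
                          [["P1", "2020-01-01", "LDL", "1", None, None]])
        cfg = expand_eav_entities(fig4_cfg, seen)
        other = make_table("labs", ["pid", "date", "Parameter", "Result", "Unit", "Norm range"],
                           [["P2", "2020-01-02", "HDL", "2", None, None]])
        log = AnomalyLog()
        records, _ = denormalize_eav(other, cfg.entities[0], cfg, log)
        assert records[0].attribute == "HDL"
        assert log.count(kind="unlisted-parameter") == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_random_tables_match_pivot_oracle(self, fig4_cfg, seed):
        rng = random.Random(seed)
        params = ["LDL", "HDL", "CRP", "Na", "K"][: rng.randint(1, 5)]
        rows = []
        for _ in range(rng.randint(0, 20)):
            rows.append([
                f"P{rng.randint(1, 3)}",
                "2020-01-01",
                rng.choice(params + [None]),
                rng.choice([str(rng.randint(1, 99)), None]),
                rng.choice(["mg/dL", None]),
                rng.choice(["<130", None]),
            ])
        table = make_table("labs", ["pid", "date", "Parameter", "Result", "Unit", "Norm range"], rows)
        cfg = expand_eav_entities(fig4_cfg, table)
        records, skipped = denormalize_eav(table, cfg.entities[0], cfg)
        got = sorted(
            (r.attribute, r.value, tuple(sorted(r.meta_values.items()))) for r in records
        )
        df = pd.DataFrame(rows, columns=["pid", "date", "Parameter", "Result", "Unit", "Norm range"])
        df = df.astype(object).where(pd.notna(df), None)
        assert got == pivot_oracle(df, ["Parameter"], "Result", ["Unit", "Norm range"])
        # conservation: every row is a record or a counted skip
        assert len(records) + sum(skipped.values()) == len(rows)

    def test_row_order_does_not_change_record_multiset(self, fig4_cfg):
        rows = [["P1", "2020-01-01", "LDL", "1", None, None],
                ["P2", "2020-01-02", "CRP", "2", "mg/L", None],
                ["P1", "2020-01-03", "LDL", "3", None, "<130"]]
        t1 = make_table("labs", ["pid", "date", "Parameter", "Result", "Unit", "Norm range"], rows)
        t2 = make_table("labs", ["pid", "date", "Parameter", "Result", "Unit", "Norm range"],
                        rows[::-1])
        cfg = expand_eav_entities(fig4_cfg, t1)
        key = lambda r: (r.attribute, r.value, tuple(sorted(r.meta_values.items())))
        a = sorted(map(key, denormalize_eav(t1, cfg.entities[0], cfg)[0]))
        b = sorted(map(key, denormalize_eav(t2, cfg.entities[0], cfg)[0]))
        assert a == b


class TestWidenDeclared:
    def _cfg_and_table(self, rows):
        import textwrap

        cfg = parse_config(textwrap.dedent("""
            study: {label: D}
            sources:
              patients: {path: p.csv, role: patient-file, key: [pid]}
            entities:
              - name: Demo
                anchor: patient
                source: patients
                attributes:
                  - {name: sex, column: sex}
                  - {name: age, column: age}
                  - {name: bp, column: bp, meta: [bp_pos]}
            """))
        table = make_table("patients", ["pid", "sex", "age", "bp", "bp_pos"], rows)
        return cfg, table

    def test_one_record_per_nonmissing_cell(self):
        cfg, table = self._cfg_and_table([["P1", "M", None, "120", "sitting"]])
        records = widen_declared(table, cfg.entities[0], cfg)
        assert {(r.attribute, r.value) for r in records} == {("sex", "M"), ("bp", "120")}

    def test_empty_table_yields_no_records(self):
        cfg, table = self._cfg_and_table([])
        assert widen_declared(table, cfg.entities[0], cfg) == []

    def test_missing_meta_cell_leaves_key_absent(self):
        cfg, table = self._cfg_and_table([["P1", "M", "40", "120", None]])
        bp = next(r for r in widen_declared(table, cfg.entities[0], cfg) if r.attribute == "bp")
        assert bp.meta_values == {}

    def test_conservation_counting_missing_as_skipped(self):
        rows = [["P1", "M", None, "120", None], ["P2", None, None, None, None]]
        cfg, table = self._cfg_and_table(rows)
        records = widen_declared(table, cfg.entities[0], cfg)
        n_attrs = 3
        missing_cells = 4  # age@P1, sex/age/bp@P2
        assert len(records) + missing_cells == len(rows) * n_attrs
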