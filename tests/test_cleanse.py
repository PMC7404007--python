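"""Missing values, type inference, timestamps with precision, filters."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metastage.cleanse import (
    apply_filters,
    normalize_missing,
    parse_timestamp,
    profile_column,
)
from metastage.config import CleansingOptions, FilterSpec
from metastage.errors import ConfigSchemaError, TimestampError

from conftest import make_table

DEFAULT_TOKENS = {"", "NA", "N/A", "NULL", "-", "."}


class TestNormalizeMissing:
    def test_default_tokens(self):
        out, n = normalize_missing(["1", "NA", "", "2"], DEFAULT_TOKENS)
        assert out == ["1", None, None, "2"] and n == 2

    def test_case_insensitive_match(self):
        out, n = normalize_missing(["na", " n/a "], DEFAULT_TOKENS)
        assert out == [None, None] and n == 2

    def test_empty_input(self):
        assert normalize_missing([], DEFAULT_TOKENS) == ([], 0)

    def test_empty_token_set_rejected(self):
        with pytest.raises(ValueError):
            normalize_missing(["x"], set())


class TestProfileColumn:
    def test_decimal_point_numeric(self):
        p = profile_column(["1.5", "2", "3"])
        assert p.inferred_type == "numeric" and p.decimal_separator == "."

    def test_decimal_comma_numeric(self):
        p = profile_column(["1,5", "2,0"])
        assert p.inferred_type == "numeric" and p.decimal_separator == ","

    def test_single_bad_cell_demotes_to_categorical(self):
        p = profile_column(["1.5", "abc", "2"])
        assert p.inferred_type == "categorical" and p.distinct_count == 3

    def test_mixed_dot_and_comma_not_comma_numeric(self):
        # a dot anywhere disables the comma convention (thousands ambiguity)
        p = profile_column(["1.5", "2,0"])
        assert p.inferred_type != "numeric"

    def test_dates_above_threshold(self):
        cells = ["2020-01-0%d" % (i % 9 + 1) for i in range(40)]
        p = profile_column(cells)
        assert p.inferred_type == "date"
        assert p.date_parse_fraction == 1.0

    def test_many_distinct_strings_are_text(self):
        p = profile_column([f"free text {i}" for i in range(500)])
        assert p.inferred_type == "text"

    def test_few_distinct_strings_are_categorical(self):
        p = profile_column(["yes", "no", "yes", "maybe"] * 10)
        assert p.inferred_type == "categorical"

    def test_missing_excluded_from_fractions(self):
        p = profile_column(["1", None, "2", None])
        assert p.inferred_type == "numeric"
        assert p.missing_count == 2
        assert p.numeric_parse_fraction == 1.0

    @settings(deadline=None, max_examples=50)
    @given(st.permutations(["1.5", "abc", "2020-01-01", None, "2", "x"]))
    def test_permutation_invariance(self, cells):
        reference = profile_column(["1.5", "abc", "2020-01-01", None, "2", "x"])
        assert profile_column(list(cells)) == reference


class TestParseTimestamp:
    @pytest.mark.parametrize(
        "token,precision,rendered",
        [
            ("2019", "year", "2019"),
            ("2019-03", "month", "2019-03"),
            ("2019-03-02", "day", "2019-03-02"),
            ("2019-03-02T14:30", "minute", "2019-03-02T14:30"),
            ("2019-03-02 14:30:05", "second", "2019-03-02T14:30:05"),
        ],
    )
    def test_precision_reflects_token_granularity(self, token, precision, rendered):
        ts = parse_timestamp(token)
        assert ts.precision == precision
        assert ts.render() == rendered

    def test_partial_dates_use_window_start(self):
        assert parse_timestamp("2019").instant.isoformat() == "2019-01-01T00:00:00"
        assert parse_timestamp("2019-03").instant.isoformat() == "2019-03-01T00:00:00"

    def test_day_first_convention(self):
        ts = parse_timestamp("02.03.2019", CleansingOptions(day_first=True))
        assert ts.instant.date().isoformat() == "2019-03-02" and ts.precision == "day"

    def test_month_first_convention(self):
        ts = parse_timestamp("02.03.2019", CleansingOptions(day_first=False))
        assert ts.instant.date().isoformat() == "2019-02-03"

    def test_unambiguous_day_overrides_convention(self):
        ts = parse_timestamp("13.05.2019", CleansingOptions(day_first=False))
        assert ts.instant.date().isoformat() == "2019-05-13"

    def test_configured_extra_format(self):
        opts = CleansingOptions(date_formats=["%Y%m%d"])
        ts = parse_timestamp("20190302", opts)
        assert ts.instant.date().isoformat() == "2019-03-02" and ts.precision == "day"

    @pytest.mark.parametrize("bad", ["not a date", "2019-13-40", "31.31.2019", ""])
    def test_unparseable_raises_timestamp_error(self, bad):
        with pytest.raises(TimestampError):
            parse_timestamp(bad)

    def test_rendering_preserves_informational_content(self):
        for token in ["2019", "2019-03", "2019-03-02", "2019-03-02T14:30"]:
            assert parse_timestamp(token).render() == token


class TestApplyFilters:
    def _table(self):
        return make_table(
            "t", ["Status", "value"],
            [["final", str(i)] if i < 4 else ["draft", str(i)] for i in range(10)],
        )

    def test_keep_in_set(self):
        spec = FilterSpec(source="t", column="Status", predicate="in-set",
                          values=["final"], action="keep")
        out, removed = apply_filters(self._table(), [spec])
        assert len(out.rows) == 4 and removed == 6

    def test_empty_filter_list_is_identity(self):
        table = self._table()
        out, removed = apply_filters(table, [])
        assert out is table and removed == 0

    def test_numeric_range(self):
        spec = FilterSpec(source="t", column="value", predicate="numeric-range",
                          minimum=2, maximum=5, action="keep")
        out, removed = apply_filters(self._table(), [spec])
        assert [r[1] for r in out.rows] == ["2", "3", "4", "5"]

    def test_drop_action_complements_keep(self):
        keep = FilterSpec(source="t", column="Status", predicate="equals",
                          value="final", action="keep")
        drop = FilterSpec(source="t", column="Status", predicate="equals",
                          value="final", action="drop")
        kept, _ = apply_filters(self._table(), [keep])
        dropped, _ = apply_filters(self._table(), [drop])
        assert len(kept.rows) + len(dropped.rows) == 10

    def test_numeric_range_on_categorical_column_is_config_error(self):
        from metastage.cleanse import profile_column

        table = self._table()
        profiles = {"Status": profile_column(table.column_values("Status"))}
        spec = FilterSpec(source="t", column="Status", predicate="numeric-range",
                          minimum=0, action="keep")
        with pytest.raises(ConfigSchemaError):
            apply_filters(table, [spec], profiles)

    def test_filters_on_disjoint_columns_commute(self):
        f1 = FilterSpec(source="t", column="Status", predicate="equals",
                        value="final", action="keep")
        f2 = FilterSpec(source="t", column="value", predicate="numeric-range",
                        maximum=6, action="keep")
        a, _ = apply_filters(apply_filters(self._table(), [f1])[0], [f2])
        b, _ = apply_filters(apply_filters(self._table(), [f2])[0], [f1])
        assert a.rows == b.rows

    def test_removed_counts_reconcile(self):
        f = FilterSpec(source="t", column="Status", predicate="non-missing", action="keep")
        table = make_table("t", ["Status", "value"], [["final", "1"], [None, "2"]])
        out, removed = apply_filters(table, [f])
        assert removed == len(table.rows) - len(out.rows) == 1
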