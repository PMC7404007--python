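"""Missing-value normalization, type/format inference, timestamps, filters.

Type inference is deliberately conservative: a column is numeric only when
*every* non-missing cell parses under a single decimal-separator convention
(one bad cell demotes the whole column — silent coercion of clinical values
is worse than a categorical fallback). Decimal commas are accepted only when
no cell contains a dot and every numeric candidate matches the
digits-comma-digits pattern, which avoids thousands-separator ambiguity.

Timestamps carry an explicit *precision* (year … second). A partial date is
represented by the start of its precision window (Jan 1 / first of month /
midnight) with the precision kept alongside, so emitters can disclose the
imputation instead of fabricating exactness.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Literal, Optional

from .config import CleansingOptions, FilterSpec
from .errors import ConfigSchemaError, TimestampError
from ._util import _NUM_COMMA, _NUM_DOT, parse_number
from .ingest import SourceTable

MISSING = None

Precision = Literal["year", "month", "day", "minute", "second"]

#: Date-parse fraction at or above which a column is typed as date.
DATE_THRESHOLD = 0.95

#: Categorical ceiling: distinct_count <= max(CAT_MIN, CAT_FRACTION * rows).
CAT_MIN = 20
CAT_FRACTION = 0.05


def normalize_missing(
    cells: list[str | None], tokens: set[str]
) -> tuple[list[str | None], int]:
    """Replace cells matching a missing token with the canonical marker.

    Matching is case-insensitive after outer-whitespace trimming. Returns the
    normalized cells and the number of missing cells (including cells that
    were already the canonical marker).
    """
    if not tokens:
        raise ValueError("missing-token set must be non-empty")
    lowered = {t.strip().casefold() for t in tokens}
    out: list[str | None] = []
    count = 0
    for cell in cells:
        if cell is None or cell.strip().casefold() in lowered:
            out.append(MISSING)
            count += 1
        else:
            out.append(cell)
    return out, count


def normalize_table_missing(table: SourceTable, tokens: set[str]) -> tuple[SourceTable, int]:
    """Apply :func:`normalize_missing` column-wise to a whole table."""
    total = 0
    new_rows: list[list[str | None]] = [list(r) for r in table.rows]
    for j in range(len(table.columns)):
        col, n = normalize_missing([r[j] for r in new_rows], tokens)
        total += n
        for i, v in enumerate(col):
            new_rows[i][j] = v
    return (
        SourceTable(
            logical_name=table.logical_name,
            columns=list(table.columns),
            rows=new_rows,
            provenance=table.provenance,
            row_ids=list(table.row_ids),
        ),
        total,
    )


# ---------------------------------------------------------------------------
# timestamps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Timestamp:
    instant: datetime
    precision: Precision
    original: str

    def render(self) -> str:
        """Render the instant at its own precision (ISO-like, sortable)."""
        fmt = {
            "year": "%Y",
            "month": "%Y-%m",
            "day": "%Y-%m-%d",
            "minute": "%Y-%m-%dT%H:%M",
            "second": "%Y-%m-%dT%H:%M:%S",
        }[self.precision]
        return self.instant.strftime(fmt)

    def sort_key(self) -> datetime:
        return self.instant


_ISO_PATTERNS: list[tuple[re.Pattern[str], str, Precision]] = [
    (re.compile(r"^(\d{4})$"), "%Y", "year"),
    (re.compile(r"^(\d{4})-(\d{1,2})$"), "%Y-%m", "month"),
    (re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$"), "%Y-%m-%d", "day"),
    (re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})[T ](\d{1,2}):(\d{2})$"), "%Y-%m-%d %H:%M", "minute"),
    (
        re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})[T ](\d{1,2}):(\d{2}):(\d{2})$"),
        "%Y-%m-%d %H:%M:%S",
        "second",
    ),
]

_DMY = re.compile(r"^(\d{1,2})[./](\d{1,2})[./](\d{4})( (\d{1,2}):(\d{2})(:(\d{2}))?)?$")

_FMT_PRECISION: list[tuple[str, Precision]] = [
    ("%S", "second"),
    ("%M", "minute"),
    ("%d", "day"),
    ("%m", "month"),
    ("%Y", "year"),
]


def _format_precision(fmt: str) -> Precision:
    for directive, precision in _FMT_PRECISION:
        if directive in fmt:
            return precision
    return "year"


def parse_timestamp(token: str, options: CleansingOptions | None = None) -> Timestamp:
    """Parse a timestamp token, recording the granularity actually present.

    ISO-8601 shapes are tried first (``2019``, ``2019-03``, ``2019-03-02``,
    optionally with a time part), then numeric day/month forms under the
    configured day-first convention, then any user-supplied strptime formats.
    Raises :class:`TimestampError` for unparseable tokens.
    """
    options = options or CleansingOptions()
    token = token.strip()
    if not token:
        raise TimestampError("empty timestamp token")
    for pattern, fmt, precision in _ISO_PATTERNS:
        if pattern.match(token):
            try:
                instant = datetime.strptime(token.replace("T", " "), fmt)
            except ValueError as exc:
                raise TimestampError(f"invalid calendar date: {token!r}") from exc
            return Timestamp(instant, precision, token)
    m = _DMY.match(token)
    if m:
        a, b, year = int(m.group(1)), int(m.group(2)), int(m.group(3))
        day, month = (a, b) if options.day_first else (b, a)
        if month > 12 and day <= 12:
            # unambiguous despite the convention: 2019 has no month 13
            day, month = month, day
        try:
            instant = datetime(year, month, day)
        except ValueError as exc:
            raise TimestampError(f"invalid calendar date: {token!r}") from exc
        precision: Precision = "day"
        if m.group(4):
            hour, minute = int(m.group(5)), int(m.group(6))
            second = int(m.group(8)) if m.group(8) else 0
            instant = instant.replace(hour=hour, minute=minute, second=second)
            precision = "second" if m.group(8) else "minute"
        return Timestamp(instant, precision, token)
    for fmt in options.date_formats:
        try:
            instant = datetime.strptime(token, fmt)
        except ValueError:
            continue
        return Timestamp(instant, _format_precision(fmt), token)
    raise TimestampError(f"unparseable timestamp: {token!r}")


# ---------------------------------------------------------------------------
# column profiling
# ---------------------------------------------------------------------------

@dataclass
class ColumnProfile:
    inferred_type: Literal["numeric", "categorical", "date", "text"]
    numeric_parse_fraction: float
    date_parse_fraction: float
    decimal_separator: str = "."
    distinct_count: int = 0
    missing_count: int = 0
    winning_date_formats: list[str] = field(default_factory=list)


def profile_column(
    cells: list[str | None], options: CleansingOptions | None = None
) -> ColumnProfile:
    """Infer the type of a column from its (missing-normalized) cells.

    Precedence: numeric (all non-missing cells parse under one decimal
    convention) > date (>= 95% parse) > categorical (distinct count within
    the ceiling) > text. Fractions are computed over non-missing cells only,
    so the profile is permutation-invariant.
    """
    options = options or CleansingOptions()
    present = [c for c in cells if c is not None]
    missing = len(cells) - len(present)
    if not present:
        return ColumnProfile("text", 0.0, 0.0, missing_count=missing)

    distinct = len(set(present))
    dot_ok = sum(1 for c in present if _NUM_DOT.match(c.strip()))
    numeric_fraction = dot_ok / len(present)
    sep = "."
    if dot_ok < len(present) and not any("." in c for c in present):
        comma_ok = sum(1 for c in present if _NUM_COMMA.match(c.strip()))
        if comma_ok == len(present) and any("," in c for c in present):
            numeric_fraction, sep = 1.0, ","

    date_ok = 0
    formats: dict[str, int] = {}
    for c in present:
        try:
            ts = parse_timestamp(c, options)
        except TimestampError:
            continue
        date_ok += 1
        formats[ts.precision] = formats.get(ts.precision, 0) + 1
    date_fraction = date_ok / len(present)

    if numeric_fraction == 1.0:
        inferred = "numeric"
    elif date_fraction >= DATE_THRESHOLD:
        inferred = "date"
    elif distinct <= max(CAT_MIN, CAT_FRACTION * len(cells)):
        inferred = "categorical"
    else:
        inferred = "text"
    return ColumnProfile(
        inferred_type=inferred,
        numeric_parse_fraction=numeric_fraction,
        date_parse_fraction=date_fraction,
        decimal_separator=sep,
        distinct_count=distinct,
        missing_count=missing,
        winning_date_formats=sorted(formats, key=lambda k: (-formats[k], k)),
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _satisfies(cell: str | None, spec: FilterSpec) -> bool:
    if spec.predicate == "non-missing":
        return cell is not None
    if cell is None:
        return False
    cell = cell.strip()
    if spec.predicate == "equals":
        return cell == spec.value
    if spec.predicate == "in-set":
        return cell in set(spec.values or [])
    # numeric-range
    try:
        v = parse_number(cell)
    except ValueError:
        return False
    if spec.minimum is not None and v < spec.minimum:
        return False
    if spec.maximum is not None and v > spec.maximum:
        return False
    return True


def apply_filters(
    table: SourceTable,
    filters: list[FilterSpec],
    profiles: Optional[dict[str, ColumnProfile]] = None,
) -> tuple[SourceTable, int]:
    """Apply keep/drop row filters bound to this table's logical source.

    ``profiles`` (column name -> profile), when given, lets type
    compatibility be enforced: a numeric-range filter on a non-numeric
    column is a configuration error. Returns the filtered table and the
    number of rows removed.
    """
    relevant = [f for f in filters if f.source == table.logical_name]
    if not relevant:
        return table, 0
    for f in relevant:
        if f.column not in table.columns:
            raise ConfigSchemaError(
                f"filter column {f.column!r} not in source {table.logical_name!r}"
            )
        if (
            profiles is not None
            and f.predicate == "numeric-range"
            and f.column in profiles
            and profiles[f.column].inferred_type != "numeric"
        ):
            raise ConfigSchemaError(
                f"numeric-range filter on non-numeric column {f.column!r} "
                f"(inferred {profiles[f.column].inferred_type})"
            )
    keep_rows: list[list[str | None]] = []
    keep_ids: list[int] = []
    for row, row_id in zip(table.rows, table.row_ids):
        ok = True
        for f in relevant:
            hit = _satisfies(row[table.column_index(f.column)], f)
            if (f.action == "keep" and not hit) or (f.action == "drop" and hit):
                ok = False
                break
        if ok:
            keep_rows.append(row)
            keep_ids.append(row_id)
    removed = len(table.rows) - len(keep_rows)
    return (
        SourceTable(
            logical_name=table.logical_name,
            columns=list(table.columns),
            rows=keep_rows,
            provenance=table.provenance,
            row_ids=keep_ids,
        ),
        removed,
    )
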