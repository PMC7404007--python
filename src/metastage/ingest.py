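"""Robust reading of raw input files.

Clinical source systems export delimited text in whatever encoding and
dialect their vendor chose; the staging engine must absorb that without
per-file configuration. This module detects the character encoding (BOM
first, then trial decoding with a fixed priority), sniffs the delimiter
dialect by consistency scoring over a bounded sample, and parses files into
a canonical in-memory table of verbatim string cells with full provenance.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

from .config import SourceBinding
from .errors import EncodingDetectionError, IngestError
from .report import AnomalyLog

#: Delimiter candidates tried by the dialect sniffer, in tie-break order.
DELIMITER_CANDIDATES = (",", ";", "\t", "|")

#: Number of leading lines sampled for dialect sniffing.
SNIFF_LINES = 100

_BOMS: tuple[tuple[bytes, str], ...] = (
    (b"\xef\xbb\xbf", "utf-8"),
    (b"\xff\xfe", "utf-16"),
    (b"\xfe\xff", "utf-16"),
)


@dataclass(frozen=True)
class Dialect:
    delimiter: str = ","
    quote_char: str = '"'
    has_header: bool = True
    line_terminator: str = "\n"

    def __post_init__(self) -> None:
        if self.delimiter == self.quote_char:
            raise ValueError("delimiter and quote character must differ")


@dataclass
class Provenance:
    path: str
    encoding: str
    dialect: Dialect


@dataclass
class SourceTable:
    logical_name: str
    columns: list[str]
    rows: list[list[str | None]]
    provenance: Provenance
    row_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.row_ids:
            self.row_ids = list(range(2, 2 + len(self.rows)))

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def column_values(self, name: str) -> list[str | None]:
        i = self.column_index(name)
        return [row[i] for row in self.rows]


def detect_encoding(raw: bytes) -> tuple[str, float]:
    """Detect the character encoding of ``raw``.

    A byte-order mark takes absolute precedence. Without one, candidates are
    tried in fixed priority — UTF-8, then a NUL-byte heuristic for BOM-less
    UTF-16, then ISO-8859-1 — so identical bytes always yield the same
    answer. Returns ``(encoding_label, confidence)``.
    """
    if not raw:
        raise EncodingDetectionError("cannot detect encoding of empty input")
    for bom, label in _BOMS:
        if raw.startswith(bom):
            return label, 1.0
    try:
        raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        sample = raw[:4096]
        nul_fraction = sample.count(0) / len(sample)
        if nul_fraction > 0.3:
            for label in ("utf-16-le", "utf-16-be"):
                try:
                    raw.decode(label)
                    return label, 0.6
                except UnicodeDecodeError:
                    continue
        try:
            raw.decode("iso-8859-1")
        except UnicodeDecodeError:  # pragma: no cover - latin-1 decodes any byte
            raise EncodingDetectionError(
                f"no candidate encoding decodes input (first undecodable byte at offset {exc.start})"
            ) from exc
        return "iso-8859-1", 0.7
    ascii_only = all(b < 0x80 for b in raw)
    return "utf-8", 1.0 if ascii_only else 0.9


def decode_bytes(raw: bytes, encoding: str) -> str:
    """Decode ``raw``, stripping the BOM the detector may have keyed on."""
    if encoding == "utf-8" and raw.startswith(b"\xef\xbb\xbf"):
        return raw.decode("utf-8-sig")
    return raw.decode(encoding)


_NUMERIC_CELL = re.compile(r"^[+-]?(\d+([.,]\d*)?|[.,]\d+)$")


def _parse_sample(sample: str, delimiter: str, quote_char: str, max_lines: int) -> list[list[str]]:
    reader = csv.reader(io.StringIO(sample), delimiter=delimiter, quotechar=quote_char)
    rows = []
    for row in reader:
        if row:
            rows.append(row)
        if len(rows) >= max_lines:
            break
    return rows


def detect_dialect(sample: str, max_lines: int = SNIFF_LINES) -> Dialect:
    """Choose the delimiter maximizing column-count consistency over ``sample``.

    Each candidate delimiter is scored by the fraction of sampled lines whose
    parsed cell count matches the modal count, zeroed when the modal count is
    a single column (the candidate never splits anything) or when quotes are
    unbalanced. Ties fall back to the fixed candidate order. If no candidate
    splits the sample, a single-column dialect with the default delimiter is
    returned. The header flag is inferred from the type contrast between the
    first line and the rest.
    """
    if not sample.strip():
        raise IngestError("cannot sniff dialect of an empty sample")
    best: tuple[float, int, int] | None = None
    best_delim = None
    best_rows: list[list[str]] = []
    for rank, delim in enumerate(DELIMITER_CANDIDATES):
        rows = _parse_sample(sample, delim, '"', max_lines)
        if not rows:
            continue
        widths = [len(r) for r in rows]
        modal = max(set(widths), key=widths.count)
        if modal <= 1:
            continue
        consistency = widths.count(modal) / len(widths)
        key = (consistency, modal, -rank)
        if best is None or key > best:
            best, best_delim, best_rows = key, delim, rows
    if best_delim is None:
        rows = _parse_sample(sample, ",", '"', max_lines)
        return Dialect(delimiter=",", has_header=_infer_header(rows))
    return Dialect(delimiter=best_delim, has_header=_infer_header(best_rows))


def _infer_header(rows: list[list[str]]) -> bool:
    """Header heuristic: some column is numeric in the body but not in line 1."""
    if len(rows) < 2:
        return True
    header, body = rows[0], rows[1:]
    width = len(header)
    for i in range(width):
        cells = [r[i].strip() for r in body if i < len(r) and r[i].strip()]
        if cells and all(_NUMERIC_CELL.match(c) for c in cells):
            if not _NUMERIC_CELL.match(header[i].strip()):
                return True
    # no type contrast found: assume a header when line 1 has no numeric cell
    return not any(_NUMERIC_CELL.match(c.strip()) for c in header if c.strip())


def read_table(
    path: str | Path,
    binding: SourceBinding,
    log: AnomalyLog | None = None,
    strict: bool = False,
) -> SourceTable:
    """Read a delimited text file into a :class:`SourceTable`.

    Encoding and dialect are detected automatically; cells are kept verbatim
    apart from outer-whitespace trimming. Ragged rows are padded (short) or
    truncated (long) and logged with their line numbers — or rejected
    outright in strict mode. Duplicated header names are an error.
    """
    path = Path(path)
    log = log if log is not None else AnomalyLog()
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise IngestError(f"cannot read {path}: {exc}") from exc
    if not raw:
        raise IngestError(f"input file is empty: {path}")
    encoding, confidence = detect_encoding(raw)
    text = decode_bytes(raw, encoding)
    sample = "\n".join(text.splitlines()[:SNIFF_LINES])
    dialect = detect_dialect(sample)
    log.add(
        "ingest",
        "encoding-detected",
        f"{path.name}: encoding {encoding} (confidence {confidence:.2f}), "
        f"delimiter {dialect.delimiter!r}",
        severity="info",
        file=path.name,
        encoding=encoding,
        confidence=confidence,
    )

    reader = csv.reader(io.StringIO(text), delimiter=dialect.delimiter, quotechar=dialect.quote_char)
    records = [row for row in reader if row]
    if not records:
        raise IngestError(f"no parsable rows in {path}")
    if dialect.has_header:
        header = [c.strip() for c in records[0]]
        body = records[1:]
        first_row_id = 2
    else:
        header = [f"col_{i + 1}" for i in range(len(records[0]))]
        body = records
        first_row_id = 1
        log.add("ingest", "no-header", f"{path.name}: no header detected, synthesized column names",
                file=path.name)
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise IngestError(f"{path}: duplicated header names: {', '.join(dupes)}")

    width = len(header)
    rows: list[list[str | None]] = []
    row_ids: list[int] = []
    for offset, rec in enumerate(body):
        row_id = first_row_id + offset
        cells = [c.strip() for c in rec]
        if len(cells) != width:
            kind = "padded-row" if len(cells) < width else "truncated-row"
            msg = (
                f"{path.name} line {row_id}: expected {width} cells, got {len(cells)} "
                f"({'padded' if len(cells) < width else 'truncated'})"
            )
            if strict:
                raise IngestError(msg)
            log.add("ingest", kind, msg, file=path.name, row_id=row_id,
                    expected=width, got=len(cells))
            cells = (cells + [""] * width)[:width]
        rows.append(list(cells))
        row_ids.append(row_id)
    return SourceTable(
        logical_name=binding.logical_name,
        columns=header,
        rows=rows,
        provenance=Provenance(path=str(path), encoding=encoding, dialect=dialect),
        row_ids=row_ids,
    )
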