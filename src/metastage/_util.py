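"""Small shared helpers: path sanitization, stable codes, canonical numbers."""

from __future__ import annotations

import hashlib
import re

_SEGMENT_BAD = re.compile(r"[\\/\x00-\x1f\x7f]")
_WS_RUN = re.compile(r"\s+")

#: Maximum length of one ontology path segment (i2b2 path-length constraints).
MAX_SEGMENT_LEN = 200


def sanitize_segment(text: str) -> str:
    """Make ``text`` safe as one backslash-delimited ontology path segment.

    Backslashes, slashes and control characters become underscores; the
    segment is trimmed to :data:`MAX_SEGMENT_LEN` characters. Collisions
    introduced by sanitization are the caller's responsibility to detect.
    """
    out = _SEGMENT_BAD.sub("_", text).strip()
    return out[:MAX_SEGMENT_LEN]


def sanitize_id(text: str) -> str:
    """Sanitize a source key value for use inside a canonical identifier."""
    out = re.sub(r"[^0-9A-Za-z.\-]", "_", text.strip())
    return out or "_"


def normalize_label(text: str) -> str:
    """Trim outer whitespace and collapse internal whitespace runs.

    Comparison stays case-sensitive: clinically distinct codes that differ
    only in case must not be merged silently.
    """
    return _WS_RUN.sub(" ", text.strip())


def path_code(full_path: str, length: int = 16) -> str:
    """Stable short code for an ontology node: hex digest prefix of its path."""
    return hashlib.sha256(full_path.encode("utf-8")).hexdigest()[:length]


_NUM_DOT = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")
_NUM_COMMA = re.compile(r"^[+-]?\d+(,\d+)?$")


def parse_number(token: str, decimal_separator: str = ".") -> float:
    """Parse a numeric token under the given decimal-separator convention."""
    token = token.strip()
    if decimal_separator == ",":
        if not _NUM_COMMA.match(token):
            raise ValueError(f"not a decimal-comma number: {token!r}")
        token = token.replace(",", ".")
    elif not _NUM_DOT.match(token):
        raise ValueError(f"not a decimal-point number: {token!r}")
    return float(token)


def canonical_number(token: str, decimal_separator: str = ".") -> str:
    """Canonical '.'-decimal rendering of a numeric token.

    Integral values render without a fractional part ("140", not "140.0");
    everything else uses Python's shortest round-tripping float repr.
    """
    value = parse_number(token, decimal_separator)
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return repr(value)


def sha256_hex(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()
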