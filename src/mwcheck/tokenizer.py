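"""Error-tolerant lexer for mwTab flat text.

The grammar is line-oriented: ``#SECTION`` headers, ``CODE:KEY<TAB>VALUE``
item lines, five-field ``SUBJECT_SAMPLE_FACTORS`` lines, and fenced
tab-delimited tables (``MS_METABOLITE_DATA_START`` ... ``_END``).  Real
deposition files violate the grammar in recurring ways; the tokenizer
repairs what can be repaired unambiguously (recording an annotation) and
refuses, with a precise error, what cannot:

* extra empty trailing cells and missing trailing tabs in table rows are
  harmonized against the header (:func:`harmonize_row`);
* a ``#FACTORS`` header (not a real section) is tokenized and flagged
  rather than dropped;
* a missing tab after an item-line prefix, an orphan continuation line
  (embedded carriage return in a value), an ambiguous subject-sample-
  factor fragment, or a repeated ``*_DATA_END`` fence each raise their
  own :class:`~mwcheck.errors.ParseError` subclass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import (
    MissingTabError,
    MultipleDataEndError,
    OrphanLineError,
    ParseError,
    SSFAdditionalDataError,
    SSFFactorError,
)
from .model import (
    DuplicatePreservingMap,
    KNOWN_SECTIONS,
    HEADER_SECTION,
    ParseAnnotations,
    SubjectSampleFactorRecord,
)

__all__ = [
    "Token", "classify_line", "parse_ssf_line", "parse_factor_string",
    "parse_additional_string", "harmonize_row", "tokenize",
]

_FENCE_RE = re.compile(r"^([A-Z][A-Z0-9_]*)_(START|END)\s*$")
_ITEM_PREFIX_RE = re.compile(r"^([A-Z][A-Z0-9_]*):")
_BARE_ITEM_RE = re.compile(r"^([A-Z][A-Z0-9_]*)\t(.*)$", re.S)
_HEADER_ATTR_RE = re.compile(r"([A-Z][A-Z0-9_]*):(\S*)")


@dataclass
class Token:
    kind: str  # SectionHeader | Item | SSFLine | TableBegin | TableHeaderRow
    #        | TableDataRow | TableEnd | Blank
    line_no: int
    #: kind-specific payload: section name + header attrs, item code/key/
    #: value, raw cells of a table row or SSF line, fence name ...
    payload: dict = field(default_factory=dict)


def classify_line(line: str, line_no: int, in_table: bool = False) -> Token:
    """Map one physical line to exactly one token, or raise.

    ``in_table`` switches to cell mode between table fences.  Outside a
    table, a line with an item-code prefix but no tab raises
    :class:`MissingTabError`; an uncapitalized prefix-less line raises
    :class:`OrphanLineError` (the embedded-carriage-return failure
    class).
    """
    stripped = line.rstrip("\n").rstrip("\r")
    if not stripped.strip():
        return Token("Blank", line_no)

    if stripped.startswith("#"):
        body = stripped[1:].strip()
        if body == "END":
            return Token("Blank", line_no)  # trailing end-of-file marker
        if body.startswith(HEADER_SECTION):
            attrs = _HEADER_ATTR_RE.findall(body[len(HEADER_SECTION):])
            return Token("SectionHeader", line_no,
                         {"name": HEADER_SECTION, "attrs": attrs})
        return Token("SectionHeader", line_no, {"name": body, "attrs": []})

    fence = _FENCE_RE.match(stripped)
    if fence and not ("\t" in stripped):
        kind = "TableBegin" if fence.group(2) == "START" else "TableEnd"
        return Token(kind, line_no, {"table": fence.group(1)})

    if in_table:
        return Token("TableDataRow", line_no,
                     {"cells": stripped.split("\t")})

    first_field = stripped.split("\t", 1)[0].strip()
    if first_field == "SUBJECT_SAMPLE_FACTORS":
        return Token("SSFLine", line_no, {"cells": stripped.split("\t")})

    m = _ITEM_PREFIX_RE.match(stripped)
    if m:
        if "\t" not in stripped:
            raise MissingTabError(
                f"item line {stripped[:40]!r} is missing the tab after its "
                f"section code", line_no)
        head, value = stripped.split("\t", 1)
        code = m.group(1)
        key = head[len(code) + 1:].strip()
        return Token("Item", line_no,
                     {"code": code, "key": key, "value": value})

    bare = _BARE_ITEM_RE.match(stripped)
    if bare:
        return Token("Item", line_no,
                     {"code": None, "key": bare.group(1),
                      "value": bare.group(2)})

    raise OrphanLineError(
        f"orphan line {stripped[:40]!r} (no section code; possibly a value "
        f"containing an embedded carriage return)", line_no)


# ---------------------------------------------------------------------
# SUBJECT_SAMPLE_FACTORS
# ---------------------------------------------------------------------

def parse_factor_string(text: str, line_no: int | None = None) -> DuplicatePreservingMap:
    """Split ``key:value | key:value`` factors.

    A fragment with zero or two-plus ``:`` separators is ambiguous and
    refused: guessing would produce an incorrect document, which is
    worse than no document.
    """
    out = DuplicatePreservingMap()
    if not text.strip() or text.strip() == "-":
        return out
    for fragment in text.split("|"):
        fragment = fragment.strip()
        if not fragment:
            continue
        if fragment.count(":") != 1:
            raise SSFFactorError(
                f"ambiguous factors fragment {fragment!r}: expected exactly "
                f"one ':' separator", line_no)
        key, value = fragment.split(":")
        out.append(key.strip(), value.strip())
    return out


def parse_additional_string(text: str, line_no: int | None = None) -> DuplicatePreservingMap:
    """Split ``key=value; key=value`` additional sample data.

    A fragment with anything other than exactly one ``=`` means either a
    missing ``;`` between pairs or an extra ``=``; both make key/value
    assignment ambiguous and are refused.
    """
    out = DuplicatePreservingMap()
    if not text.strip() or text.strip() == "-":
        return out
    for fragment in text.split(";"):
        fragment = fragment.strip()
        if not fragment:
            continue
        if fragment.count("=") != 1:
            raise SSFAdditionalDataError(
                f"ambiguous additional-data fragment {fragment!r}: expected "
                f"exactly one '=' separator (missing ';' or extra '=')",
                line_no)
        key, value = fragment.split("=")
        out.append(key.strip(), value.strip())
    return out


def parse_ssf_line(cells: list[str], line_no: int | None = None,
                   raw_line: str | None = None) -> SubjectSampleFactorRecord:
    """Build a record from the tab-split fields of an SSF line.

    Field layout: tag, subject (may be blank), sample, factors,
    additional data (optional).
    """
    fields = cells[1:] if cells and cells[0].strip() == "SUBJECT_SAMPLE_FACTORS" else list(cells)
    while len(fields) < 4:
        fields.append("")
    subject, sample, factors_text, additional_text = (f.strip() for f in fields[:4])
    if len(fields) > 4 and any(f.strip() for f in fields[4:]):
        raise ParseError(
            f"SUBJECT_SAMPLE_FACTORS line has {len(fields)} fields; "
            f"expected at most 4 after the tag", line_no)
    if subject == "-":
        subject = ""
    return SubjectSampleFactorRecord(
        subject_id=subject,
        sample_id=sample,
        factors=parse_factor_string(factors_text, line_no),
        additional_data=parse_additional_string(additional_text, line_no),
        raw_line=raw_line,
    )


# ---------------------------------------------------------------------
# row harmonization
# ---------------------------------------------------------------------

def harmonize_row(header: list[str], cells: list[str],
                  annotations: ParseAnnotations | None = None,
                  section: str = "", row_index: int = 0) -> list[str]:
    """Force a data row onto exactly the header's columns.

    Trailing empty cells beyond the header are dropped (extra tabs with
    no data tacked onto the row); short rows are padded with empty text
    (the tabs that should be there are not).  A row longer than the
    header with *non-empty* overflow is truncated but recorded in
    ``annotations.header_mismatches`` — the raw material of the
    bad-headers check.  Idempotent on already-harmonized rows.
    """
    cells = list(cells)
    while len(cells) > len(header) and not cells[-1].strip():
        cells.pop()
    if len(cells) > len(header):
        if annotations is not None:
            annotations.header_mismatches.append(
                (section, row_index, len(cells), len(header)))
        cells = cells[:len(header)]
    while len(cells) < len(header):
        cells.append("")
    return cells


# ---------------------------------------------------------------------
# whole-file tokenization
# ---------------------------------------------------------------------

def _prescan_fences(lines: list[str]) -> None:
    """Refuse files where any table's ``*_END`` fence repeats."""
    seen_end: dict[str, int] = {}
    for i, line in enumerate(lines, start=1):
        m = _FENCE_RE.match(line.rstrip("\r\n"))
        if m and m.group(2) == "END":
            name = m.group(1)
            if name in seen_end:
                raise MultipleDataEndError(
                    f"multiple {name}_END lines (first at line "
                    f"{seen_end[name]})", i)
            seen_end[name] = i


def tokenize(text: str) -> tuple[list[Token], ParseAnnotations]:
    """Lex a whole mwTab file into tokens plus parse annotations.

    Tokens come out in file order.  Section headers outside the spec
    vocabulary (the infamous ``#FACTORS`` line) are tokenized normally
    but their line numbers land in ``annotations.bogus_section_lines``.
    Duplicate subsection keys are recorded per section.  Errors from
    :func:`classify_line` propagate with their 1-based line numbers.
    """
    annotations = ParseAnnotations()
    lines = text.splitlines()
    _prescan_fences(lines)

    tokens: list[Token] = []
    in_table: str | None = None
    table_row_seen = False
    current_section = ""
    seen_keys: dict[str, set[str]] = {}
    dup_recorded: set[tuple[str, str]] = set()

    for line_no, line in enumerate(lines, start=1):
        token = classify_line(line, line_no, in_table=in_table is not None)

        if token.kind == "TableBegin":
            in_table = token.payload["table"]
            table_row_seen = False
        elif token.kind == "TableEnd":
            if in_table is None:
                raise MultipleDataEndError(
                    f"unexpected {token.payload['table']}_END outside a "
                    f"table", line_no)
            in_table = None
        elif token.kind == "TableDataRow":
            if not table_row_seen:
                token.kind = "TableHeaderRow"
                table_row_seen = True
        elif token.kind == "SectionHeader":
            name = token.payload["name"]
            current_section = name
            seen_keys.setdefault(name, set())
            if name not in KNOWN_SECTIONS and name != HEADER_SECTION:
                annotations.bogus_section_lines.append(line_no)
        elif token.kind == "Item":
            key = token.payload["key"]
            keys = seen_keys.setdefault(current_section, set())
            if key in keys and (current_section, key) not in dup_recorded:
                annotations.duplicate_subsections.append(
                    (current_section, key))
                dup_recorded.add((current_section, key))
            keys.add(key)

        tokens.append(token)

    if in_table is not None:
        raise ParseError(f"unterminated table {in_table} (missing "
                         f"{in_table}_END)", len(lines))
    return tokens, annotations
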