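"""Reading and writing both analysis-file formats, duplicate-key aware.

The JSON dialect mirrors the repository's own: one top-level object with
a ``METABOLOMICS WORKBENCH`` header member, section members, a
``SUBJECT_SAMPLE_FACTORS`` record list, and data-bearing sections as
objects holding ``Units``/``Data``/``Factors``/``Metabolites``/
``Extended`` members whose tables are lists of row objects.  Duplicate
keys below the top level are legal JSON, occur in real files, and are
preserved in order on both read and write (standard writers refuse
them, so serialization is custom).  Duplicate keys at the *top* level
are refused.

Writers are byte-deterministic: sections and subsections are emitted in
a canonical order, so writing the same document twice yields identical
bytes and every read/write cycle is a fixed point.
"""

from __future__ import annotations

import io
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable

from .errors import (
    JSONParseError,
    NonRecordRowError,
    ParseError,
    TopLevelDuplicateKeyError,
)
from .model import (
    DataTableComposite,
    DuplicatePreservingMap,
    HEADER_SECTION,
    KeyValueBlock,
    MWTabDocument,
    ParseAnnotations,
    SectionContent,
    SubjectSampleFactorRecord,
    TABLE_SECTION_ROLES,
)
from .tokenizer import harmonize_row, parse_ssf_line, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "read_mwtab", "read_json", "write_mwtab", "write_json",
    "read_document", "process_batch", "BatchResult", "BatchRecord",
    "SECTION_WRITE_ORDER",
]

#: Canonical section emission order (the specification's presentation
#: order); METABOLITES and EXTENDED tables follow their data section.
SECTION_WRITE_ORDER = [
    "PROJECT", "STUDY", "SUBJECT", "SUBJECT_SAMPLE_FACTORS", "COLLECTION",
    "TREATMENT", "SAMPLEPREP", "CHROMATOGRAPHY", "ANALYSIS", "MS", "NM",
    "MS_METABOLITE_DATA", "NMR_METABOLITE_DATA", "METABOLITES",
    "EXTENDED_MS_METABOLITE_DATA", "EXTENDED_NMR_METABOLITE_DATA",
    "NMR_BINNED_DATA",
]

_SECTION_CODES = {
    "PROJECT": "PR", "STUDY": "ST", "SUBJECT": "SU", "COLLECTION": "CO",
    "TREATMENT": "TR", "SAMPLEPREP": "SP", "CHROMATOGRAPHY": "CH",
    "ANALYSIS": "AN", "MS": "MS", "NM": "NM",
}

#: Header attributes carried on the ``#METABOLOMICS WORKBENCH`` line
#: itself (everything else becomes a bare item line below it).
_HEADER_LINE_ATTRS = ("STUDY_ID", "ANALYSIS_ID", "PROJECT_ID")

#: Accepted spellings of the anchor header cell of METABOLITES/EXTENDED
#: tables in flat text; anything else is recorded for the
#: missing-header check.
ACCEPTED_ANCHOR_LITERALS = {"metabolite", "metabolite name"}


# ---------------------------------------------------------------------
# source plumbing
# ---------------------------------------------------------------------

def _read_text(source) -> tuple[str, str | None]:
    """Fetch UTF-8 text from a path, string-of-text, or stream."""
    if hasattr(source, "read"):
        data = source.read()
        name = getattr(source, "name", None)
        if isinstance(data, bytes):
            data = data.decode("utf-8")
        return data, name
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8"), str(source)
    if isinstance(source, str):
        if "\n" in source or "\t" in source or source.lstrip().startswith(("#", "{")):
            return source, None
        return Path(source).read_text(encoding="utf-8"), source
    raise TypeError(f"unsupported source {type(source).__name__}")


def _open_sink(sink):
    """Return (stream, should_close); missing directories are created."""
    if sink is None:
        return io.StringIO(), True
    if hasattr(sink, "write"):
        return sink, False
    path = Path(sink)
    if path.parent and not path.parent.exists():
        path.parent.mkdir(parents=True, exist_ok=True)
    return open(path, "w", encoding="utf-8", newline="\n"), True


# ---------------------------------------------------------------------
# mwTab reading
# ---------------------------------------------------------------------

_DATA_SECTIONS = {"MS_METABOLITE_DATA", "NMR_METABOLITE_DATA"}


def read_mwtab(source) -> MWTabDocument:
    """Parse mwTab flat text into a document.

    Lossless with respect to :func:`write_mwtab`; tokenizer errors
    propagate with file identity and line number.
    """
    text, name = _read_text(source)
    try:
        tokens, annotations = tokenize(text)
    except ParseError as exc:
        exc.source = exc.source or name
        raise

    doc = MWTabDocument(source_format="mwtab", annotations=annotations,
                        source_name=name)
    current: str | None = None
    table: DataTableComposite | None = None
    table_section: str | None = None
    pending_units: dict[str, str] = {}

    def _ensure_kv(section: str) -> KeyValueBlock:
        sc = doc.sections.get(section)
        if sc is None:
            sc = SectionContent("key_value_block", KeyValueBlock())
            doc.sections[section] = sc
        return sc.body

    for token in tokens:
        kind = token.kind
        if kind == "Blank":
            continue
        if kind == "SectionHeader":
            name_ = token.payload["name"]
            current = name_
            if name_ == HEADER_SECTION:
                for k, v in token.payload["attrs"]:
                    doc.header.append(k, v)
            elif name_ == "SUBJECT_SAMPLE_FACTORS":
                doc.sections.setdefault(
                    name_, SectionContent("subject_sample_factors", []))
            elif name_ in TABLE_SECTION_ROLES:
                pass  # created when the fence or units line arrives
            else:
                _ensure_kv(name_)
        elif kind == "Item":
            key, value = token.payload["key"], token.payload["value"]
            if current == HEADER_SECTION or current is None:
                doc.header.append(key, value)
            elif key == "UNITS" and current in TABLE_SECTION_ROLES:
                pending_units[current] = value
                sc = doc.sections.get(current)
                if sc is not None and sc.kind == "data_table_composite":
                    sc.body.units = value
            elif current in TABLE_SECTION_ROLES or \
                    current == "SUBJECT_SAMPLE_FACTORS" or \
                    doc.sections.get(current) is not None and \
                    doc.sections[current].kind != "key_value_block":
                # guessing a home for this line would misrepresent the file
                raise ParseError(
                    f"unexpected item line {key!r} in section {current}",
                    token.line_no, source=name)
            else:
                _ensure_kv(current).items.append(key, value)
        elif kind == "SSFLine":
            sc = doc.sections.setdefault(
                "SUBJECT_SAMPLE_FACTORS",
                SectionContent("subject_sample_factors", []))
            try:
                record = parse_ssf_line(token.payload["cells"],
                                        token.line_no)
            except ParseError as exc:
                exc.source = exc.source or name
                raise
            sc.body.append(record)
        elif kind == "TableBegin":
            table_section = current if current in TABLE_SECTION_ROLES else (
                token.payload["table"] if token.payload["table"] in
                TABLE_SECTION_ROLES else current or token.payload["table"])
            role = TABLE_SECTION_ROLES.get(table_section, "DATA")
            sc = doc.sections.get(table_section)
            if sc is not None and sc.kind == "data_table_composite":
                table = sc.body
            else:
                table = DataTableComposite(
                    table_role=role,
                    units=pending_units.get(table_section, ""))
                doc.sections[table_section] = SectionContent(
                    "data_table_composite", table)
        elif kind == "TableHeaderRow":
            assert table is not None and table_section is not None
            cells = list(token.payload["cells"])
            while cells and not cells[-1].strip():
                cells.pop()
            if table.table_role == "DATA" and cells and \
                    cells[0].strip() == "Samples":
                table.columns = ["Metabolite"] + [c.strip() for c in cells[1:]]
                _record_duplicate_columns(doc.annotations, table_section,
                                          table)
            elif table.table_role in ("METABOLITES", "EXTENDED"):
                literal = cells[0].strip() if cells else ""
                if literal.lower().replace("_", " ") not in \
                        ACCEPTED_ANCHOR_LITERALS:
                    doc.annotations.anchor_literals.append(
                        (table_section, literal))
                table.columns = ["Metabolite"] + cells[1:]
                _record_duplicate_columns(doc.annotations, table_section,
                                          table)
            else:
                table.columns = cells
                _record_duplicate_columns(doc.annotations, table_section,
                                          table)
        elif kind == "TableDataRow":
            assert table is not None and table_section is not None
            cells = token.payload["cells"]
            if table.table_role == "DATA" and cells and \
                    cells[0].strip() == "Factors":
                factors = harmonize_row(table.columns, cells)
                table.factors_row = dict(zip(table.samples,
                                             (c.strip() for c in factors[1:])))
                continue
            cells = harmonize_row(table.columns, cells, doc.annotations,
                                  table_section, len(table.rows))
            table.rows.append(DuplicatePreservingMap(
                zip(table.columns, cells)))
        elif kind == "TableEnd":
            table = None
            table_section = None
    return doc


def _record_duplicate_columns(annotations: ParseAnnotations, section: str,
                              table: DataTableComposite) -> None:
    seen: set[str] = set()
    for col in table.columns:
        if col in seen:
            if table.table_role == "DATA":
                annotations.duplicate_sample_columns.append((section, col))
            else:
                annotations.duplicate_column_names.append((section, col))
        seen.add(col)


# ---------------------------------------------------------------------
# mwTab writing
# ---------------------------------------------------------------------

def write_mwtab(doc: MWTabDocument, sink=None) -> str:
    """Serialize a document to mwTab flat text (byte-deterministic)."""
    lines: list[str] = []
    header_line = "#" + HEADER_SECTION
    emitted = set()
    for attr in _HEADER_LINE_ATTRS:
        if attr in doc.header:
            header_line += f" {attr}:{doc.header.first(attr)}"
            emitted.add(attr)
    lines.append(header_line)
    for k, v in doc.header:
        if k not in emitted:
            lines.append(f"{k}\t{'' if v is None else v}")
    emitted.clear()

    for section in _ordered_sections(doc):
        sc = doc.sections[section]
        lines.append(f"#{section}")
        if sc.kind == "key_value_block":
            code = _SECTION_CODES.get(section, section[:2].upper() or "XX")
            for k, v in sc.body.items:
                lines.append(f"{code}:{k}\t{'' if v is None else v}")
        elif sc.kind == "subject_sample_factors":
            for rec in sc.body:
                lines.append("SUBJECT_SAMPLE_FACTORS\t{}\t{}\t{}\t{}".format(
                    rec.subject_id, rec.sample_id, rec.factors_string(),
                    rec.additional_string()))
        else:
            _write_table(lines, section, sc.body)
    lines.append("#END")
    text = "\n".join(lines) + "\n"

    stream, close = _open_sink(sink)
    stream.write(text)
    if close and not isinstance(stream, io.StringIO):
        stream.close()
    return text


def _write_table(lines: list[str], section: str,
                 table: DataTableComposite) -> None:
    if table.units:
        lines.append(f"{section}:UNITS\t{table.units}")
    lines.append(f"{section}_START")
    if table.table_role == "DATA":
        lines.append("\t".join(["Samples"] + table.samples))
        if table.factors_row is not None:
            lines.append("\t".join(
                ["Factors"] + [table.factors_row.get(s, "")
                               for s in table.samples]))
    else:
        lines.append("\t".join(table.columns))
    for row in table.rows:
        if table.table_role == "DATA":
            lines.append("\t".join(
                "" if v is None else str(v) for _, v in row))
        else:
            lines.append("\t".join(
                "" if v is None else str(v) for _, v in row))
    lines.append(f"{section}_END")


def _ordered_sections(doc: MWTabDocument) -> list[str]:
    rank = {name: i for i, name in enumerate(SECTION_WRITE_ORDER)}
    known = [s for s in doc.sections if s in rank]
    unknown = [s for s in doc.sections if s not in rank]
    return sorted(known, key=rank.__getitem__) + unknown


# ---------------------------------------------------------------------
# JSON reading
# ---------------------------------------------------------------------

class _FalseRow:
    """Sentinel serialized as a bare ``false`` table row (synthetic
    stand-in for the repository's defective rows)."""

    def __eq__(self, other):  # pragma: no cover - trivial
        return isinstance(other, _FalseRow)


def read_json(source, force: bool = False) -> MWTabDocument:
    """Parse a JSON analysis file, preserving duplicate keys in order.

    Duplicate keys at the top level are refused.  Non-object values in a
    table row list are refused unless ``force`` is set, in which case
    the rows are skipped and logged with their indices.
    """
    text, name = _read_text(source)
    try:
        top = json.loads(text,
                         object_pairs_hook=DuplicatePreservingMap.from_pairs)
    except json.JSONDecodeError as exc:
        raise JSONParseError(f"malformed JSON: {exc.msg}", exc.lineno,
                             source=name) from exc
    if not isinstance(top, DuplicatePreservingMap):
        raise JSONParseError("top level of the JSON file must be an object",
                             source=name)
    dups = top.duplicate_keys()
    if dups:
        raise TopLevelDuplicateKeyError(
            f"duplicate keys at the top level of the JSON: {dups}",
            source=name)

    doc = MWTabDocument(source_format="json", source_name=name)
    for key, value in top:
        if key == HEADER_SECTION and isinstance(value,
                                                DuplicatePreservingMap):
            doc.header.extend(value.items())
        elif key == "SUBJECT_SAMPLE_FACTORS" and isinstance(value, list):
            doc.sections[key] = SectionContent(
                "subject_sample_factors",
                [_json_ssf_record(v) for v in value])
        elif key in _DATA_SECTIONS and isinstance(value,
                                                  DuplicatePreservingMap):
            _read_json_data_section(doc, key, value, force, name)
        elif key == "NMR_BINNED_DATA" and isinstance(
                value, DuplicatePreservingMap):
            units = value.first("Units", "") or ""
            rows = value.first("Data", [])
            doc.sections[key] = SectionContent(
                "data_table_composite",
                _json_table(rows, "NMR_BINNED", units, force, key, doc))
        elif key == "METABOLITES" and isinstance(value, list):
            doc.sections[key] = SectionContent(
                "data_table_composite",
                _json_table(value, "METABOLITES", "", force, key, doc))
        elif isinstance(value, DuplicatePreservingMap):
            doc.sections[key] = SectionContent(
                "key_value_block", KeyValueBlock(value))
        elif isinstance(value, str):
            doc.header.append(key, value)
        else:
            raise JSONParseError(
                f"unsupported top-level member {key!r} of type "
                f"{type(value).__name__}", source=name)
    return doc


def _json_ssf_record(value) -> SubjectSampleFactorRecord:
    if not isinstance(value, DuplicatePreservingMap):
        raise NonRecordRowError(
            f"SUBJECT_SAMPLE_FACTORS entry is not an object: {value!r}")
    factors = value.first("Factors")
    additional = value.first("Additional sample data")
    return SubjectSampleFactorRecord(
        subject_id=str(value.first("Subject ID", "") or ""),
        sample_id=str(value.first("Sample ID", "") or ""),
        factors=factors.copy() if isinstance(
            factors, DuplicatePreservingMap) else DuplicatePreservingMap(),
        additional_data=additional.copy() if isinstance(
            additional, DuplicatePreservingMap) else DuplicatePreservingMap(),
    )


def _json_table(rows, role: str, units: str, force: bool, section: str,
                doc: MWTabDocument) -> DataTableComposite:
    table = DataTableComposite(table_role=role, units=units)
    if not isinstance(rows, list):
        raise JSONParseError(
            f"table member of section {section} must be a list")
    kept: list[DuplicatePreservingMap] = []
    for i, row in enumerate(rows):
        if not isinstance(row, DuplicatePreservingMap):
            if force:
                logger.warning(
                    "skipping non-object row %d of %s (force): %r",
                    i, section, row)
                doc.annotations.forced_row_skips.append((section, i))
                continue
            raise NonRecordRowError(
                f"row {i} of {section} is not an object (got {row!r}); "
                f"re-run with force to skip such rows")
        kept.append(DuplicatePreservingMap(
            (k, "" if v is None else str(v)) for k, v in row))
    table.rows = kept
    table.columns = kept[0].keys() if kept else []
    return table


def _read_json_data_section(doc: MWTabDocument, section: str,
                            value: DuplicatePreservingMap, force: bool,
                            name: str | None) -> None:
    units = value.first("Units", "") or ""
    data_rows = value.first("Data", [])
    table = _json_table(data_rows, "DATA", units, force, section, doc)
    factors = value.first("Factors")
    if isinstance(factors, DuplicatePreservingMap):
        table.factors_row = {k: str(v) for k, v in factors}
    doc.sections[section] = SectionContent("data_table_composite", table)

    metabolites = value.first("Metabolites")
    if isinstance(metabolites, list):
        doc.sections["METABOLITES"] = SectionContent(
            "data_table_composite",
            _json_table(metabolites, "METABOLITES", "", force,
                        "METABOLITES", doc))
    extended = value.first("Extended")
    if isinstance(extended, list):
        ext_name = "EXTENDED_" + section
        doc.sections[ext_name] = SectionContent(
            "data_table_composite",
            _json_table(extended, "EXTENDED", "", force, ext_name, doc))


# ---------------------------------------------------------------------
# JSON writing
# ---------------------------------------------------------------------

def _json_scalar(value) -> str:
    return json.dumps(value, ensure_ascii=False)


def _dump(obj, indent: int, out: list[str]) -> None:
    pad = " " * indent
    child_pad = " " * (indent + 4)
    if isinstance(obj, _FalseRow):
        out.append("false")
    elif isinstance(obj, (DuplicatePreservingMap, dict)):
        items = obj.items() if isinstance(obj, DuplicatePreservingMap) \
            else list(obj.items())
        if not items:
            out.append("{}")
            return
        out.append("{\n")
        for i, (k, v) in enumerate(items):
            out.append(f"{child_pad}{_json_scalar(str(k))}: ")
            _dump(v, indent + 4, out)
            out.append(",\n" if i < len(items) - 1 else "\n")
        out.append(pad + "}")
    elif isinstance(obj, list):
        if not obj:
            out.append("[]")
            return
        out.append("[\n")
        for i, v in enumerate(obj):
            out.append(child_pad)
            _dump(v, indent + 4, out)
            out.append(",\n" if i < len(obj) - 1 else "\n")
        out.append(pad + "]")
    else:
        out.append(_json_scalar(obj))


def dumps_duplicate_aware(obj) -> str:
    """JSON text that re-emits repeated keys as repeated members."""
    out: list[str] = []
    _dump(obj, 0, out)
    return "".join(out) + "\n"


def write_json(doc: MWTabDocument, sink=None) -> str:
    """Serialize a document to the JSON dialect (byte-deterministic)."""
    top = DuplicatePreservingMap()
    if len(doc.header):
        top.append(HEADER_SECTION, doc.header.copy())

    handled: set[str] = set()
    for section in _ordered_sections(doc):
        if section in handled:
            continue
        sc = doc.sections[section]
        if sc.kind == "key_value_block":
            top.append(section, sc.body.items.copy())
        elif sc.kind == "subject_sample_factors":
            top.append(section, [_ssf_to_json(r) for r in sc.body])
        elif section in _DATA_SECTIONS:
            member = DuplicatePreservingMap()
            table = sc.body
            if table.units:
                member.append("Units", table.units)
            member.append("Data", [r if isinstance(r, _FalseRow) else r.copy()
                                   for r in table.rows])
            if table.factors_row is not None:
                member.append("Factors", DuplicatePreservingMap(
                    table.factors_row.items()))
            met = doc.sections.get("METABOLITES")
            if met is not None:
                member.append("Metabolites", [r.copy() for r in met.body.rows])
                handled.add("METABOLITES")
            ext_name = "EXTENDED_" + section
            ext = doc.sections.get(ext_name)
            if ext is not None:
                member.append("Extended", [r.copy() for r in ext.body.rows])
                handled.add(ext_name)
            top.append(section, member)
        elif section == "NMR_BINNED_DATA":
            member = DuplicatePreservingMap()
            if sc.body.units:
                member.append("Units", sc.body.units)
            member.append("Data", [r.copy() for r in sc.body.rows])
            top.append(section, member)
        else:
            # METABOLITES/EXTENDED without a host data section
            top.append(section, [r.copy() for r in sc.body.rows])

    text = dumps_duplicate_aware(top)
    stream, close = _open_sink(sink)
    stream.write(text)
    if close and not isinstance(stream, io.StringIO):
        stream.close()
    return text


def _ssf_to_json(rec: SubjectSampleFactorRecord) -> DuplicatePreservingMap:
    out = DuplicatePreservingMap()
    out.append("Subject ID", rec.subject_id)
    out.append("Sample ID", rec.sample_id)
    out.append("Factors", rec.factors.copy())
    if len(rec.additional_data):
        out.append("Additional sample data", rec.additional_data.copy())
    return out


# ---------------------------------------------------------------------
# format sniffing + batch processing
# ---------------------------------------------------------------------

def detect_format(text: str) -> str:
    return "json" if text.lstrip()[:1] == "{" else "mwtab"


def read_document(source, force: bool = False) -> MWTabDocument:
    """Read either format, sniffing from the content."""
    text, name = _read_text(source)
    if detect_format(text) == "json":
        doc = read_json(text, force=force)
    else:
        doc = read_mwtab(text)
    doc.source_name = doc.source_name or name
    return doc


@dataclass
class BatchRecord:
    input_id: str
    outcome: str  # ok | parse_error | write_error | skipped
    detail: str = ""
    result: Any = None


@dataclass
class BatchResult:
    records: list[BatchRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    @property
    def ok(self) -> list[BatchRecord]:
        return [r for r in self.records if r.outcome == "ok"]

    @property
    def failed(self) -> list[BatchRecord]:
        return [r for r in self.records if r.outcome != "ok"]


def process_batch(inputs: Iterable, operation: Callable[[Any], Any],
                  output_dir=None) -> BatchResult:
    """Apply *operation* to every input; a failure never aborts the batch.

    One outcome record per input, always.  ``output_dir`` (with any
    missing parents) is created up front so write closures need not
    worry about it.
    """
    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
    result = BatchResult()
    for item in inputs:
        ident = str(item)
        try:
            value = operation(item)
        except ParseError as exc:
            result.records.append(
                BatchRecord(ident, "parse_error", str(exc)))
        except OSError as exc:
            result.records.append(
                BatchRecord(ident, "write_error", str(exc)))
        except Exception as exc:  # noqa: BLE001 - batch must survive anything
            result.records.append(
                BatchRecord(ident, "parse_error",
                            f"{type(exc).__name__}: {exc}"))
        else:
            result.records.append(BatchRecord(ident, "ok", result=value))
    return result
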