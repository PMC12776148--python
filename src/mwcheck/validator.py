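"""The categorized validation suite: 36 checks plus structural schema.

Every check has a numeric id, a short name, a severity (warning or
error), category tags (format / value / consistency) and an
applicability set of source formats.  A handful of checks are by nature
visible only in flat mwTab text (duplicate subsections, header/row
mismatches, the factors preamble, duplicated sample columns, duplicated
column names) because JSON objects overwrite repeated keys; conversely
per-row column inconsistency can only arise in JSON row objects.

Contracts that matter:

* :func:`validate` never raises on any parsable document — an internal
  check failure becomes a message, not an exception;
* output is deterministic across calls and processes;
* repeated findings of one root cause are condensed to a single message
  per (id, section, subsection-or-column) carrying an occurrence count;
* message wording is aware of whether the source was tabular or JSON.

The severity and category maps are declared data on the registry and are
configurable; only the always-warning nature of the rename suggestion
(id 15) is fixed by the design.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .columns import (
    ColumnRegistry,
    default_registry,
    find_standard_columns,
    normalize_column_name,
    validate_column_values,
)
from .model import (
    DataTableComposite,
    MWTabDocument,
    ValidationMessage,
)
from .mwschema import SchemaRule, validate_structure
from .tokenizer import parse_factor_string

__all__ = [
    "CheckSpec", "StatusRecord", "CHECK_REGISTRY", "validate", "categorize",
    "check_subject_sample_factors", "check_metabolite_tables",
    "check_generic_tables", "check_standard_columns", "check_factor_match",
    "NEAR_CONSTANT_THRESHOLD", "NEAR_CONSTANT_MIN_CELLS",
]

#: Modal-value share at (or above) which a column counts as
#: near-constant, computed over non-empty cells; a fully constant
#: column does not fire.
NEAR_CONSTANT_THRESHOLD = 0.90
#: Minimum number of non-empty cells before the near-constant check can
#: fire at all, to avoid flagging tiny tables.
NEAR_CONSTANT_MIN_CELLS = 10

_BOTH = frozenset({"mwtab", "json"})
_MWTAB_ONLY = frozenset({"mwtab"})
_JSON_ONLY = frozenset({"json"})


@dataclass(frozen=True)
class CheckSpec:
    id: int
    short_name: str
    severity: str
    categories: frozenset
    applicability: frozenset
    description: str


def _spec(id_, name, severity, categories, applicability, description):
    return CheckSpec(id_, name, severity, frozenset(categories),
                     applicability, description)


_WARNING_IDS = {15, 17, 18, 19, 20, 28, 31}
_CONSISTENCY_IDS = {3, 7, 9, 12, 17, 18, 22}
_FORMAT_IDS = {1, 2, 21, 24, 25, 26, 30, 32, 33, 34}

_SHORT_NAMES = {
    1: "Duplicate Sub-section", 2: "Bad Headers", 3: "Factor Mismatch",
    4: "Duplicate Sample ID in SSF", 5: "Duplicate Factors in SSF",
    6: "Duplicate Additional Data", 7: "Missing Sample ID(s) in SSF",
    8: "Duplicate Samples in DATA",
    9: "Metabolite(s) in DATA not METABOLITES",
    10: "Blank Metabolite(s) in DATA",
    11: "Duplicate Metabolite(s) in DATA",
    12: "Metabolite(s) in METABOLITES not DATA",
    13: "Blank Metabolite(s) in METABOLITES",
    14: "Duplicate Metabolite(s) in METABOLITES",
    15: "Standard Column Name Match", 16: "METABOLITES Bad Standard Values",
    17: "Missing Implied Column", 18: "Paired Columns Value Mismatch",
    19: '"other_id" Column', 20: "Multiple Standard Name Match",
    21: 'Missing "sample_id" in EXTENDED',
    22: "Missing Sample ID(s) in EXTENDED", 23: "Bad Metabolite Name",
    24: "JSON Schema Error", 25: "Inconsistent Columns",
    26: "Column With No Name", 27: "Null Column",
    28: "Possible Bad Column Values", 29: "Duplicate Rows",
    30: "Duplicate Column Names", 31: "Multiple Polarities",
    32: "No MS or NM Section", 33: "Missing METABOLITES Section",
    34: "Missing Header", 35: "Blank Sample ID(s) in EXTENDED",
    36: "Blank Metabolite(s) in EXTENDED",
}

_DESCRIPTIONS = {
    1: "The same sub-section appears twice in a section.",
    2: "A table section has a mismatch between the number of columns in "
       "data rows and the header row.",
    3: "The factors in the data table and SUBJECT_SAMPLE_FACTORS do not "
       "match.",
    25: "A table has at least one row with different columns than another.",
}


def _applicability(id_: int) -> frozenset:
    if id_ in {1, 2, 3, 8, 30}:
        return _MWTAB_ONLY
    if id_ == 25:
        return _JSON_ONLY
    return _BOTH


def _categories(id_: int) -> frozenset:
    cats = set()
    if id_ in _CONSISTENCY_IDS:
        cats.add("consistency")
    if id_ in _FORMAT_IDS:
        cats.add("format")
    if not cats or id_ not in _FORMAT_IDS | _CONSISTENCY_IDS:
        cats.add("value")
    return frozenset(cats)


CHECK_REGISTRY: dict[int, CheckSpec] = {
    i: _spec(i, _SHORT_NAMES[i],
             "warning" if i in _WARNING_IDS else "error",
             _categories(i), _applicability(i),
             _DESCRIPTIONS.get(i, _SHORT_NAMES[i]))
    for i in range(1, 37)
}


@dataclass
class StatusRecord:
    """Per-document status tier plus error-category flags."""

    status: str  # Passing | Warnings Only | Errors
    has_consistency_errors: bool = False
    has_value_errors: bool = False
    has_format_errors: bool = False
    message_count: int = 0


def categorize(messages: list[ValidationMessage]) -> StatusRecord:
    """Passing = no messages; Warnings Only = only warnings; otherwise
    Errors, with a flag per category carried by any non-warning."""
    if not messages:
        return StatusRecord("Passing")
    errors = [m for m in messages if m.severity != "warning"]
    rec = StatusRecord("Warnings Only" if not errors else "Errors",
                       message_count=len(messages))
    for m in errors:
        if "consistency" in m.categories:
            rec.has_consistency_errors = True
        if "value" in m.categories:
            rec.has_value_errors = True
        if "format" in m.categories:
            rec.has_format_errors = True
    return rec


# ---------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------

_HEADER_LIKE_NAMES = {
    "metabolite", "metabolite name", "metabolite id", "compound name",
    "bin range(ppm)", "samples", "compound",
}


class _Emitter:
    """Collects condensed, format-aware messages for one document."""

    def __init__(self, doc: MWTabDocument):
        self.doc = doc
        self.messages: list[ValidationMessage] = []
        self.row_word = "row" if doc.source_format == "mwtab" else "entry"
        self.col_word = "column" if doc.source_format == "mwtab" else "key"

    def emit(self, id_: int, section: str, subsection: str, text: str,
             count: int = 1) -> None:
        spec = CHECK_REGISTRY[id_]
        self.messages.append(ValidationMessage(
            id=id_, short_name=spec.short_name, severity=spec.severity,
            categories=spec.categories, section=section,
            subsection=subsection, message=text, count=count))


def _anchor_column(table: DataTableComposite) -> str | None:
    if "Metabolite" in table.columns:
        return "Metabolite"
    for col in table.columns:
        if normalize_column_name(col) in ("metabolite", "metabolite name"):
            return col
    return table.columns[0] if table.columns else None


def _anchor_values(table: DataTableComposite) -> list[str]:
    col = _anchor_column(table)
    if col is None:
        return []
    out = []
    for row in table.rows:
        vals = row.get(col)
        out.append("" if not vals or vals[0] is None else str(vals[0]))
    return out


def _column_values(table: DataTableComposite, col: str) -> list[str]:
    """All cells of *col* across rows, duplicate columns flattened."""
    out: list[str] = []
    for row in table.rows:
        out.extend("" if v is None else str(v) for v in row.get(col))
    return out


def _nonblank(values) -> list[str]:
    return [v for v in values if v is not None and str(v).strip()]


def _find_matching_column(table: DataTableComposite, canonical: str,
                          registry: ColumnRegistry) -> str | None:
    for col in table.columns:
        if canonical in registry and registry[canonical].matches_name(col):
            return col
    return None


# ---------------------------------------------------------------------
# check groups
# ---------------------------------------------------------------------

def check_subject_sample_factors(doc: MWTabDocument,
                                 em: _Emitter) -> None:
    """ids 4-7: duplicate sample IDs / factor keys / additional-data
    keys within SUBJECT_SAMPLE_FACTORS, and data-table samples missing
    from it."""
    records = doc.ssf_records()
    section = "SUBJECT_SAMPLE_FACTORS"
    if records:
        counts = Counter(r.sample_id for r in records if r.sample_id.strip())
        dups = sorted(k for k, n in counts.items() if n > 1)
        if dups:
            em.emit(4, section, "Sample ID",
                    f"Sample ID(s) {', '.join(dups)} appear more than once "
                    f"in {section}", count=len(dups))
        fdup = sum(1 for r in records if r.factors.has_duplicates)
        if fdup:
            em.emit(5, section, "Factors",
                    f"{fdup} {em.row_word}(s) in {section} repeat a factor "
                    f"name", count=fdup)
        adup = sum(1 for r in records
                   if r.additional_data.has_duplicates)
        if adup:
            em.emit(6, section, "Additional sample data",
                    f"{adup} {em.row_word}(s) in {section} repeat an "
                    f"additional-data key", count=adup)

    ssf_ids = {r.sample_id for r in records}
    for name, table in doc.tables_by_role("DATA"):
        missing = [s for s in dict.fromkeys(table.samples)
                   if s.strip() and s not in ssf_ids]
        if missing:
            em.emit(7, section, name,
                    f"Sample ID(s) {', '.join(missing)} in {name} are not "
                    f"in {section}", count=len(missing))


def check_metabolite_tables(doc: MWTabDocument, em: _Emitter) -> None:
    """ids 8-14, 21-23, 32, 33, 35, 36: set comparisons between the
    DATA/METABOLITES/EXTENDED tables, blank and duplicated names, and
    missing analytical/annotation sections."""
    data_tables = doc.tables_by_role("DATA")
    met = doc.sections.get("METABOLITES")
    met_table = met.body if met is not None else None

    if "MS" not in doc.sections and "NM" not in doc.sections:
        em.emit(32, "", "", 'The file does not have a "MS" or "NM" '
                           'section; at least one is required')
    if data_tables and met_table is None:
        em.emit(33, data_tables[0][0], "",
                f"{data_tables[0][0]} is present but there is no "
                f"METABOLITES section")

    for section, dup_list in (
            [(n, doc.annotations.duplicate_sample_columns) for n, _ in
             data_tables]):
        dups = [c for s, c in dup_list if s == section]
        if dups and doc.source_format == "mwtab":
            em.emit(8, section, ", ".join(sorted(set(dups))),
                    f"Sample column(s) {sorted(set(dups))} appear more "
                    f"than once in {section}", count=len(dups))

    def name_checks(section: str, table: DataTableComposite,
                    blank_id: int, dup_id: int) -> set[str]:
        names = _anchor_values(table)
        blanks = sum(1 for v in names if not v.strip())
        if blanks:
            em.emit(blank_id, section, "Metabolite",
                    f"{blanks} metabolite {em.row_word}(s) in {section} "
                    f"have a blank or null name", count=blanks)
        counts = Counter(v for v in names if v.strip())
        dups = sorted(k for k, n in counts.items() if n > 1)
        if dups:
            em.emit(dup_id, section, "Metabolite",
                    f"Metabolite(s) {', '.join(dups[:5])} appear more than "
                    f"once in {section}", count=len(dups))
        bad = sorted({v for v in names
                      if normalize_column_name(v) in _HEADER_LIKE_NAMES})
        if bad:
            em.emit(23, section, "Metabolite",
                    f"Metabolite name(s) {bad} look like table headers, "
                    f"not metabolites", count=len(bad))
        return {v for v in names if v.strip()}

    met_names: set[str] | None = None
    if met_table is not None:
        met_names = name_checks("METABOLITES", met_table, 13, 14)
    for section, table in data_tables:
        data_names = name_checks(section, table, 10, 11)
        if met_names is not None:
            only_data = sorted(data_names - met_names)
            if only_data:
                em.emit(9, section, "Metabolite",
                        f"{len(only_data)} metabolite(s) in {section} are "
                        f"not in METABOLITES (e.g. {only_data[:3]})",
                        count=len(only_data))
            only_met = sorted(met_names - data_names)
            if only_met:
                em.emit(12, "METABOLITES", "Metabolite",
                        f"{len(only_met)} metabolite(s) in METABOLITES are "
                        f"not in {section} (e.g. {only_met[:3]})",
                        count=len(only_met))

    registry = default_registry()
    ssf_ids = {r.sample_id for r in doc.ssf_records() if r.sample_id.strip()}
    for section, table in doc.tables_by_role("EXTENDED"):
        sid_col = _find_matching_column(table, "sample_id", registry)
        if sid_col is None:
            em.emit(21, section, "sample_id",
                    f'{section} is missing the required "sample_id" '
                    f'{em.col_word}')
        else:
            sid_values = _column_values(table, sid_col)
            blanks = sum(1 for v in sid_values if not v.strip())
            if blanks:
                em.emit(35, section, sid_col,
                        f"{blanks} Sample ID(s) in {section} are blank or "
                        f"null", count=blanks)
            present = set(_nonblank(sid_values))
            missing = sorted(ssf_ids - present)
            if missing:
                em.emit(22, section, sid_col,
                        f"{section} has no entries for Sample ID(s) "
                        f"{missing}", count=len(missing))
        blanks = sum(1 for v in _anchor_values(table) if not v.strip())
        if blanks:
            em.emit(36, section, "Metabolite",
                    f"{blanks} Metabolite name(s) in {section} are blank "
                    f"or null", count=blanks)


def check_generic_tables(doc: MWTabDocument, em: _Emitter) -> None:
    """ids 1, 2, 25-30, 34: format-bound annotations plus column- and
    row-level table hygiene that applies to every table role."""
    ann = doc.annotations
    if doc.source_format == "mwtab":
        for section, key in dict.fromkeys(ann.duplicate_subsections):
            em.emit(1, section, key,
                    f"sub-section {key} appears more than once in "
                    f"{section}")
        mism = Counter(section for section, *_ in ann.header_mismatches)
        for section, n in sorted(mism.items()):
            em.emit(2, section, "",
                    f"{n} row(s) in {section} carry more data cells than "
                    f"the header has columns", count=n)
        dupcols = Counter((s, c) for s, c in ann.duplicate_column_names)
        for (section, col), n in sorted(dupcols.items()):
            em.emit(30, section, col,
                    f"column name {col!r} appears more than once in "
                    f"{section}", count=n)

    for section, table in doc.tables():
        if not table.columns:
            continue
        if doc.source_format == "json":
            consensus = table.columns
            bad = sum(1 for row in table.rows
                      if row.keys() != consensus)
            if bad:
                em.emit(25, section, "",
                        f"{bad} {em.row_word}(s) of {section} have "
                        f"different {em.col_word}s than the first",
                        count=bad)
        unnamed = [c for c in table.columns if not str(c).strip()]
        if unnamed:
            em.emit(26, section, "",
                    f"{len(unnamed)} {em.col_word}(s) in {section} have no "
                    f"name", count=len(unnamed))
        for col in dict.fromkeys(table.columns):
            values = _column_values(table, col)
            nonblank = _nonblank(values)
            if values and not nonblank:
                em.emit(27, section, str(col),
                        f"every value of {em.col_word} {col!r} in {section} "
                        f"is null or blank", count=len(values))
                continue
            if len(nonblank) >= NEAR_CONSTANT_MIN_CELLS:
                top = Counter(nonblank).most_common(1)[0][1]
                share = top / len(nonblank)
                if NEAR_CONSTANT_THRESHOLD <= share < 1.0:
                    em.emit(28, section, str(col),
                            f"{share:.0%} of the values of {em.col_word} "
                            f"{col!r} in {section} are identical; the rest "
                            f"differ and may be mistakes",
                            count=len(nonblank) - top)
        seen: dict[tuple, int] = {}
        dup_rows = 0
        for row in table.rows:
            key = tuple(row.items())
            dup_rows += key in seen
            seen[key] = 1
        if dup_rows:
            em.emit(29, section, "",
                    f"{dup_rows} {em.row_word}(s) in {section} are exact "
                    f"duplicates of another", count=dup_rows)

    # missing/wrong required anchor header (34)
    required_anchor_roles = {"DATA", "METABOLITES"}
    for section, table in doc.tables():
        if table.table_role in required_anchor_roles and table.columns \
                and "Metabolite" not in table.columns:
            em.emit(34, section, "Metabolite",
                    f'{section} is missing the required "Metabolite" '
                    f'{em.col_word}')
    if doc.source_format == "mwtab":
        from .fileio import ACCEPTED_ANCHOR_LITERALS
        for section, literal in dict.fromkeys(ann.anchor_literals):
            if normalize_column_name(literal) not in \
                    ACCEPTED_ANCHOR_LITERALS:
                em.emit(34, section, "Metabolite",
                        f"the header of {section} names its first column "
                        f"{literal!r} instead of the required "
                        f'"Metabolite"')


def check_standard_columns(doc: MWTabDocument, em: _Emitter,
                           registry: ColumnRegistry | None = None) -> None:
    """ids 15-20, 31: standard-name matching on the METABOLITES table."""
    registry = registry or default_registry()
    met = doc.sections.get("METABOLITES")
    if met is None or met.kind != "data_table_composite":
        return
    table: DataTableComposite = met.body
    outcomes = find_standard_columns(
        [c for c in table.columns if c != "Metabolite"], registry)
    matched_canonicals: dict[str, str] = {}

    for outcome in outcomes:
        if not outcome.matches:
            continue
        if len(outcome.matches) > 1:
            em.emit(20, "METABOLITES", outcome.raw_name,
                    f"{em.col_word} {outcome.raw_name!r} matches more than "
                    f"one standard name ({sorted(outcome.matches)}); it may "
                    f"be pulling double duty")
        if outcome.is_rename_candidate:
            suggestion = sorted(outcome.matches)[0]
            em.emit(15, "METABOLITES", outcome.raw_name,
                    f"{em.col_word} {outcome.raw_name!r} looks like the "
                    f"standard column {suggestion!r}; consider renaming it")
        if len(outcome.matches) == 1:
            canonical = next(iter(outcome.matches))
            matched_canonicals.setdefault(canonical, outcome.raw_name)
            bad = validate_column_values(
                canonical, _column_values(table, outcome.raw_name), registry)
            if bad:
                em.emit(16, "METABOLITES", outcome.raw_name,
                        f"{len(bad)} value(s) of {em.col_word} "
                        f"{outcome.raw_name!r} do not look like "
                        f"{canonical} values", count=len(bad))
            if canonical == "other_id":
                em.emit(19, "METABOLITES", outcome.raw_name,
                        f'{em.col_word} {outcome.raw_name!r} matches '
                        f'"other_id"; a more specific ID column (e.g. '
                        f'kegg_id or lab_id) is preferable')

    for canonical, raw in sorted(matched_canonicals.items()):
        for partner in registry[canonical].implied_partners:
            if partner not in matched_canonicals:
                em.emit(17, "METABOLITES", raw,
                        f"{em.col_word} {raw!r} ({canonical}) should be "
                        f"paired with a {partner!r} {em.col_word}, which is "
                        f"not present")
            else:
                a = _column_values(table, raw)
                b = _column_values(table,
                                   matched_canonicals[partner])
                mismatches = sum(
                    1 for va, vb in zip(a, b)
                    if bool(str(va).strip()) != bool(str(vb).strip()))
                if mismatches and canonical < partner:
                    em.emit(18, "METABOLITES", raw,
                            f"{mismatches} {em.row_word}(s) have a value in "
                            f"{raw!r} but not in "
                            f"{matched_canonicals[partner]!r} (or vice "
                            f"versa)", count=mismatches)

    if "polarity" in matched_canonicals:
        values = set(_nonblank(_column_values(
            table, matched_canonicals["polarity"])))
        if len(values) > 1:
            em.emit(31, "METABOLITES", matched_canonicals["polarity"],
                    f"polarity {em.col_word} has {len(values)} distinct "
                    f"values {sorted(values)}; one analysis should be a "
                    f"single polarity", count=len(values))


def check_factor_match(doc: MWTabDocument, em: _Emitter) -> None:
    """id 3: the data table's factors preamble vs SUBJECT_SAMPLE_FACTORS
    (mwTab sources only — the JSON twin has no second factor source)."""
    if doc.source_format != "mwtab":
        return
    ssf = {r.sample_id: r for r in doc.ssf_records()}
    for section, table in doc.tables_by_role("DATA"):
        if table.factors_row is None:
            continue
        mismatched = []
        for sample, text in table.factors_row.items():
            rec = ssf.get(sample)
            if rec is None:
                continue  # id 7's concern
            try:
                parsed = parse_factor_string(text)
            except Exception:
                parsed = None
            if parsed is not None:
                same = parsed == rec.factors
            else:
                same = text.strip() == rec.factors_string()
            if not same:
                mismatched.append(sample)
        if mismatched:
            em.emit(3, section, "Factors",
                    f"factors for sample(s) {sorted(mismatched)} in "
                    f"{section} do not match SUBJECT_SAMPLE_FACTORS",
                    count=len(mismatched))


# ---------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------

_CHECK_GROUPS = (
    check_subject_sample_factors,
    check_metabolite_tables,
    check_generic_tables,
    check_standard_columns,
    check_factor_match,
)


def validate(doc: MWTabDocument, source_format: str | None = None,
             registry: ColumnRegistry | None = None,
             schema_rules: list[SchemaRule] | None = None
             ) -> list[ValidationMessage]:
    """Run the full suite on a parsed document.

    Returns the deterministic, condensed message list, sorted by
    (id, section, subsection).  Checks inapplicable to the document's
    source format are skipped.  Never raises: a crashing check is
    reported as a message against its own id group.
    """
    fmt = source_format or doc.source_format
    em = _Emitter(doc)
    em.row_word = "row" if fmt == "mwtab" else "entry"
    em.col_word = "column" if fmt == "mwtab" else "key"

    for group in _CHECK_GROUPS:
        try:
            if group is check_standard_columns:
                group(doc, em, registry)
            else:
                group(doc, em)
        except Exception as exc:  # noqa: BLE001 - crash-freedom contract
            em.messages.append(ValidationMessage(
                id=24, short_name="JSON Schema Error", severity="error",
                categories=frozenset({"format"}), section="", subsection="",
                message=f"internal check failure in {group.__name__}: "
                        f"{type(exc).__name__}: {exc}"))
    try:
        em.messages.extend(validate_structure(doc, schema_rules))
    except Exception as exc:  # noqa: BLE001
        em.messages.append(ValidationMessage(
            id=24, short_name="JSON Schema Error", severity="error",
            categories=frozenset({"format"}), section="", subsection="",
            message=f"internal check failure in validate_structure: "
                    f"{type(exc).__name__}: {exc}"))

    messages = [m for m in em.messages
                if fmt in CHECK_REGISTRY[m.id].applicability]
    messages.sort(key=lambda m: (m.id, m.section, m.subsection, m.message))
    return messages
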