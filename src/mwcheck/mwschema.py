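"""Structural validation against the mwTab specification.

The specification's requirements are transcribed into a declarative
rule table — one :class:`SchemaRule` per (section, subsection) — rather
than code, so drift in the specification is absorbed by data edits.
Three distinct failure kinds are reported, all under validation id 24:

* a required subsection (or whole section) is missing;
* a required subsection is present but blank or null — deliberately a
  *different* finding from absence, because depositors mix the two
  conventions for "no data";
* a value violates its constrained value space (e.g. a STUDY_ID that is
  not ``ST`` + six digits, or ``5 W`` in a voltage field).

Accession patterns follow the universal Metabolomics Workbench
convention: ``ST``/``AN``/``PR`` followed by six digits.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .model import (
    HEADER_SECTION,
    KeyValueBlock,
    MWTabDocument,
    ValidationMessage,
)

__all__ = ["SchemaRule", "id_pattern", "default_rules", "load_rules",
           "validate_structure", "SCHEMA_CHECK_ID"]

SCHEMA_CHECK_ID = 24

_ID_PATTERNS = {
    "study": r"ST\d{6}",
    "analysis": r"AN\d{6}",
    "project": r"PR\d{6}",
}


def id_pattern(kind: str) -> str:
    """Accession pattern for a study/analysis/project identifier."""
    try:
        return _ID_PATTERNS[kind]
    except KeyError:
        raise ValueError(f"unknown accession kind {kind!r}") from None


@dataclass(frozen=True)
class SchemaRule:
    """One declarative requirement on a section's subsection.

    ``value_pattern`` (full-match, case-sensitive unless inlined flags)
    constrains the value space; ``condition_section`` makes the rule
    conditional on another section's presence (the CHROMATOGRAPHY rules
    apply only to mass-spec analyses, i.e. when MS is present).
    """

    section: str
    subsection: str
    required: bool = False
    value_pattern: str | None = None
    condition_section: str | None = None
    custom_message: str = ""

    def __post_init__(self):
        if self.value_pattern is not None:
            re.compile(self.value_pattern)  # must compile


#: Five CHROMATOGRAPHY attributes promoted from optional to required by
#: the 2023-08-01 specification update.
CHROMATOGRAPHY_REQUIRED = (
    "CHROMATOGRAPHY_TYPE", "INSTRUMENT_NAME", "COLUMN_NAME",
    "SOLVENT_A", "SOLVENT_B",
)

_DATE = r"\d{4}-\d{2}-\d{2}"


def default_rules() -> list[SchemaRule]:
    rules: list[SchemaRule] = [
        SchemaRule(HEADER_SECTION, "STUDY_ID", True, id_pattern("study")),
        SchemaRule(HEADER_SECTION, "ANALYSIS_ID", True,
                   id_pattern("analysis")),
        SchemaRule(HEADER_SECTION, "PROJECT_ID", True,
                   id_pattern("project")),
        SchemaRule(HEADER_SECTION, "VERSION", True, r"\d+(\.\d+)?"),
        SchemaRule(HEADER_SECTION, "CREATED_ON", True, _DATE),
        SchemaRule("PROJECT", "PROJECT_TITLE", True),
        SchemaRule("PROJECT", "LAST_NAME", True),
        SchemaRule("PROJECT", "FIRST_NAME", True),
        SchemaRule("PROJECT", "INSTITUTE", True),
        SchemaRule("STUDY", "STUDY_TITLE", True),
        SchemaRule("STUDY", "INSTITUTE", True),
        SchemaRule("STUDY", "LAST_NAME", True),
        SchemaRule("STUDY", "FIRST_NAME", True),
        SchemaRule("SUBJECT", "SUBJECT_TYPE", True),
        SchemaRule("SUBJECT", "SUBJECT_SPECIES", True),
        SchemaRule("COLLECTION", "COLLECTION_SUMMARY", True),
        SchemaRule("TREATMENT", "TREATMENT_SUMMARY", True),
        SchemaRule("SAMPLEPREP", "SAMPLEPREP_SUMMARY", True),
        SchemaRule("ANALYSIS", "ANALYSIS_TYPE", True, r"MS|NMR"),
        # MS/NM subsection rules apply only when that analytical section
        # exists; presence of one of the two is the no-MS-or-NM check's
        # concern, not the schema's.
        SchemaRule("MS", "INSTRUMENT_NAME", True, condition_section="MS"),
        SchemaRule("MS", "INSTRUMENT_TYPE", True, condition_section="MS"),
        SchemaRule("MS", "MS_TYPE", True, condition_section="MS"),
        SchemaRule("MS", "ION_MODE", True, r"POSITIVE|NEGATIVE|UNSPECIFIED",
                   condition_section="MS"),
        SchemaRule("MS", "MS_COMMENTS", True, condition_section="MS"),
        SchemaRule("MS", "CAPILLARY_VOLTAGE", False,
                   r"-?\d+(\.\d+)?\s*(V|kV)?", condition_section="MS",
                   custom_message="expected a voltage"),
        SchemaRule("NM", "INSTRUMENT_NAME", True, condition_section="NM"),
        SchemaRule("NM", "INSTRUMENT_TYPE", True, condition_section="NM"),
        SchemaRule("NM", "NMR_EXPERIMENT_TYPE", True,
                   condition_section="NM"),
    ]
    rules += [SchemaRule("CHROMATOGRAPHY", sub, True,
                         condition_section="MS")
              for sub in CHROMATOGRAPHY_REQUIRED]
    return rules


def load_rules(path) -> list[SchemaRule]:
    """Rule table from a JSON config file (list of rule records)."""
    records = json.loads(Path(path).read_text(encoding="utf-8"))
    return [SchemaRule(
        section=r["section"], subsection=r["subsection"],
        required=bool(r.get("required", False)),
        value_pattern=r.get("value_pattern"),
        condition_section=r.get("condition_section"),
        custom_message=r.get("custom_message", ""),
    ) for r in records]


def dump_rules(rules: list[SchemaRule], path) -> None:
    records = [{k: v for k, v in vars(r).items() if v not in (None, "", False)}
               | {"section": r.section, "subsection": r.subsection}
               for r in rules]
    Path(path).write_text(json.dumps(records, indent=2) + "\n",
                          encoding="utf-8")


# ---------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------

def _message(doc: MWTabDocument, section: str, subsection: str, kind: str,
             text: str, count: int = 1) -> ValidationMessage:
    categories = {"format"}
    if kind == "value_space":
        categories.add("value")
    return ValidationMessage(
        id=SCHEMA_CHECK_ID, short_name="JSON Schema Error", severity="error",
        categories=frozenset(categories), section=section,
        subsection=subsection, message=text, count=count)


def _section_values(doc: MWTabDocument, section: str, subsection: str):
    if section == HEADER_SECTION:
        return doc.header.get(subsection) if subsection in doc.header else None
    block = doc.key_value_section(section)
    if block is None:
        return None
    return block.items.get(subsection) if subsection in block.items else None


def validate_structure(doc: MWTabDocument,
                       rules: list[SchemaRule] | None = None
                       ) -> list[ValidationMessage]:
    """Evaluate the rule table; one condensed message per distinct
    (section, subsection, failure kind).  Never raises on a parsable
    document."""
    rules = default_rules() if rules is None else rules
    fmt_word = "key" if doc.source_format == "json" else "subsection line"
    messages: list[ValidationMessage] = []
    missing_sections_reported: set[str] = set()

    for rule in rules:
        if rule.condition_section and \
                rule.condition_section not in doc.sections:
            continue
        section_present = (rule.section == HEADER_SECTION and len(doc.header)) \
            or rule.section in doc.sections
        if not section_present:
            if rule.required and rule.section not in missing_sections_reported:
                missing_sections_reported.add(rule.section)
                messages.append(_message(
                    doc, rule.section, "", "missing",
                    f"required section {rule.section} is missing"))
            continue
        values = _section_values(doc, rule.section, rule.subsection)
        if values is None:
            if rule.required:
                messages.append(_message(
                    doc, rule.section, rule.subsection, "missing",
                    f"required {fmt_word} {rule.subsection} is not present "
                    f"in the {rule.section} section"))
            continue
        blank = [v for v in values if v is None or str(v).strip() == ""]
        if blank and rule.required:
            kind = ("null" if any(v is None for v in blank) else "blank")
            messages.append(_message(
                doc, rule.section, rule.subsection, "blank",
                f"required {fmt_word} {rule.subsection} in {rule.section} is "
                f"{'null valued' if kind == 'null' else 'present but blank'}",
                count=len(blank)))
        if rule.value_pattern:
            pattern = re.compile(rule.value_pattern)
            bad = [v for v in values
                   if v is not None and str(v).strip()
                   and not pattern.fullmatch(str(v).strip())]
            if bad:
                hint = rule.custom_message or \
                    f"expected to match {rule.value_pattern!r}"
                messages.append(_message(
                    doc, rule.section, rule.subsection, "value_space",
                    f"value {str(bad[0])!r} of {rule.subsection} in "
                    f"{rule.section} does not look right ({hint})",
                    count=len(bad)))
    return messages
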