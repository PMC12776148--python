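"""In-memory representation of one Metabolomics Workbench analysis file.

The model is format-neutral: an analysis parsed from mwTab flat text and
the same analysis parsed from its JSON twin produce equal documents
(modulo parse annotations, which record facts about the *source*, not
the content).  Three deliberate choices shape everything here:

* **Duplicate keys are first-class.**  Real deposition files repeat
  subsection keys, factor names and even sample columns.  All key/value
  content is therefore held in :class:`DuplicatePreservingMap`, which
  keeps every pair in insertion order.
* **Absent, empty and null are three states.**  A key may be missing, be
  present with ``""``, or (in JSON sources) be present with ``None``.
  Depositors mix these conventions, so the model must not collapse them.
* **Cells are text.**  Numeric interpretation happens only inside
  validators; lossless round-tripping trumps typed convenience.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator

__all__ = [
    "DuplicatePreservingMap",
    "ParseAnnotations",
    "KeyValueBlock",
    "SubjectSampleFactorRecord",
    "DataTableComposite",
    "SectionContent",
    "MWTabDocument",
    "ValidationMessage",
    "ConsistencyDifference",
    "DuplicateKeyError",
    "header_fields",
    "table_to_matrix",
    "matrix_to_table",
    "table_to_dataframe",
    "KNOWN_SECTIONS",
    "TABLE_SECTION_ROLES",
    "HEADER_SECTION",
]

HEADER_SECTION = "METABOLOMICS WORKBENCH"

#: Section-name vocabulary of the mwTab specification.  Unknown names
#: still parse but are flagged in :class:`ParseAnnotations`.
KNOWN_SECTIONS = frozenset({
    "PROJECT", "STUDY", "SUBJECT", "SUBJECT_SAMPLE_FACTORS", "COLLECTION",
    "TREATMENT", "SAMPLEPREP", "CHROMATOGRAPHY", "ANALYSIS", "MS", "NM",
    "MS_METABOLITE_DATA", "NMR_METABOLITE_DATA", "NMR_BINNED_DATA",
    "METABOLITES", "EXTENDED_MS_METABOLITE_DATA",
    "EXTENDED_NMR_METABOLITE_DATA",
})

#: table-bearing section name -> role of the table it holds
TABLE_SECTION_ROLES = {
    "MS_METABOLITE_DATA": "DATA",
    "NMR_METABOLITE_DATA": "DATA",
    "METABOLITES": "METABOLITES",
    "EXTENDED_MS_METABOLITE_DATA": "EXTENDED",
    "EXTENDED_NMR_METABOLITE_DATA": "EXTENDED",
    "NMR_BINNED_DATA": "NMR_BINNED",
}


class DuplicateKeyError(KeyError):
    """Raised by :meth:`DuplicatePreservingMap.one` when a key repeats."""


class DuplicatePreservingMap:
    """Ordered key->value container that retains repeated keys.

    Retrieval by key returns *all* values for that key, in order; the
    :meth:`one` accessor yields a single value but errors on duplicates,
    forcing callers to confront duplication rather than silently taking
    the last value.  A map with no repeated keys behaves like a plain
    ordered mapping.
    """

    __slots__ = ("_pairs",)

    def __init__(self, pairs: Iterable[tuple[str, Any]] = ()):
        self._pairs: list[tuple[str, Any]] = [(k, v) for k, v in pairs]

    # -- construction -------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, Any]]) -> "DuplicatePreservingMap":
        return cls(pairs)

    @classmethod
    def from_dict(cls, mapping: dict) -> "DuplicatePreservingMap":
        return cls(mapping.items())

    def append(self, key: str, value: Any) -> None:
        self._pairs.append((key, value))

    def extend(self, pairs: Iterable[tuple[str, Any]]) -> None:
        self._pairs.extend(pairs)

    def remove(self, key: str) -> None:
        """Remove every entry with *key* (no-op if absent)."""
        self._pairs = [(k, v) for k, v in self._pairs if k != key]

    def replace(self, key: str, value: Any) -> None:
        """Replace the first entry for *key* (append if absent)."""
        for i, (k, _) in enumerate(self._pairs):
            if k == key:
                self._pairs[i] = (key, value)
                return
        self._pairs.append((key, value))

    def rename(self, old: str, new: str) -> None:
        self._pairs = [(new if k == old else k, v) for k, v in self._pairs]

    # -- retrieval ----------------------------------------------------
    def get(self, key: str) -> list[Any]:
        """All values stored under *key*, in insertion order."""
        return [v for k, v in self._pairs if k == key]

    def one(self, key: str) -> Any:
        vals = self.get(key)
        if not vals:
            raise KeyError(key)
        if len(vals) > 1:
            raise DuplicateKeyError(f"{key!r} has {len(vals)} values")
        return vals[0]

    def first(self, key: str, default: Any = None) -> Any:
        for k, v in self._pairs:
            if k == key:
                return v
        return default

    def keys(self) -> list[str]:
        """All keys in order, duplicates included."""
        return [k for k, _ in self._pairs]

    def unique_keys(self) -> list[str]:
        seen: dict[str, None] = {}
        for k, _ in self._pairs:
            seen.setdefault(k)
        return list(seen)

    def duplicate_keys(self) -> list[str]:
        counts: dict[str, int] = {}
        for k, _ in self._pairs:
            counts[k] = counts.get(k, 0) + 1
        return [k for k, n in counts.items() if n > 1]

    @property
    def has_duplicates(self) -> bool:
        return bool(self.duplicate_keys())

    def items(self) -> list[tuple[str, Any]]:
        return list(self._pairs)

    def copy(self) -> "DuplicatePreservingMap":
        return DuplicatePreservingMap(self._pairs)

    # -- dunder -------------------------------------------------------
    def __contains__(self, key: str) -> bool:
        return any(k == key for k, _ in self._pairs)

    def __iter__(self) -> Iterator[tuple[str, Any]]:
        return iter(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, DuplicatePreservingMap):
            return self._pairs == other._pairs
        if isinstance(other, dict):
            return not self.has_duplicates and dict(self._pairs) == other
        return NotImplemented

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"DuplicatePreservingMap({self._pairs!r})"


@dataclass
class ParseAnnotations:
    """Facts recorded *during* parsing, never inferred later.

    Empty for a clean file.  These feed the format-bound validations
    (duplicate subsection, bad headers, duplicate columns, wrong anchor
    header) that are invisible in the harmonized in-memory model.
    """

    duplicate_subsections: list[tuple[str, str]] = field(default_factory=list)
    #: (section, 0-based data-row index, observed cell count, header count)
    header_mismatches: list[tuple[str, int, int, int]] = field(default_factory=list)
    #: 1-based line numbers of section headers outside the spec vocabulary
    bogus_section_lines: list[int] = field(default_factory=list)
    duplicate_sample_columns: list[tuple[str, str]] = field(default_factory=list)
    duplicate_column_names: list[tuple[str, str]] = field(default_factory=list)
    #: (section, literal text of the anchor header cell before renaming)
    anchor_literals: list[tuple[str, str]] = field(default_factory=list)
    #: (section, 0-based row index) of rows skipped under force reading
    forced_row_skips: list[tuple[str, int]] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not any(getattr(self, f.name) for f in dataclasses.fields(self))


@dataclass(eq=True)
class KeyValueBlock:
    """A plain ``subsection -> text`` section body."""

    items: DuplicatePreservingMap = field(default_factory=DuplicatePreservingMap)


@dataclass
class SubjectSampleFactorRecord:
    """One SUBJECT_SAMPLE_FACTORS line / JSON record.

    ``raw_line`` keeps the original flat-text line for mwTab sources and
    is excluded from equality, as is everything not part of the content.
    """

    subject_id: str = ""
    sample_id: str = ""
    factors: DuplicatePreservingMap = field(default_factory=DuplicatePreservingMap)
    additional_data: DuplicatePreservingMap = field(default_factory=DuplicatePreservingMap)
    raw_line: str | None = field(default=None, compare=False)

    def factors_string(self) -> str:
        """Serialized factors in canonical ``key:value | key:value`` form."""
        return " | ".join(f"{k}:{v}" for k, v in self.factors)

    def additional_string(self) -> str:
        return "; ".join(f"{k}={v}" for k, v in self.additional_data)


@dataclass
class DataTableComposite:
    """One fenced table: quantification DATA, METABOLITES annotations,
    EXTENDED data or (deprecated) NMR binned data.

    ``columns`` is the full harmonized header including the anchor
    column, which is canonically named ``Metabolite`` for DATA,
    METABOLITES and EXTENDED tables built from mwTab text.  Rows are
    ``column -> cell text`` maps; after harmonization every mwTab row
    carries exactly the header's columns.  ``factors_row`` (DATA tables
    from mwTab sources) maps each sample column to its factor string.
    """

    table_role: str = "DATA"  # DATA | METABOLITES | EXTENDED | NMR_BINNED
    units: str = ""
    columns: list[str] = field(default_factory=list)
    factors_row: dict[str, str] | None = None
    rows: list[Any] = field(default_factory=list)  # DuplicatePreservingMap each

    @property
    def anchor(self) -> str:
        return self.columns[0] if self.columns else ""

    @property
    def samples(self) -> list[str]:
        """Column names after the anchor (sample IDs for DATA tables)."""
        return self.columns[1:]


@dataclass(eq=True)
class SectionContent:
    """Tagged union of the three section body shapes."""

    kind: str  # key_value_block | subject_sample_factors | data_table_composite
    body: Any

    def __post_init__(self) -> None:
        expected = {
            "key_value_block": KeyValueBlock,
            "subject_sample_factors": list,
            "data_table_composite": DataTableComposite,
        }[self.kind]
        if not isinstance(self.body, expected):
            raise TypeError(f"{self.kind} body must be {expected.__name__}")


@dataclass
class MWTabDocument:
    """Ordered, typed representation of one analysis file."""

    header: DuplicatePreservingMap = field(default_factory=DuplicatePreservingMap)
    sections: dict[str, SectionContent] = field(default_factory=dict)
    source_format: str = field(default="mwtab", compare=False)  # mwtab | json
    annotations: ParseAnnotations = field(default_factory=ParseAnnotations, compare=False)
    source_name: str | None = field(default=None, compare=False)

    # convenience accessors ------------------------------------------
    def key_value_section(self, name: str) -> KeyValueBlock | None:
        sc = self.sections.get(name)
        return sc.body if sc and sc.kind == "key_value_block" else None

    def ssf_records(self) -> list[SubjectSampleFactorRecord]:
        sc = self.sections.get("SUBJECT_SAMPLE_FACTORS")
        return sc.body if sc and sc.kind == "subject_sample_factors" else []

    def tables(self) -> list[tuple[str, DataTableComposite]]:
        return [(name, sc.body) for name, sc in self.sections.items()
                if sc.kind == "data_table_composite"]

    def tables_by_role(self, role: str) -> list[tuple[str, DataTableComposite]]:
        return [(n, t) for n, t in self.tables() if t.table_role == role]


@dataclass(frozen=True)
class ValidationMessage:
    """One validation finding, format-aware and condensed.

    ``id`` is the numeric check identifier from the validation registry;
    ``categories`` is a non-empty subset of {format, value, consistency}.
    """

    id: int
    short_name: str
    severity: str  # warning | error
    categories: frozenset[str]
    section: str
    subsection: str
    message: str
    count: int = 1

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("categories must be non-empty")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "short_name": self.short_name,
            "severity": self.severity,
            "categories": sorted(self.categories),
            "section": self.section,
            "subsection": self.subsection,
            "message": self.message,
            "count": self.count,
        }


CONSISTENCY_CATEGORIES = (
    "DATA", "SSF", "SectionKeys", "SubsectionKeys",
    "SubsectionValues", "SubsectionType",
)


@dataclass(frozen=True)
class ConsistencyDifference:
    """One cross-document discrepancy with its category tag."""

    category: str
    path: str
    detail: str

    def __post_init__(self) -> None:
        if self.category not in CONSISTENCY_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------

def header_fields(doc: MWTabDocument) -> dict[str, str]:
    """Present header attributes in stored order; absent ones omitted.

    The METABOLOMICS WORKBENCH block is an open key-value set; the
    conventional attributes (VERSION, CREATED_ON, STUDY_ID, ANALYSIS_ID,
    PROJECT_ID) appear when present, alongside anything else the file
    carries.  An attribute present with a blank value stays present.
    """
    out: dict[str, str] = {}
    for k, v in doc.header:
        out.setdefault(k, v)
    return out


def table_to_matrix(table: DataTableComposite) -> list[list[str]]:
    """Rectangular matrix: header row followed by cell rows.

    Duplicated column names are kept as repeated header cells and every
    data column is retained.  Requires harmonized rows (each row's key
    sequence equals the header); a non-harmonized row is a contract
    violation.
    """
    matrix = [list(table.columns)]
    for i, row in enumerate(table.rows):
        if row.keys() != table.columns:
            raise ValueError(f"row {i} is not harmonized against the header")
        matrix.append([v for _, v in row])
    return matrix


def matrix_to_table(matrix: list[list[str]], table_role: str = "DATA",
                    units: str = "",
                    factors_row: dict[str, str] | None = None) -> DataTableComposite:
    """Inverse of :func:`table_to_matrix` (lossless round trip)."""
    if not matrix:
        raise ValueError("matrix must contain at least a header row")
    header = list(matrix[0])
    rows = []
    for cells in matrix[1:]:
        if len(cells) != len(header):
            raise ValueError("matrix is not rectangular")
        rows.append(DuplicatePreservingMap(zip(header, cells)))
    return DataTableComposite(table_role=table_role, units=units,
                              columns=header, factors_row=factors_row,
                              rows=rows)


def table_to_dataframe(table: DataTableComposite):
    """The table as a pandas DataFrame of text cells (duplicate column
    names allowed, as pandas permits)."""
    import pandas as pd

    matrix = table_to_matrix(table)
    return pd.DataFrame(matrix[1:], columns=matrix[0], dtype=object)
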