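"""Fuzzy matching of tabular column names to canonical standard names.

Depositors spell the same METABOLITES metadata column many ways —
``retention_time`` appears as "ret time", "ret_time" or "retention
time"; ``moverz_quant`` as "mz", "m/z" or "moverz".  Each canonical name
owns a :class:`ColumnFinder`: an ordered list of matching rules applied
to the *normalized* raw name, an optional value validator for the
column's cells, implied-partner links (a ``retention_index`` column
implies a ``retention_index_type`` column) and deliberate-overlap
declarations.  Matching is rule-per-finder rather than a global
edit-distance cutoff, so fuzziness is tuned name by name; ties are
reported, never silently resolved.

The module is table-agnostic — inputs are header lists and value lists —
so it can validate any tabular data, but the prebuilt registry targets
Metabolomics Workbench METABOLITES metadata.  The registry lives in a
human-editable JSON file (``data/column_registry.json``); its contents
are provisional data, correctable without code changes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

__all__ = [
    "ColumnFinder", "MatchOutcome", "ColumnRegistry",
    "normalize_column_name", "match_column_name", "find_standard_columns",
    "validate_column_values", "default_registry",
]

_SEPARATORS = re.compile(r"[\s_\-]+")


def normalize_column_name(raw: str) -> str:
    """Lowercase, strip, and collapse space/underscore/hyphen runs to a
    single space.  Deterministic; the common ground on which all name
    rules operate."""
    return _SEPARATORS.sub(" ", raw.strip().lower()).strip()


@dataclass
class ColumnFinder:
    """Matching and value rules for one canonical column name."""

    canonical_name: str
    name_rules: list[str]
    value_rule: str | None = None
    implied_partners: list[str] = field(default_factory=list)
    exclusive_with: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._name_res = [re.compile(p) for p in self.name_rules]
        # value rules are case-sensitive (a chemical formula is not a
        # formula in lowercase); rules that tolerate case carry an
        # inline (?i:...) group
        self._value_re = (re.compile(self.value_rule)
                          if self.value_rule else None)

    def matches_name(self, raw: str) -> bool:
        norm = normalize_column_name(raw)
        return any(r.fullmatch(norm) for r in self._name_res)

    def accepts_value(self, value: str) -> bool:
        if self._value_re is None:
            return True
        return bool(self._value_re.fullmatch(value.strip()))


@dataclass
class MatchOutcome:
    """Result of matching one raw header entry against the registry."""

    raw_name: str
    matches: set[str]
    bad_value_indices: list[int] = field(default_factory=list)

    @property
    def is_rename_candidate(self) -> bool:
        """True when the column matched but is not already spelled as a
        canonical name (only those feed the rename warning)."""
        return bool(self.matches) and self.raw_name.strip() not in self.matches


class ColumnRegistry:
    """The prebuilt ``column finders`` collection, keyed by canonical
    name, with the implied-partner relation symmetric on load."""

    def __init__(self, finders: list[ColumnFinder]):
        self.finders: dict[str, ColumnFinder] = {}
        for f in finders:
            if f.canonical_name in self.finders:
                raise ValueError(f"duplicate finder {f.canonical_name!r}")
            self.finders[f.canonical_name] = f
        # store the pairing once, readable from both sides
        for f in list(self.finders.values()):
            for partner in f.implied_partners:
                other = self.finders.get(partner)
                if other and f.canonical_name not in other.implied_partners:
                    other.implied_partners.append(f.canonical_name)

    def __len__(self) -> int:
        return len(self.finders)

    def __iter__(self):
        return iter(self.finders.values())

    def __getitem__(self, canonical: str) -> ColumnFinder:
        return self.finders[canonical]

    def __contains__(self, canonical: str) -> bool:
        return canonical in self.finders

    @classmethod
    def from_json(cls, path_or_text) -> "ColumnRegistry":
        if isinstance(path_or_text, (str, Path)) and \
                str(path_or_text).lstrip().startswith("["):
            records = json.loads(str(path_or_text))
        else:
            records = json.loads(Path(path_or_text).read_text(
                encoding="utf-8"))
        return cls([ColumnFinder(
            canonical_name=r["canonical"],
            name_rules=list(r["patterns"]),
            value_rule=r.get("value_pattern"),
            implied_partners=list(r.get("partners", [])),
            exclusive_with=list(r.get("exclusive", [])),
        ) for r in records])


@lru_cache(maxsize=1)
def default_registry() -> ColumnRegistry:
    text = resources.files("mwcheck.data").joinpath(
        "column_registry.json").read_text(encoding="utf-8")
    return ColumnRegistry.from_json(text)


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------

def match_column_name(raw: str, registry: ColumnRegistry | None = None
                      ) -> set[str]:
    """All canonical names whose rules accept the normalized raw name."""
    registry = registry or default_registry()
    return {f.canonical_name for f in registry if f.matches_name(raw)}


def find_standard_columns(header: list[str],
                          registry: ColumnRegistry | None = None
                          ) -> list[MatchOutcome]:
    """One outcome per header entry, in header order."""
    registry = registry or default_registry()
    return [MatchOutcome(raw, match_column_name(raw, registry))
            for raw in header]


def validate_column_values(canonical: str, values: list[str],
                           registry: ColumnRegistry | None = None
                           ) -> list[int]:
    """Indices of non-empty values the canonical column's rule rejects.

    Empty values are never "bad" here — nullness is a separate check's
    concern.  A canonical without a value rule rejects nothing.
    """
    registry = registry or default_registry()
    finder = registry[canonical]
    if finder.value_rule is None:
        return []
    return [i for i, v in enumerate(values)
            if v is not None and str(v).strip()
            and not finder.accepts_value(str(v))]
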