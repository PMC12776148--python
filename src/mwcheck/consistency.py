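"""Cross-document consistency comparison with six difference categories.

"Consistent" means the two parsed documents carry the same data — the
acid test for a repository that serves each analysis in two formats.
Differences are tagged:

* ``SectionKeys`` — a section present in one document only (the classic
  culprit is an empty FACTORS section conjured by a stray ``#FACTORS``
  line in the flat text);
* ``SubsectionKeys`` — a subsection present in one only;
* ``SubsectionValues`` — same subsection, different value;
* ``SubsectionType`` — same subsection, different value *shape* (a
  scalar in one, a list — i.e. a repeated key — in the other, or a null
  against a string);
* ``SSF`` — any difference inside SUBJECT_SAMPLE_FACTORS records;
* ``DATA`` — any difference inside the DATA/METABOLITES/EXTENDED/binned
  table composites.

Table row order and column order are significant: the files are ordered
artifacts and losslessness is the package's promise.  No semantic
equivalence is attempted ("1.0" differs from "1").  Header attributes
are compared as a pseudo-section named after the header block.  The
factors preamble row exists only in flat mwTab text, so it is compared
only when both documents carry one.
"""

from __future__ import annotations

from collections import Counter

from .model import (
    ConsistencyDifference,
    DataTableComposite,
    DuplicatePreservingMap,
    HEADER_SECTION,
    MWTabDocument,
)

__all__ = ["compare_documents", "summarize"]


def _type_name(v) -> str:
    if v is None:
        return "null"
    return type(v).__name__


def _compare_kv(section: str, a: DuplicatePreservingMap,
                b: DuplicatePreservingMap,
                out: list[ConsistencyDifference]) -> None:
    keys = dict.fromkeys(a.unique_keys() + b.unique_keys())
    for key in keys:
        va, vb = a.get(key), b.get(key)
        path = f"{section}/{key}"
        if not va or not vb:
            if bool(va) != bool(vb):
                side = "first" if va else "second"
                out.append(ConsistencyDifference(
                    "SubsectionKeys", path,
                    f"subsection present in the {side} document only"))
            continue
        if len(va) != len(vb):
            out.append(ConsistencyDifference(
                "SubsectionType", path,
                f"{len(va)} value(s) in one document, {len(vb)} in the "
                f"other"))
            continue
        for i, (x, y) in enumerate(zip(va, vb)):
            if type(x) is not type(y) and (x is None or y is None):
                out.append(ConsistencyDifference(
                    "SubsectionType", path,
                    f"value {i}: {_type_name(x)} vs {_type_name(y)}"))
            elif x != y:
                out.append(ConsistencyDifference(
                    "SubsectionValues", path,
                    f"value {i}: {x!r} vs {y!r}"))


def _compare_tables(section: str, a: DataTableComposite,
                    b: DataTableComposite,
                    out: list[ConsistencyDifference]) -> None:
    def diff(detail: str) -> None:
        out.append(ConsistencyDifference("DATA", section, detail))

    if a.units != b.units:
        diff(f"units differ: {a.units!r} vs {b.units!r}")
    if a.columns != b.columns:
        diff(f"columns differ: {a.columns} vs {b.columns}")
    if a.factors_row is not None and b.factors_row is not None \
            and a.factors_row != b.factors_row:
        diff("factors rows differ")
    if len(a.rows) != len(b.rows):
        diff(f"{len(a.rows)} rows vs {len(b.rows)} rows")
    else:
        bad = [i for i, (ra, rb) in enumerate(zip(a.rows, b.rows))
               if ra != rb]
        if bad:
            diff(f"{len(bad)} row(s) differ (first at index {bad[0]})")


def compare_documents(a: MWTabDocument,
                      b: MWTabDocument) -> list[ConsistencyDifference]:
    """All differences between two parsed documents; empty iff
    consistent.  Symmetric in categories and counts (sides swap in the
    detail text)."""
    out: list[ConsistencyDifference] = []
    _compare_kv(HEADER_SECTION, a.header, b.header, out)

    names = dict.fromkeys(list(a.sections) + list(b.sections))
    for name in names:
        sa, sb = a.sections.get(name), b.sections.get(name)
        if sa is None or sb is None:
            side = "first" if sa is not None else "second"
            out.append(ConsistencyDifference(
                "SectionKeys", name,
                f"section present in the {side} document only"))
            continue
        if sa.kind != sb.kind:
            out.append(ConsistencyDifference(
                "SectionKeys", name,
                f"section kind differs: {sa.kind} vs {sb.kind}"))
            continue
        if sa.kind == "key_value_block":
            _compare_kv(name, sa.body.items, sb.body.items, out)
        elif sa.kind == "subject_sample_factors":
            ra, rb = sa.body, sb.body
            if len(ra) != len(rb):
                out.append(ConsistencyDifference(
                    "SSF", name, f"{len(ra)} records vs {len(rb)} records"))
            else:
                bad = [i for i, (x, y) in enumerate(zip(ra, rb)) if x != y]
                if bad:
                    out.append(ConsistencyDifference(
                        "SSF", name,
                        f"{len(bad)} record(s) differ (first at index "
                        f"{bad[0]})"))
        else:
            _compare_tables(name, sa.body, sb.body, out)
    return out


def summarize(differences) -> dict[str, int]:
    """Per-category difference counts (documents may hit several)."""
    counts = Counter(d.category for d in differences)
    return dict(counts)
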