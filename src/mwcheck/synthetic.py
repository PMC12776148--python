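"""Synthetic analysis-file generator and defect injector.

:func:`generate_valid` builds a complete, internally consistent analysis
— header accessions, all required metadata sections, subject-sample
factors, quantification DATA, METABOLITES annotations with
standard-named columns and valid values, optional EXTENDED data — that
passes the full validation suite with zero messages, deterministically
under its seed.  It replaces repository downloads as the package's test
bed.

:func:`inject_defect` mutates a valid fixture so that exactly the
targeted validation id fires (implied ids may fire too: duplicating a
metabolite also makes a set comparison fail).  Defects that are
unrepresentable in a well-formed model (duplicate subsection lines,
ragged rows, duplicate columns, a lying factors preamble) are injected
at the serialized-text level; everything else mutates the model and
re-serializes.

:func:`inject_parse_defect` produces files that must *refuse* to parse,
one per failure class observed in the wild, each raising its designated
:class:`~mwcheck.errors.ParseError` subclass.

The content makes no attempt at statistical realism: uniform random
positive intensities suffice, metabolite names come from a fixed word
list, sample IDs are ``S001...`` and the factor is
``Treatment:{Control,Case}``.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass

from .errors import (
    JSONParseError,
    MissingTabError,
    MultipleDataEndError,
    NonRecordRowError,
    OrphanLineError,
    ParseError,
    SSFAdditionalDataError,
    SSFFactorError,
    TopLevelDuplicateKeyError,
)
from .fileio import _FalseRow, write_json, write_mwtab
from .model import (
    DataTableComposite,
    DuplicatePreservingMap,
    KeyValueBlock,
    MWTabDocument,
    SectionContent,
    SubjectSampleFactorRecord,
)

__all__ = [
    "FixtureSpec", "generate_valid", "inject_defect", "inject_parse_defect",
    "DEFECT_APPLICABILITY", "PARSE_DEFECT_CLASSES", "PARSE_DEFECT_ERRORS",
]

_METABOLITE_WORDS = [
    "glucose", "alanine", "glycine", "serine", "leucine", "isoleucine",
    "valine", "proline", "threonine", "cysteine", "methionine", "lysine",
    "arginine", "histidine", "tyrosine", "tryptophan", "phenylalanine",
    "glutamate", "glutamine", "aspartate", "asparagine", "citrate",
    "succinate", "fumarate", "malate", "pyruvate", "lactate", "ribose",
    "fructose", "sucrose", "maltose", "xylose", "inositol", "creatinine",
    "taurine", "carnitine", "choline", "betaine", "ornithine", "citrulline",
    "uracil", "adenine", "guanine", "cytosine", "thymine", "xanthine",
    "hypoxanthine", "urate", "cholesterol", "palmitate",
]

_FORMULAS = [
    "C6H12O6", "C3H7NO2", "C2H5NO2", "C3H7NO3", "C6H13NO2", "C5H9NO2",
    "C4H9NO3", "C5H11NO2S", "C6H14N2O2", "C6H14N4O2", "C6H9N3O2",
    "C9H11NO3", "C11H12N2O2", "C9H11NO2", "C5H9NO4", "C5H10N2O3",
    "C4H7NO4", "C4H8N2O3", "C6H8O7", "C4H6O4", "C4H4O4", "C4H6O5",
    "C3H4O3", "C3H6O3", "C5H10O5",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic analysis.

    Defaults describe a small but non-degenerate mass-spec analysis:
    four samples split over two treatment levels and twelve metabolites
    (enough non-empty cells for the near-constant-column check to be in
    play).  Identical specs yield byte-identical fixture files.
    """

    seed: int = 0
    n_samples: int = 4
    n_metabolites: int = 12
    analytical_mode: str = "MS"  # MS | NM
    include_extended: bool = False

    def __post_init__(self):
        if self.n_samples < 1 or self.n_metabolites < 1:
            raise ValueError("need at least one sample and one metabolite")
        if self.analytical_mode not in ("MS", "NM"):
            raise ValueError("analytical_mode must be MS or NM")


def _metabolite_names(rng: random.Random, n: int) -> list[str]:
    base = rng.sample(_METABOLITE_WORDS, min(n, len(_METABOLITE_WORDS)))
    i = 2
    while len(base) < n:
        base.extend(f"{w}-{i}" for w in
                    _METABOLITE_WORDS[:n - len(base)])
        i += 1
    return base[:n]


def _kv(pairs) -> SectionContent:
    return SectionContent("key_value_block",
                          KeyValueBlock(DuplicatePreservingMap(pairs)))


def generate_valid(spec: FixtureSpec
                   ) -> tuple[MWTabDocument, str, str]:
    """A Passing document plus its mwTab and JSON serializations."""
    rng = random.Random(spec.seed)
    accession = rng.randrange(1, 10 ** 6)
    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    mets = _metabolite_names(rng, spec.n_metabolites)
    is_ms = spec.analytical_mode == "MS"

    doc = MWTabDocument(source_format="mwtab")
    header = doc.header
    header.append("STUDY_ID", f"ST{accession:06d}")
    header.append("ANALYSIS_ID", f"AN{accession:06d}")
    header.append("PROJECT_ID", f"PR{accession:06d}")
    header.append("VERSION", "1")
    header.append("CREATED_ON",
                  f"2025-{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}")

    doc.sections["PROJECT"] = _kv([
        ("PROJECT_TITLE", f"Synthetic metabolomics project {accession}"),
        ("LAST_NAME", "Doe"), ("FIRST_NAME", "Jane"),
        ("INSTITUTE", "Synthetic University"),
    ])
    doc.sections["STUDY"] = _kv([
        ("STUDY_TITLE", f"Synthetic study {accession}"),
        ("INSTITUTE", "Synthetic University"),
        ("LAST_NAME", "Doe"), ("FIRST_NAME", "Jane"),
    ])
    doc.sections["SUBJECT"] = _kv([
        ("SUBJECT_TYPE", "Mammal"),
        ("SUBJECT_SPECIES", "Mus musculus"),
    ])

    records = []
    factor_levels = ["Control", "Case"]
    for i, sample in enumerate(samples):
        factors = DuplicatePreservingMap(
            [("Treatment", factor_levels[i % 2])])
        additional = DuplicatePreservingMap(
            [("RAW_FILE", f"{sample}.raw"), ("batch", str(1 + i // 2))])
        records.append(SubjectSampleFactorRecord(
            subject_id=f"SU{i + 1:03d}", sample_id=sample,
            factors=factors, additional_data=additional))
    doc.sections["SUBJECT_SAMPLE_FACTORS"] = SectionContent(
        "subject_sample_factors", records)

    doc.sections["COLLECTION"] = _kv([
        ("COLLECTION_SUMMARY", "Plasma collected after overnight fast"),
    ])
    doc.sections["TREATMENT"] = _kv([
        ("TREATMENT_SUMMARY", "Vehicle or compound, single dose"),
    ])
    doc.sections["SAMPLEPREP"] = _kv([
        ("SAMPLEPREP_SUMMARY", "Protein precipitation with methanol"),
    ])
    if is_ms:
        doc.sections["CHROMATOGRAPHY"] = _kv([
            ("CHROMATOGRAPHY_TYPE", "Reversed phase"),
            ("INSTRUMENT_NAME", "Thermo Vanquish"),
            ("COLUMN_NAME", "Waters Acquity BEH C18"),
            ("SOLVENT_A", "water with 0.1% formic acid"),
            ("SOLVENT_B", "acetonitrile with 0.1% formic acid"),
        ])
    doc.sections["ANALYSIS"] = _kv([
        ("ANALYSIS_TYPE", "MS" if is_ms else "NMR"),
    ])
    if is_ms:
        doc.sections["MS"] = _kv([
            ("INSTRUMENT_NAME", "Thermo Q Exactive"),
            ("INSTRUMENT_TYPE", "Orbitrap"),
            ("MS_TYPE", "ESI"),
            ("ION_MODE", "POSITIVE"),
            ("MS_COMMENTS", "Full scan, data dependent MS2"),
        ])
    else:
        doc.sections["NM"] = _kv([
            ("INSTRUMENT_NAME", "Bruker Avance III"),
            ("INSTRUMENT_TYPE", "FT-NMR"),
            ("NMR_EXPERIMENT_TYPE", "1D 1H"),
        ])

    data_section = "MS_METABOLITE_DATA" if is_ms else "NMR_METABOLITE_DATA"
    factors_row = {r.sample_id: r.factors_string() for r in records}
    data = DataTableComposite(
        table_role="DATA",
        units="peak area" if is_ms else "peak intensity",
        columns=["Metabolite"] + samples,
        factors_row=factors_row)
    for met in mets:
        cells = [met] + [f"{rng.uniform(1e3, 9e5):.1f}" for _ in samples]
        data.rows.append(DuplicatePreservingMap(zip(data.columns, cells)))
    doc.sections[data_section] = SectionContent("data_table_composite", data)

    met_table = DataTableComposite(
        table_role="METABOLITES",
        columns=["Metabolite", "moverz_quant", "retention_time", "kegg_id",
                 "formula"])
    kegg_numbers = rng.sample(range(100000), spec.n_metabolites)
    for i, met in enumerate(mets):
        cells = [met,
                 f"{rng.uniform(70, 900):.4f}",
                 f"{rng.uniform(0.5, 20):.2f}",
                 f"C{kegg_numbers[i]:05d}",
                 _FORMULAS[i % len(_FORMULAS)]]
        met_table.rows.append(
            DuplicatePreservingMap(zip(met_table.columns, cells)))
    doc.sections["METABOLITES"] = SectionContent(
        "data_table_composite", met_table)

    if spec.include_extended:
        ext = DataTableComposite(
            table_role="EXTENDED",
            columns=["Metabolite", "sample_id", "peak_area"])
        for sample in samples:
            cells = [mets[0], sample, f"{rng.uniform(1e3, 9e5):.1f}"]
            ext.rows.append(DuplicatePreservingMap(zip(ext.columns, cells)))
        doc.sections["EXTENDED_" + data_section] = SectionContent(
            "data_table_composite", ext)

    return doc, write_mwtab(doc), write_json(doc)


# ---------------------------------------------------------------------
# defect injection keyed by validation id
# ---------------------------------------------------------------------

_MWTAB_ONLY_DEFECTS = {1, 2, 3, 8, 30}
_JSON_ONLY_DEFECTS = {25}

#: (validation id, serialized format) pairs the injector can produce.
DEFECT_APPLICABILITY: dict[int, frozenset] = {
    i: (frozenset({"mwtab"}) if i in _MWTAB_ONLY_DEFECTS
        else frozenset({"json"}) if i in _JSON_ONLY_DEFECTS
        else frozenset({"mwtab", "json"}))
    for i in range(1, 37)
}


def _data_section(doc: MWTabDocument) -> tuple[str, DataTableComposite]:
    return doc.tables_by_role("DATA")[0]


def _met_table(doc: MWTabDocument) -> DataTableComposite:
    return doc.sections["METABOLITES"].body


def _set_anchor(table: DataTableComposite, row_index: int,
                value: str) -> None:
    table.rows[row_index].replace("Metabolite", value)


def _add_column(table: DataTableComposite, name: str,
                values: list[str]) -> None:
    table.columns.append(name)
    for row, value in zip(table.rows, values):
        row.append(name, value)


def _numeric_values(n: int, start: float = 1.0) -> list[str]:
    return [f"{start + 1.37 * i:.2f}" for i in range(n)]


def _new_met_row(table: DataTableComposite, name: str) -> DuplicatePreservingMap:
    cells = {"Metabolite": name, "moverz_quant": "123.4567",
             "retention_time": "9.99", "kegg_id": "C99999",
             "formula": "C7H7NO2"}
    return DuplicatePreservingMap(
        (col, cells.get(col, "1.0")) for col in table.columns)


def _mutate_model(doc: MWTabDocument, validation_id: int,
                  spec: FixtureSpec) -> None:
    records = doc.ssf_records()
    data_name, data = _data_section(doc)
    met = _met_table(doc)
    n = len(met.rows)

    if validation_id == 4:
        records.append(copy.deepcopy(records[0]))
    elif validation_id == 5:
        records[0].factors.append("Treatment", "Case")
        data.factors_row[records[0].sample_id] = records[0].factors_string()
    elif validation_id == 6:
        records[0].additional_data.append("RAW_FILE", "extra.raw")
    elif validation_id == 7:
        _add_column(data, "S999", _numeric_values(len(data.rows)))
    elif validation_id == 9:
        data.rows.append(DuplicatePreservingMap(
            zip(data.columns,
                ["orphanol"] + _numeric_values(len(data.samples)))))
    elif validation_id == 10:
        _set_anchor(data, 0, "")
    elif validation_id == 11:
        _set_anchor(data, 1, data.rows[0].first("Metabolite"))
    elif validation_id == 12:
        met.rows.append(_new_met_row(met, "orphanol"))
    elif validation_id == 13:
        _set_anchor(met, 0, "")
    elif validation_id == 14:
        _set_anchor(met, 1, met.rows[0].first("Metabolite"))
    elif validation_id == 15:
        met.columns[met.columns.index("moverz_quant")] = "m/z"
        for row in met.rows:
            row.rename("moverz_quant", "m/z")
    elif validation_id == 16:
        met.rows[0].replace("kegg_id", "banana")
    elif validation_id == 17:
        _add_column(met, "retention_index", _numeric_values(n, 1200.0))
    elif validation_id == 18:
        _add_column(met, "retention_index", _numeric_values(n, 1200.0))
        _add_column(met, "retention_index_type", ["Fiehn"] * n)
        met.rows[0].replace("retention_index_type", "")
    elif validation_id == 19:
        _add_column(met, "other_id", [f"X-{i}" for i in range(n)])
        _add_column(met, "other_id_type", ["internal"] * n)
    elif validation_id == 20:
        _add_column(met, "mass", _numeric_values(n, 100.0))
    elif validation_id == 21:
        ext = doc.tables_by_role("EXTENDED")[0][1]
        ext.columns[ext.columns.index("sample_id")] = "vial"
        for row in ext.rows:
            row.rename("sample_id", "vial")
    elif validation_id == 22:
        ext = doc.tables_by_role("EXTENDED")[0][1]
        ext.rows.pop()
    elif validation_id == 23:
        _set_anchor(data, 0, "metabolite_name")
    elif validation_id == 24:
        doc.sections["SUBJECT"].body.items.remove("SUBJECT_TYPE")
    elif validation_id == 25:
        met.rows[1].remove("formula")
    elif validation_id == 26:
        idx = len(met.columns) - 1
        met.columns.insert(idx, "")
        for i, row in enumerate(met.rows):
            pairs = row.items()
            pairs.insert(idx, ("", f"x{i}"))
            met.rows[i] = DuplicatePreservingMap(pairs)
    elif validation_id == 27:
        _add_column(met, "comments", [""] * n)
    elif validation_id == 28:
        for i, row in enumerate(met.rows):
            row.replace("formula", "C6H12O6" if i else "C5H10O5")
    elif validation_id == 29:
        data.rows.append(copy.deepcopy(data.rows[0]))
    elif validation_id == 31:
        _add_column(met, "polarity",
                    ["negative"] + ["positive"] * (n - 1))
    elif validation_id == 32:
        doc.sections.pop("MS", None)
        doc.sections.pop("NM", None)
    elif validation_id == 33:
        doc.sections.pop("METABOLITES")
    elif validation_id == 34:
        met.columns[met.columns.index("Metabolite")] = "metabolite_name"
        for row in met.rows:
            row.rename("Metabolite", "metabolite_name")
    elif validation_id == 35:
        ext = doc.tables_by_role("EXTENDED")[0][1]
        ext.rows[0].replace("sample_id", "")
    elif validation_id == 36:
        ext = doc.tables_by_role("EXTENDED")[0][1]
        ext.rows[0].replace("Metabolite", "")
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"no model-level recipe for id {validation_id}")


def _mutate_mwtab_text(text: str, validation_id: int) -> str:
    lines = text.splitlines()

    def find(predicate) -> int:
        for i, line in enumerate(lines):
            if predicate(line):
                return i
        raise AssertionError("expected line not found in fixture text")

    if validation_id == 1:
        i = find(lambda s: s.startswith("CO:COLLECTION_SUMMARY"))
        lines.insert(i + 1, lines[i])
    elif validation_id == 2:
        start = find(lambda s: s.endswith("_METABOLITE_DATA_START"))
        lines[start + 3] = lines[start + 3] + "\tstray\tcells"
    elif validation_id == 3:
        i = find(lambda s: s.startswith("Factors\t"))
        cells = lines[i].split("\t")
        cells[1] = "Treatment:Mismatched"
        lines[i] = "\t".join(cells)
    elif validation_id == 8:
        start = find(lambda s: s.endswith("_METABOLITE_DATA_START"))
        end = find(lambda s: s.endswith("_METABOLITE_DATA_END"))
        for i in range(start + 1, end):
            first = lines[i].split("\t")[1]
            lines[i] = lines[i] + "\t" + first
    elif validation_id == 30:
        start = find(lambda s: s == "METABOLITES_START")
        end = find(lambda s: s == "METABOLITES_END")
        lines[start + 1] += "\tformula"
        for i in range(start + 2, end):
            lines[i] += "\tC2H4O2"
    elif validation_id == 34:
        start = find(lambda s: s == "METABOLITES_START")
        cells = lines[start + 1].split("\t")
        cells[0] = "compound"
        lines[start + 1] = "\t".join(cells)
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"no text-level recipe for id {validation_id}")
    return "\n".join(lines) + "\n"


_TEXT_LEVEL_DEFECTS = {1, 2, 3, 8, 30}
_NEEDS_EXTENDED = {21, 22, 35, 36}


def inject_defect(spec: FixtureSpec, validation_id: int,
                  target_format: str) -> str:
    """Serialized file (in *target_format*) that parses but fails the
    targeted validation id.  Raises ``ValueError`` for pairs outside the
    applicability matrix."""
    if validation_id not in DEFECT_APPLICABILITY:
        raise ValueError(f"unknown validation id {validation_id}")
    if target_format not in DEFECT_APPLICABILITY[validation_id]:
        raise ValueError(
            f"validation {validation_id} is not applicable to "
            f"{target_format} files")
    if validation_id in _NEEDS_EXTENDED and not spec.include_extended:
        spec = FixtureSpec(spec.seed, spec.n_samples, spec.n_metabolites,
                           spec.analytical_mode, include_extended=True)
    if validation_id == 28 and spec.n_metabolites < 11:
        # the near-constant check needs enough non-empty cells to fire
        spec = FixtureSpec(spec.seed, spec.n_samples, 12,
                           spec.analytical_mode, spec.include_extended)
    doc, mwtab_text, _ = generate_valid(spec)

    if validation_id in _TEXT_LEVEL_DEFECTS:
        return _mutate_mwtab_text(mwtab_text, validation_id)
    if validation_id == 34 and target_format == "mwtab":
        return _mutate_mwtab_text(mwtab_text, 34)

    mutated = copy.deepcopy(doc)
    _mutate_model(mutated, validation_id, spec)
    writer = write_mwtab if target_format == "mwtab" else write_json
    return writer(mutated)


# ---------------------------------------------------------------------
# parse-defect injection
# ---------------------------------------------------------------------

PARSE_DEFECT_CLASSES = (
    "ssf_missing_semicolon", "ssf_extra_equals", "ssf_extra_colon",
    "missing_tab", "embedded_carriage_return", "multiple_data_end",
    "json_malformed", "json_false_row", "json_top_level_duplicate",
)

#: defect class -> the designated exception the reader raises
PARSE_DEFECT_ERRORS: dict[str, type[ParseError]] = {
    "ssf_missing_semicolon": SSFAdditionalDataError,
    "ssf_extra_equals": SSFAdditionalDataError,
    "ssf_extra_colon": SSFFactorError,
    "missing_tab": MissingTabError,
    "embedded_carriage_return": OrphanLineError,
    "multiple_data_end": MultipleDataEndError,
    "json_malformed": JSONParseError,
    "json_false_row": NonRecordRowError,
    "json_top_level_duplicate": TopLevelDuplicateKeyError,
}


def inject_parse_defect(spec: FixtureSpec, defect_class: str) -> str:
    """Serialized file whose read raises the class's designated error
    (``json_false_row`` parses under force)."""
    if defect_class not in PARSE_DEFECT_CLASSES:
        raise ValueError(f"unknown parse-defect class {defect_class!r}")
    doc, mwtab_text, json_text = generate_valid(spec)
    lines = mwtab_text.splitlines()

    def find(predicate) -> int:
        for i, line in enumerate(lines):
            if predicate(line):
                return i
        raise AssertionError("expected line not found in fixture text")

    if defect_class == "ssf_missing_semicolon":
        i = find(lambda s: s.startswith("SUBJECT_SAMPLE_FACTORS\t"))
        lines[i] = lines[i].replace("; ", " ", 1)
    elif defect_class == "ssf_extra_equals":
        i = find(lambda s: s.startswith("SUBJECT_SAMPLE_FACTORS\t"))
        lines[i] = lines[i].replace("RAW_FILE=", "RAW_FILE==", 1)
    elif defect_class == "ssf_extra_colon":
        i = find(lambda s: s.startswith("SUBJECT_SAMPLE_FACTORS\t"))
        lines[i] = lines[i].replace("Treatment:", "Treatment:group:", 1)
    elif defect_class == "missing_tab":
        i = find(lambda s: s.startswith("AN:ANALYSIS_TYPE\t"))
        lines[i] = lines[i].replace("\t", " ", 1)
    elif defect_class == "embedded_carriage_return":
        i = find(lambda s: s.startswith("CO:COLLECTION_SUMMARY"))
        lines.insert(i + 1, "collected overnight at four degrees")
    elif defect_class == "multiple_data_end":
        start = find(lambda s: s.endswith("_METABOLITE_DATA_START"))
        fence = lines[start].replace("_START", "_END")
        lines.insert(start + 4, fence)
    elif defect_class == "json_malformed":
        return json_text.rstrip()[:-1]
    elif defect_class == "json_false_row":
        mutated = copy.deepcopy(doc)
        _, data = _data_section(mutated)
        data.rows[0] = _FalseRow()
        return write_json(mutated)
    elif defect_class == "json_top_level_duplicate":
        brace = json_text.index("{")
        return (json_text[:brace + 1] + '\n    "PROJECT": {},' +
                json_text[brace + 1:])
    return "\n".join(lines) + "\n"
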