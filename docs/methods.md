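# Methods

## The problem

A Metabolomics Workbench analysis exists as two text renderings of one
record: mwTab flat text and JSON. Both are produced and consumed by many
hands, and both accumulate defects — structural (missing required
subsections, ragged tables), value-level (an identifier that is not an
identifier, a voltage of "5 W"), and cross-rendering (content present in
one format only). `mwcheck` models the analysis once, format-neutrally,
and makes three activities precise: *parsing* (what can be read, what
must be refused), *validation* (what is wrong, with what severity and
category), and *consistency* (whether two renderings carry the same
data).

## The document model

The in-memory document is a header map plus an ordered set of sections:
key-value blocks, a list of subject-sample-factor records, and table
composites (quantification DATA, METABOLITES annotations, EXTENDED
data, deprecated NMR binned data). Three modeling commitments drive
everything else:

* **Duplicate keys are first-class.** Every key→value collection is a
  `DuplicatePreservingMap`, an ordered pair list that retains repeats.
  Plain dictionaries silently overwrite — exactly the data-loss failure
  mode this package exists to prevent. Retrieval returns *all* values
  for a key; a single-value accessor exists but errors on duplicates,
  so callers must confront duplication explicitly.
* **Absent, empty and null are three distinct states.** Depositors mix
  the "key with null value" and "key not included" conventions for
  missing data; collapsing them would erase a real difference between
  files (and the schema validator words the two failures apart).
* **Cells are text.** Numeric interpretation happens only inside
  validators; lossless round-tripping trumps typed convenience. No
  semantic equivalence is attempted anywhere ("1.0" ≠ "1").

## Parsing policy: repair the unambiguous, refuse the ambiguous

The tokenizer repairs only defects with a single possible reading, and
records each repair as a *parse annotation* (facts observed during
parsing, never inferred later): trailing empty cells beyond a table
header are dropped, short rows are padded, non-empty overflow is
truncated but annotated, a stray `#FACTORS` header creates an (empty,
annotated) section rather than being dropped, and the anchor column of
DATA/METABOLITES tables is always built with the canonical name
`Metabolite`, the literal spelling kept in an annotation. Anything
ambiguous raises a dedicated error class with its 1-based line number: a
factors fragment whose `:` count is not exactly one, an additional-data
fragment whose `=` count is not exactly one (a missing `;` and an extra
`=` are textually the same defect after splitting and share one error
class), an item line missing its tab, an orphan line (the embedded
carriage-return signature), a repeated `*_DATA_END` fence, malformed
JSON, a non-object table row (parseable with `force=True`, which skips
and logs the row), and duplicate keys at the JSON top level. Guessing
would produce a wrong document, which is strictly worse than no
document; repair of pathological files is a separate tool's job, not the
parser's.

Encoding is UTF-8 with a hard error on undecodable bytes.

## Serialization

Writers are byte-deterministic: sections are emitted in the canonical
specification presentation order (PROJECT → STUDY → SUBJECT →
SUBJECT_SAMPLE_FACTORS → COLLECTION → TREATMENT → SAMPLEPREP →
CHROMATOGRAPHY → ANALYSIS → MS/NM → data tables), subsections in stored
order. The JSON writer is custom because standard writers refuse
duplicate members; it re-emits repeats in order, and nests METABOLITES /
EXTENDED tables inside their host data-table section as the repository
does. The JSON writer also includes the `Factors` preamble row (as a
`Factors` member) when the document carries one, so mwTab→JSON round
trips are lossless; since repository-downloaded JSON lacks that row, the
consistency comparator compares factors rows only when both documents
have one. Section order is not part of document equality (writers
canonicalize it); row order and column order are, because the files are
ordered artifacts and losslessness is the package's core promise.

## Validation

The registry enumerates checks 1–36 exactly once each, with severity,
category and applicability as declared data. Applicability encodes what
each format can express: duplicate subsections (1), header/row count
mismatches (2), factors-preamble mismatches (3), duplicated sample
columns (8) and duplicated column names (30) are only observable in
flat text; per-row column inconsistency (25) only in JSON row objects.
Structural schema findings all share id 24, with three failure kinds
(missing, blank/null, value-space violation; the last is dual-tagged
format+value). The schema itself is a declarative rule table —
(section, subsection, required, value-pattern, condition) — loadable
from a JSON config file, so specification drift is a data edit. The five
CHROMATOGRAPHY attributes promoted to required apply only when an MS
section is present; which five the specification promoted is not
machine-readable anywhere, so the table carries the section's headline
fields (type, instrument, column, solvents A/B), correctable as data.
Accession patterns are `ST`/`AN`/`PR` + six digits, the repository-wide
convention.

Severity: only the rename suggestion (15) is fixed as always-warning by
design; the advisory/heuristic checks {17, 18, 19, 20, 28, 31} default
to warnings, everything else to errors. Category defaults: consistency
= {3, 7, 9, 12, 17, 18, 22}; format = {1, 2, 21, 24, 25, 26, 30, 32,
33, 34}; the rest value. Both maps are registry data, not code.

Messages are condensed to one per (id, section, subsection-or-column)
with an occurrence count, and worded for the source format (rows vs
entries, columns vs keys). `validate` never raises on a parsable
document: each check group runs behind a guard that converts an internal
failure into a reported message — and the fuzzing test additionally
asserts that guard never actually fires.

### Numerical choices

* **Near-constant columns (28):** a column fires when, among its
  *non-empty* cells, the modal value's share is ≥ 0.90 and < 1.0, with
  at least 10 non-empty cells. The 90% threshold is the check's defining
  constant; the non-empty basis keeps it orthogonal to the all-null
  check (27), the strict `< 1` keeps constant columns (often legitimate
  metadata) silent, and the 10-cell floor stops one odd value in a
  three-row table from firing.
* **Paired columns (18):** a mismatch is a row with a non-empty value in
  one partner and an empty value in the other; the message is emitted
  once per pair (from the lexicographically smaller canonical) to avoid
  double reporting.
* **Polarity (31):** fires on more than one distinct non-empty value;
  case differences are distinct values (no semantic equivalence).

## Column matching

Matching is rule-per-finder, not global edit distance: each of the 56
canonical names owns an ordered list of full-match regular expressions
applied to the *normalized* name (lowercased; runs of spaces,
underscores and hyphens collapsed to one space), an optional value
rule, implied partners and deliberate-overlap declarations. Fuzziness
therefore lives inside each finder where it can be tuned name by name;
ties across finders are never resolved silently — they are exactly what
the multiple-match check (20) reports. Exact canonical spellings match
but are not rename candidates. The canonical set beyond the handful of
documented names (moverz_quant, retention_time, retention_index(_type),
other_id(_type), kegg_id, lab_id, polarity, sample_id) is drawn from
common METABOLITES metadata (identifier columns, masses, adducts,
MS/MS descriptors, QC columns); the registry is provisional,
human-editable JSON, and its self-consistency (every canonical matches
itself and no other finder except declared overlaps; partner symmetry)
is enforced by tests. Value rules are case-sensitive except where the
domain tolerates case (polarity, MS level, eV units), and syntactic
only — no ontology or online identifier resolution.

## Consistency comparison

Differences are tagged with six categories: section present in one
document only (SectionKeys — the empty-`#FACTORS` case lands here by
design), subsection in one only (SubsectionKeys), same subsection with
different values (SubsectionValues), different value *shape* — repeated
key vs single, or null vs string (SubsectionType), and any difference
inside subject-sample-factor records (SSF) or table composites (DATA).
Header attributes are compared as a pseudo-section. The comparator is
symmetric in categories and counts, and conversion correctness is
defined through it: converting a file and comparing the two parses must
yield zero differences.

## The synthetic generator

The generator emulates a small, clean deposition: four samples over a
two-level `Treatment` factor, twelve metabolites (enough non-empty
cells for the near-constant check to be in play), MS or NMR mode, an
optional EXTENDED table, accessions matching their patterns, all
required metadata filled, METABOLITES columns spelled canonically with
rule-valid values, and mutually consistent SSF/DATA/METABOLITES
sections. Intensities are uniform random positives — no statistical
realism is attempted, since no check depends on the distribution of
values, only on their text-level structure. Identical specs yield
byte-identical files.

What the generator deliberately does *not* emulate: real depositor
prose, heterogeneous column vocabularies, multi-factor designs, very
large tables, and encoding damage. Passing tests therefore demonstrate
the machinery (parse/validate/convert/compare round trips and defect
detection), not field performance on arbitrary repository files.

The defect injector is the generator's inverse eye: for each validation
id it produces a file that still parses but fails that id (implied
co-firings are expected — duplicating a metabolite name also perturbs a
set comparison), and for each parse-failure class a file whose read
raises the designated error. Defects unrepresentable in a well-formed
model (1, 2, 3, 8, 30 and all parse defects) are injected by text
surgery on the serialized file; the rest mutate the model and
re-serialize.

## Testing scale

The default suite runs the defect matrix over all 66 (id, format)
pairs, validates 100 seeded clean fixtures in both formats, round-trips
100 fixtures through all four one-step chains, compares 100 converted
pairs, and fuzzes until 1000 parsable mutants have been validated —
about ten seconds end to end. These sizes were chosen as comfortable
desk-scale analogues of the repository-wide evaluation the package is
meant for; repository-scale counts depend on a dated snapshot of the
live archive and are out of scope.

## Known limitations

* The structural schema transcribes the headline required fields, not
  the full specification (which is not available in machine-readable
  form, nor in historical versions); the rule table is the extension
  point.
* The 56-name registry and its patterns are tuned against common usage,
  not against the live repository's full column vocabulary; expect
  false negatives on exotic spellings.
* Pathological files whose stray lines swallow neighbouring content
  (the `#FACTORS`-before-results-file case) parse into annotated
  documents; repairing them is explicitly out of scope.
* The JSON dialect follows the repository's nested layout; top-level
  scalar header attributes are read but always re-written nested.
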