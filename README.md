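# mwcheck

Quality control for **Metabolomics Workbench analysis files**: a Python
library and CLI that parses, validates, converts and cross-checks
depositions in the mwTab flat-text format and its JSON twin.

The Metabolomics Workbench serves each analysis in two text formats: the
tab-delimited mwTab format (`#SECTION` headers, `CODE:KEY<TAB>VALUE`
item lines, fenced data tables) and a JSON rendering of the same
content. Real depositions violate both formats in recurring ways —
repeated keys and columns, ragged table rows, stray `#FACTORS` lines,
ambiguous `SUBJECT_SAMPLE_FACTORS` syntax, `false` where a table row
should be — and the two renderings of one analysis frequently disagree.
`mwcheck` is built for curators and meta-analysts who need to know, file
by file, exactly what is wrong and whether the two renderings carry the
same data.

## What it does

* **Duplicate-key-preserving parsing.** All key/value content lives in
  an ordered container that retains repeated keys, so a table with two
  `S1` columns or a JSON row with two `Sample1` members loses nothing.
  Ambiguous content (an extra `=` or `:` in a subject-sample-factor
  line) is *refused* with a precise error rather than guessed at.
* **A 36-check categorized validation suite** plus declarative
  structural schema rules. Each finding carries a numeric id, short
  name, severity (warning/error) and category tags — `format` (violates
  the specification), `value` (a value is wrong), `consistency` (two
  places that must agree do not) — and files are classified Passing /
  Warnings Only / Errors.
* **Standard-column-name harmonization.** A registry of 56 canonical
  METABOLITES column names (`moverz_quant`, `retention_time`,
  `kegg_id`, ...) with per-name fuzzy matching rules, per-column value
  validators and implied-partner links (`retention_index` implies
  `retention_index_type`).
* **Lossless conversion** between the two formats, with round-trip
  verification, and a **consistency comparator** that tags every
  cross-format difference with one of six categories (DATA, SSF,
  SectionKeys, SubsectionKeys, SubsectionValues, SubsectionType).
* **A synthetic generator** of valid analyses and a defect injector
  keyed by validation id, so the whole suite is testable without
  touching the live repository.

## Worked example

```sh
$ mwcheck generate --seed 5 --output demo.txt
$ mwcheck validate demo.txt
demo.txt: Passing

$ mwcheck generate --seed 5 --defect 17 --output bad.txt
$ mwcheck validate bad.txt
bad.txt: Warnings Only (1 message(s))
  [17] warning Missing Implied Column: column 'retention_index' (retention_index) should be paired with a 'retention_index_type' column, which is not present

$ mwcheck convert demo.txt --to json --output-dir out
demo.txt -> out/demo.json
$ mwcheck compare demo.txt out/demo.json
{
  "consistent": true,
  "summary": {},
  "differences": []
}
```

The first file passes every check (exit code 0). The second carries an
injected defect — a `retention_index` column without its implied
`retention_index_type` partner — and validation reports check id 17 as a
warning (exit code 1). Converting the clean file to JSON and comparing
the two parses finds zero differences: the conversion is lossless.

The same operations are available as a library:

```python
from mwcheck import read_document, validate, categorize, compare_documents

doc = read_document("demo.txt")
messages = validate(doc)          # list of ValidationMessage records
print(categorize(messages).status)  # "Passing"
```

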