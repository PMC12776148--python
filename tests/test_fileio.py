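"""Reading/writing both formats, duplicate-key handling, batch recovery."""

import json

import pytest

from mwcheck.errors import (
    NonRecordRowError,
    ParseError,
    TopLevelDuplicateKeyError,
)
from mwcheck.fileio import (
    process_batch,
    read_document,
    read_json,
    read_mwtab,
    write_json,
    write_mwtab,
)
from mwcheck.model import DuplicatePreservingMap
from mwcheck.synthetic import FixtureSpec, generate_valid


class TestReadMwtab:
    def test_clean_fixture_equals_model(self, ms_fixture):
        doc, tab, _ = ms_fixture
        parsed = read_mwtab(tab)
        assert parsed == doc
        assert parsed.source_format == "mwtab"
        assert parsed.annotations.is_clean

    def test_duplicated_sample_column_both_retained(self, ms_fixture):
        _, tab, _ = ms_fixture
        lines = tab.splitlines()
        start = lines.index("MS_METABOLITE_DATA_START")
        end = lines.index("MS_METABOLITE_DATA_END")
        for i in range(start + 1, end):
            lines[i] = lines[i] + "\t" + lines[i].split("\t")[1]
        doc = read_mwtab("\n".join(lines))
        table = doc.sections["MS_METABOLITE_DATA"].body
        assert table.columns.count("S001") == 2
        assert len(doc.sections["MS_METABOLITE_DATA"].body.rows[0].get("S001")) == 2
        assert ("MS_METABOLITE_DATA", "S001") in \
            doc.annotations.duplicate_sample_columns

    def test_ssf_extra_equals_is_refused(self, ms_fixture):
        _, tab, _ = ms_fixture
        bad = tab.replace("RAW_FILE=", "RAW_FILE==", 1)
        with pytest.raises(ParseError):
            read_mwtab(bad)


class TestReadJson:
    def test_duplicate_row_keys_below_top_level_preserved(self, ms_fixture):
        doc, _, _ = ms_fixture
        import copy
        doc = copy.deepcopy(doc)
        table = doc.sections["MS_METABOLITE_DATA"].body
        table.rows[0].append("S001", "42.0")
        text = write_json(doc)
        back = read_json(text)
        row = back.sections["MS_METABOLITE_DATA"].body.rows[0]
        original = doc.sections["MS_METABOLITE_DATA"].body.rows[0]
        assert row.get("S001") == [original.get("S001")[0], "42.0"]

    def test_top_level_duplicate_key_is_refused(self, ms_fixture):
        _, _, js = ms_fixture
        brace = js.index("{")
        bad = js[:brace + 1] + '"PROJECT": {},' + js[brace + 1:]
        with pytest.raises(TopLevelDuplicateKeyError):
            read_json(bad)

    def test_false_row_refused_without_force_skipped_with(self, ms_fixture):
        _, _, js = ms_fixture
        # surgically turn the first data row object into a bare false
        data = json.loads(js)
        n_rows = len(data["MS_METABOLITE_DATA"]["Data"])
        start = js.index('"Data": [')
        open_brace = js.index("{", start)
        depth, i = 0, open_brace
        while True:
            depth += {"{": 1, "}": -1}.get(js[i], 0)
            if depth == 0:
                break
            i += 1
        bad = js[:open_brace] + "false" + js[i + 1:]
        with pytest.raises(NonRecordRowError):
            read_json(bad)
        doc = read_json(bad, force=True)
        assert len(doc.sections["MS_METABOLITE_DATA"].body.rows) == n_rows - 1
        assert doc.annotations.forced_row_skips


class TestWriters:
    def test_mwtab_round_trip(self, ms_fixture):
        doc, _, _ = ms_fixture
        assert read_mwtab(write_mwtab(doc)) == doc

    def test_json_round_trip(self, nm_fixture):
        doc, _, _ = nm_fixture
        assert read_json(write_json(doc)) == doc

    def test_writes_are_byte_deterministic(self, ms_fixture):
        doc, tab, js = ms_fixture
        assert write_mwtab(doc) == tab
        assert write_json(doc) == js
        # fixed point after one more cycle
        assert write_json(read_json(js)) == js
        assert write_mwtab(read_mwtab(tab)) == tab

    def test_non_ascii_values_round_trip(self, ms_fixture):
        import copy
        doc = copy.deepcopy(ms_fixture[0])
        doc.sections["COLLECTION"].body.items.replace(
            "COLLECTION_SUMMARY", "plasma at 4 °C, centrifugé à 3000×g")
        assert read_mwtab(write_mwtab(doc)) == doc
        assert read_json(write_json(doc)) == doc

    def test_missing_output_directories_created(self, tmp_path, ms_fixture):
        doc, _, _ = ms_fixture
        target = tmp_path / "a" / "b" / "out.txt"
        write_mwtab(doc, target)
        assert read_mwtab(target) == doc


class TestProcessBatch:
    def test_failures_do_not_abort_batch(self, tmp_path, ms_fixture):
        _, tab, _ = ms_fixture
        good1 = tmp_path / "one.txt"
        good1.write_text(tab, encoding="utf-8")
        bad = tmp_path / "two.txt"
        bad.write_text(tab.replace("RAW_FILE=", "RAW_FILE==", 1),
                       encoding="utf-8")
        good2 = tmp_path / "three.txt"
        good2.write_text(tab, encoding="utf-8")
        result = process_batch([good1, bad, good2], read_document)
        assert len(result) == 3
        assert [r.outcome for r in result] == ["ok", "parse_error", "ok"]

    def test_empty_inputs_give_empty_result(self):
        assert len(process_batch([], read_document)) == 0

    def test_nested_output_dir_created(self, tmp_path):
        out = tmp_path / "deep" / "nested" / "dir"
        process_batch([], read_document, output_dir=out)
        assert out.is_dir()


def test_four_way_round_trip_property():
    """Every generated fixture survives all four read/write cycles."""
    from mwcheck.converter import roundtrip_check

    for seed in range(5):
        doc, _, _ = generate_valid(FixtureSpec(
            seed=seed, analytical_mode="NM" if seed % 2 else "MS",
            include_extended=bool(seed % 3)))
        for chain in (["mwtab"], ["json"], ["mwtab", "json"],
                      ["json", "mwtab"]):
            report = roundtrip_check(doc, chain)
            assert report.lossless, (seed, chain, report.error)
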