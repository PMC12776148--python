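"""Lexing, repairs and refusals on mwTab flat text."""

import pytest
from hypothesis import given, settings, strategies as st

from mwcheck.errors import (
    MissingTabError,
    MultipleDataEndError,
    OrphanLineError,
    SSFAdditionalDataError,
    SSFFactorError,
)
from mwcheck.tokenizer import (
    classify_line,
    harmonize_row,
    parse_ssf_line,
    tokenize,
)


class TestClassifyLine:
    def test_section_header(self):
        token = classify_line("#PROJECT", 1)
        assert token.kind == "SectionHeader"
        assert token.payload["name"] == "PROJECT"

    def test_item_line(self):
        token = classify_line("PR:PROJECT_TITLE\tA title", 4)
        assert token.kind == "Item"
        assert token.payload == {"code": "PR", "key": "PROJECT_TITLE",
                                 "value": "A title"}

    def test_missing_tab_after_section_code(self):
        with pytest.raises(MissingTabError) as err:
            classify_line("CO:COLLECTION_SUMMARY no tab here", 9)
        assert err.value.line_no == 9

    def test_orphan_line_from_embedded_carriage_return(self):
        with pytest.raises(OrphanLineError):
            classify_line("rest of a value pushed onto its own line", 12)

    def test_workbench_header_attributes(self):
        token = classify_line(
            "#METABOLOMICS WORKBENCH STUDY_ID:ST000001 PROJECT_ID:", 1)
        assert dict(token.payload["attrs"]) == {"STUDY_ID": "ST000001",
                                                "PROJECT_ID": ""}


class TestParseSSFLine:
    def test_well_formed(self):
        rec = parse_ssf_line(["SUBJECT_SAMPLE_FACTORS", "SU1", "S1",
                              "Treatment:Control | Time:4h",
                              "RAW=a.raw; batch=1"])
        assert rec.sample_id == "S1"
        assert rec.factors == {"Treatment": "Control", "Time": "4h"}
        assert rec.additional_data == {"RAW": "a.raw", "batch": "1"}

    def test_extra_colon_in_factor_is_refused(self):
        with pytest.raises(SSFFactorError):
            parse_ssf_line(["SUBJECT_SAMPLE_FACTORS", "", "S1",
                            "Dose:5:mg", ""])

    @pytest.mark.parametrize("additional", [
        "RAW=a.raw batch=1",      # missing semicolon between pairs
        "RAW=a=raw; batch=1",     # extra equals inside a pair
    ])
    def test_ambiguous_additional_data_is_refused(self, additional):
        with pytest.raises(SSFAdditionalDataError):
            parse_ssf_line(["SUBJECT_SAMPLE_FACTORS", "", "S1",
                            "Treatment:Control", additional])

    def test_round_trip_of_unmodified_record(self):
        rec = parse_ssf_line(["SUBJECT_SAMPLE_FACTORS", "SU1", "S1",
                              "Treatment:Control", "RAW=a.raw"])
        assert rec.factors_string() == "Treatment:Control"
        assert rec.additional_string() == "RAW=a.raw"


class TestHarmonizeRow:
    HEADER = ["Metabolite", "S1", "S2"]

    def test_trailing_empty_overflow_dropped(self):
        assert harmonize_row(self.HEADER, ["m1", "1", "2", "", ""]) == \
            ["m1", "1", "2"]

    def test_short_row_padded(self):
        assert harmonize_row(self.HEADER, ["m1", "1"]) == ["m1", "1", ""]

    def test_exact_row_unchanged(self):
        assert harmonize_row(self.HEADER, ["m1", "1", "2"]) == \
            ["m1", "1", "2"]

    def test_nonempty_overflow_recorded(self):
        from mwcheck.model import ParseAnnotations
        ann = ParseAnnotations()
        out = harmonize_row(self.HEADER, ["m1", "1", "2", "x"], ann,
                            "MS_METABOLITE_DATA", 5)
        assert out == ["m1", "1", "2"]
        assert ann.header_mismatches == [("MS_METABOLITE_DATA", 5, 4, 3)]

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.text(alphabet="ab ", max_size=3), max_size=8),
           st.lists(st.text(alphabet="ab ", max_size=3), max_size=12))
    def test_idempotent(self, header, cells):
        once = harmonize_row(header, cells)
        assert harmonize_row(header, once) == once
        assert len(once) == len(header)


class TestTokenize:
    def test_clean_fixture_has_empty_annotations(self, ms_fixture):
        _, tab, _ = ms_fixture
        tokens, annotations = tokenize(tab)
        assert annotations.is_clean
        assert tokens[0].kind == "SectionHeader"

    def test_factors_pseudo_section_is_flagged_not_dropped(self, ms_fixture):
        _, tab, _ = ms_fixture
        tab = tab.replace("#COLLECTION", "#FACTORS\n#COLLECTION", 1)
        _, annotations = tokenize(tab)
        assert len(annotations.bogus_section_lines) == 1

    def test_second_data_end_between_rows_is_refused(self, ms_fixture):
        _, tab, _ = ms_fixture
        lines = tab.splitlines()
        i = lines.index("MS_METABOLITE_DATA_END") - 2
        lines.insert(i, "MS_METABOLITE_DATA_END")
        with pytest.raises(MultipleDataEndError):
            tokenize("\n".join(lines))

    def test_parse_errors_carry_line_numbers(self, ms_fixture):
        _, tab, _ = ms_fixture
        lines = tab.splitlines()
        idx = next(i for i, s in enumerate(lines)
                   if s.startswith("AN:ANALYSIS_TYPE"))
        lines[idx] = lines[idx].replace("\t", " ")
        with pytest.raises(MissingTabError) as err:
            tokenize("\n".join(lines))
        assert err.value.line_no == idx + 1

    def test_duplicate_subsection_recorded(self, ms_fixture):
        _, tab, _ = ms_fixture
        line = next(s for s in tab.splitlines()
                    if s.startswith("CO:COLLECTION_SUMMARY"))
        tab = tab.replace(line, line + "\n" + line, 1)
        _, annotations = tokenize(tab)
        assert ("COLLECTION", "COLLECTION_SUMMARY") in \
            annotations.duplicate_subsections
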