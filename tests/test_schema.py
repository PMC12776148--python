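"""Structural (schema) validation: required subsections and value spaces."""

import random
import re

import copy
import pytest

from mwcheck.mwschema import (
    CHROMATOGRAPHY_REQUIRED,
    default_rules,
    dump_rules,
    id_pattern,
    load_rules,
    validate_structure,
)


class TestIdPattern:
    def test_analysis_pattern_accepts_real_accession(self):
        assert re.fullmatch(id_pattern("analysis"), "AN002312")

    def test_study_pattern_rejects_analysis_accession(self):
        assert not re.fullmatch(id_pattern("study"), "AN002312")

    def test_project_pattern_brute_force_oracle(self):
        # independent oracle: a project accession is exactly "PR" plus
        # six digits; compare verdicts on sampled candidates
        rng = random.Random(0)
        pattern = re.compile(id_pattern("project"))
        candidates = [f"PR{rng.randrange(10 ** 6):06d}" for _ in range(300)]
        candidates += ["PR12345", "PR1234567", "ST000001", "pr000001",
                       "PR00000a", ""]
        for c in candidates:
            oracle = (len(c) == 8 and c[:2] == "PR" and c[2:].isdigit())
            assert bool(pattern.fullmatch(c)) == oracle, c

    def test_unknown_kind_errors(self):
        with pytest.raises(ValueError):
            id_pattern("sample")


class TestValidateStructure:
    def test_valid_fixture_produces_no_messages(self, ms_fixture, nm_fixture):
        assert validate_structure(ms_fixture[0]) == []
        assert validate_structure(nm_fixture[0]) == []

    def test_missing_subject_type(self, ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        doc.sections["SUBJECT"].body.items.remove("SUBJECT_TYPE")
        messages = validate_structure(doc)
        assert any(m.section == "SUBJECT" and m.subsection == "SUBJECT_TYPE"
                   and m.id == 24 and "format" in m.categories
                   for m in messages)

    def test_blank_and_absent_required_values_are_worded_apart(self,
                                                               ms_fixture):
        blank = copy.deepcopy(ms_fixture[0])
        blank.sections["SUBJECT"].body.items.replace("SUBJECT_TYPE", "")
        absent = copy.deepcopy(ms_fixture[0])
        absent.sections["SUBJECT"].body.items.remove("SUBJECT_TYPE")
        m_blank = next(m for m in validate_structure(blank)
                       if m.subsection == "SUBJECT_TYPE")
        m_absent = next(m for m in validate_structure(absent)
                        if m.subsection == "SUBJECT_TYPE")
        assert m_blank.message != m_absent.message

    def test_value_space_violation_is_dual_tagged(self, ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        doc.sections["MS"].body.items.append("CAPILLARY_VOLTAGE", "5 W")
        messages = validate_structure(doc)
        bad = [m for m in messages if m.subsection == "CAPILLARY_VOLTAGE"]
        assert bad and bad[0].categories == {"format", "value"}

    def test_five_chromatography_attributes_required_for_ms(self,
                                                            ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        for attr in CHROMATOGRAPHY_REQUIRED:
            doc.sections["CHROMATOGRAPHY"].body.items.remove(attr)
        messages = validate_structure(doc)
        flagged = {m.subsection for m in messages
                   if m.section == "CHROMATOGRAPHY"}
        assert flagged == set(CHROMATOGRAPHY_REQUIRED)

    def test_chromatography_not_required_without_ms(self, nm_fixture):
        assert not any(m.section == "CHROMATOGRAPHY"
                       for m in validate_structure(nm_fixture[0]))

    def test_bad_accession_is_flagged(self, ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        doc.header.replace("STUDY_ID", "STUDY1")
        messages = validate_structure(doc)
        assert any(m.subsection == "STUDY_ID" for m in messages)


def test_rule_table_round_trips_through_config_file(tmp_path):
    rules = default_rules()
    path = tmp_path / "rules.json"
    dump_rules(rules, path)
    loaded = load_rules(path)
    assert loaded == rules
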