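"""The 36-check suite: registry, per-group behavior, statuses."""

import copy

import pytest

from mwcheck.fileio import read_document, read_json, read_mwtab, write_json
from mwcheck.model import DuplicatePreservingMap
from mwcheck.synthetic import FixtureSpec, generate_valid, inject_defect
from mwcheck.validator import (
    CHECK_REGISTRY,
    NEAR_CONSTANT_THRESHOLD,
    categorize,
    validate,
)


def _ids(doc):
    return {m.id for m in validate(doc)}


class TestRegistry:
    def test_ids_one_to_thirty_six_each_present_once(self):
        assert sorted(CHECK_REGISTRY) == list(range(1, 37))

    def test_format_restricted_checks(self):
        for i in (1, 2, 3, 8, 30):
            assert CHECK_REGISTRY[i].applicability == {"mwtab"}
        assert CHECK_REGISTRY[25].applicability == {"json"}
        assert CHECK_REGISTRY[9].applicability == {"mwtab", "json"}

    def test_rename_suggestion_is_always_a_warning(self):
        assert CHECK_REGISTRY[15].severity == "warning"

    def test_every_check_has_nonempty_categories(self):
        assert all(spec.categories for spec in CHECK_REGISTRY.values())


class TestValidate:
    def test_clean_fixtures_pass(self, ms_fixture, nm_fixture, ext_fixture):
        for doc, tab, js in (ms_fixture, nm_fixture, ext_fixture):
            assert validate(read_mwtab(tab)) == []
            assert validate(read_json(js)) == []

    def test_metabolite_only_in_metabolites_fires_consistency(self,
                                                              ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        met = doc.sections["METABOLITES"].body
        met.rows.append(DuplicatePreservingMap(
            zip(met.columns, ["ghostol", "100.1", "1.0", "C11111",
                              "C2H6O"])))
        messages = [m for m in validate(doc) if m.id == 12]
        assert len(messages) == 1
        assert "consistency" in messages[0].categories

    def test_determinism_across_calls(self, ms_fixture):
        doc = read_mwtab(inject_defect(FixtureSpec(seed=9), 9, "mwtab"))
        assert validate(doc) == validate(doc)

    def test_messages_are_condensed_with_counts(self, ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        data = doc.sections["MS_METABOLITE_DATA"].body
        # three rows with blank names -> one message carrying the count
        for i in range(3):
            data.rows[i].replace("Metabolite", "")
        msgs = [m for m in validate(doc) if m.id == 10]
        assert len(msgs) == 1 and msgs[0].count == 3


class TestSubjectSampleFactors:
    def test_duplicate_sample_id(self, ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        records = doc.ssf_records()
        records.append(copy.deepcopy(records[0]))
        assert 4 in _ids(doc)

    def test_data_sample_missing_from_ssf(self, ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        data = doc.sections["MS_METABOLITE_DATA"].body
        data.columns.append("S9")
        for row in data.rows:
            row.append("S9", "1.0")
        assert 7 in _ids(doc)

    def test_clean_ssf_silent(self, ms_fixture):
        assert not {4, 5, 6, 7} & _ids(ms_fixture[0])


class TestGenericTables:
    def _met(self, doc):
        return doc.sections["METABOLITES"].body

    def test_near_constant_column_fires_at_threshold_only(self):
        def share_ids(k_same, n=10):
            doc, _, _ = generate_valid(FixtureSpec(seed=5, n_metabolites=n))
            met = self._met(doc)
            for i, row in enumerate(met.rows):
                row.replace("formula",
                            "C6H12O6" if i < k_same else f"C{i}H{i + 2}O2")
            return {m.id for m in validate(doc)}

        assert NEAR_CONSTANT_THRESHOLD == pytest.approx(0.9)
        assert 28 not in share_ids(8)    # 80% modal share
        assert 28 in share_ids(9)        # 90% modal share
        assert 28 not in share_ids(10)   # constant column

    def test_all_null_column_is_27_not_28(self, ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        met = self._met(doc)
        met.columns.append("comments")
        for row in met.rows:
            row.append("comments", "")
        ids = _ids(doc)
        assert 27 in ids and 28 not in ids

    def test_all_distinct_column_fires_neither(self, ms_fixture):
        ids = _ids(ms_fixture[0])
        assert not {27, 28} & ids

    def test_duplicate_rows(self, ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        data = doc.sections["MS_METABOLITE_DATA"].body
        data.rows.append(copy.deepcopy(data.rows[0]))
        assert 29 in _ids(doc)


class TestStandardColumns:
    def test_rename_candidate_warns(self, ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        met = doc.sections["METABOLITES"].body
        met.columns[met.columns.index("moverz_quant")] = "m/z"
        for row in met.rows:
            row.rename("moverz_quant", "m/z")
        msgs = [m for m in validate(doc) if m.id == 15]
        assert msgs and msgs[0].severity == "warning"
        assert "moverz_quant" in msgs[0].message

    def test_missing_implied_partner(self, ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        met = doc.sections["METABOLITES"].body
        met.columns.append("retention_index")
        for i, row in enumerate(met.rows):
            row.append("retention_index", f"{1200 + i}")
        assert 17 in _ids(doc)

    def test_mixed_polarity_column(self, ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        met = doc.sections["METABOLITES"].body
        met.columns.append("polarity")
        for i, row in enumerate(met.rows):
            row.append("polarity", "negative" if i == 0 else "positive")
        assert 31 in _ids(doc)


class TestFactorMatch:
    def test_mismatch_fires_for_mwtab_only(self, ms_fixture):
        doc = copy.deepcopy(ms_fixture[0])
        sample = doc.ssf_records()[0].sample_id
        data = doc.sections["MS_METABOLITE_DATA"].body
        data.factors_row[sample] = "Treatment:SomethingElse"
        assert 3 in _ids(doc)
        # the same content seen through the JSON twin skips the check
        json_doc = read_json(write_json(doc))
        assert 3 not in _ids(json_doc)

    def test_identical_factors_silent(self, ms_fixture):
        assert 3 not in _ids(ms_fixture[0])


class TestCategorize:
    def test_no_messages_is_passing(self):
        assert categorize([]).status == "Passing"

    def test_only_warnings_is_warnings_only(self, ms_fixture):
        doc = read_mwtab(inject_defect(FixtureSpec(seed=4), 17, "mwtab"))
        messages = validate(doc)
        assert messages and all(m.severity == "warning" for m in messages)
        assert categorize(messages).status == "Warnings Only"

    def test_schema_error_flags_format(self, ms_fixture):
        doc = read_mwtab(inject_defect(FixtureSpec(seed=4), 24, "mwtab"))
        record = categorize(validate(doc))
        assert record.status == "Errors"
        assert record.has_format_errors
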