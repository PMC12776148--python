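"""Standard-column-name matching, value rules and registry invariants."""

import random
import re

import pytest

from mwcheck.columns import (
    default_registry,
    find_standard_columns,
    match_column_name,
    normalize_column_name,
    validate_column_values,
)


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [
        ("Ret Time", "ret time"),
        ("retention_time", "retention time"),
        ("retention time", "retention time"),
        ("  m/z  ", "m/z"),
        ("KEGG__ID", "kegg id"),
        ("", ""),
    ])
    def test_normalization(self, raw, expected):
        assert normalize_column_name(raw) == expected

    def test_separator_variants_collapse_to_same_form(self):
        forms = {"ret time", "ret_time", "ret-time", "ret  time"}
        assert len({normalize_column_name(f) for f in forms}) == 1


class TestMatching:
    @pytest.mark.parametrize("raw,expected", [
        ("ret_time", {"retention_time"}),
        ("m/z", {"moverz_quant"}),
        ("moverz", {"moverz_quant"}),
        ("zzz_unrelated", set()),
    ])
    def test_match_column_name(self, raw, expected):
        assert match_column_name(raw) == expected

    def test_find_standard_columns_rename_candidates(self):
        outcomes = find_standard_columns(["Metabolite", "mz",
                                          "retention time"])
        candidates = [o for o in outcomes if o.is_rename_candidate]
        assert len(candidates) == 2

    def test_all_canonical_header_has_no_candidates(self):
        header = ["moverz_quant", "retention_time", "kegg_id"]
        assert not any(o.is_rename_candidate
                       for o in find_standard_columns(header))

    def test_multi_match_is_flagged(self):
        outcomes = find_standard_columns(["mass"])
        assert len(outcomes[0].matches) > 1


class TestValueValidation:
    def test_kegg_id_values(self):
        assert validate_column_values("kegg_id", ["C00031", "banana"]) == [1]

    def test_empty_values_are_never_bad(self):
        assert validate_column_values("kegg_id", ["", "", None]) == []

    def test_rule_free_canonical_rejects_nothing(self):
        assert validate_column_values("adduct", ["[M+H]+", "???"]) == []

    def test_dual_implementation_oracle_on_random_strings(self):
        # independent re-implementation of the KEGG accession shape
        def oracle(s: str) -> bool:
            s = s.strip()
            return (len(s) == 6 and s[0] in "CDGRM" and s[1:].isdigit())

        rng = random.Random(42)
        alphabet = "CDGRMX0123456789ab "
        candidates = ["".join(rng.choice(alphabet)
                              for _ in range(rng.randrange(1, 9)))
                      for _ in range(200)]
        candidates += ["C00031", "D12345", "M99999", "c00031", "C0003"]
        verdicts = validate_column_values("kegg_id", candidates)
        expected = [i for i, c in enumerate(candidates)
                    if c.strip() and not oracle(c)]
        assert verdicts == expected


class TestRegistryInvariants:
    def test_exactly_56_prebuilt_finders(self):
        assert len(default_registry()) == 56

    def test_every_canonical_matches_itself_and_only_itself(self):
        registry = default_registry()
        for finder in registry:
            matches = match_column_name(finder.canonical_name, registry)
            assert finder.canonical_name in matches, finder.canonical_name
            allowed = {finder.canonical_name} | set(finder.exclusive_with)
            assert matches <= allowed, (finder.canonical_name, matches)

    def test_value_rules_self_test(self):
        # every value rule accepts at least one plausible example and
        # rejects at least one counterexample
        examples = {
            "moverz_quant": ("181.0712", "n/a"),
            "retention_time": ("5.93", "fast"),
            "retention_index": ("1200", "high"),
            "kegg_id": ("C00031", "banana"),
            "hmdb_id": ("HMDB0000122", "HX1"),
            "pubchem_cid": ("5793", "cid:5793"),
            "pubchem_sid": ("347911", "sid?"),
            "inchi_key": ("WQZGKKKJIJFFOK-GASJEMHNSA-N", "not-a-key"),
            "inchi": ("InChI=1S/C6H12O6/c7-1-2", "smiles"),
            "cas_id": ("50-99-7", "cas"),
            "chebi_id": ("CHEBI:17234", "chebi what"),
            "metlin_id": ("3581", "m-3581"),
            "lipidmaps_id": ("LMFA01010001", "LM1"),
            "chemspider_id": ("5589", "cs!"),
            "formula": ("C6H12O6", "sugar"),
            "exact_mass": ("180.0634", "heavy"),
            "neutral_mass": ("180.0634", "light"),
            "average_mass": ("180.16", "avg"),
            "theoretical_mz": ("181.0707", "?"),
            "mass_error_ppm": ("-2.3", "low"),
            "adduct_mz": ("181.07", "x"),
            "charge": ("+1", "one"),
            "polarity": ("positive", "mixed"),
            "ms_level": ("MS2", "deep"),
            "collision_energy": ("35 eV", "gentle"),
            "precursor_mz": ("181.07", "big"),
            "product_mz": ("85.02", "small"),
            "peak_area": ("1.2e6", "wide"),
            "peak_height": ("35000", "tall"),
            "signal_to_noise": ("12.5", "noisy"),
            "annotation_level": ("1", "great"),
            "confidence_score": ("98.2%", "sure"),
            "standard_concentration": ("10.0", "lots"),
        }
        registry = default_registry()
        for finder in registry:
            if finder.value_rule is None:
                continue
            good, bad = examples[finder.canonical_name]
            assert finder.accepts_value(good), finder.canonical_name
            assert not finder.accepts_value(bad), finder.canonical_name

    def test_implied_partner_symmetry(self):
        registry = default_registry()
        assert "retention_index_type" in \
            registry["retention_index"].implied_partners
        assert "retention_index" in \
            registry["retention_index_type"].implied_partners
        for finder in registry:
            for partner in finder.implied_partners:
                assert finder.canonical_name in \
                    registry[partner].implied_partners
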