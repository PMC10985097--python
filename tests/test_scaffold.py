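"""Cysteine scaffold canonicalization, categories, templates, census."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import venomscaffold as vs
from venomscaffold.scaffold import (NO_SCAFFOLD, load_templates,
                                    relaxed_pattern, roman,
                                    spacers_from_positions)


def naive_pattern(seq):
    """Independent spacer-walk canonicalizer used as the oracle."""
    pos = [i for i, ch in enumerate(seq) if ch == "C"]
    if not pos:
        return NO_SCAFFOLD
    out = "C"
    for a, b in zip(pos, pos[1:]):
        s = b - a - 1
        if s == 0:
            out += "C"
        elif s == 1:
            out += "XC"
        elif s <= 3:
            out += f"X{s}C"
        else:
            out += "-C"
    return out


class TestPositions:
    @pytest.mark.parametrize("seq,pos", [("ACDC", [2, 4]), ("KKKK", []),
                                         ("C", [1])])
    def test_examples(self, seq, pos):
        assert vs.cys_positions(seq) == pos

    @given(st.text(alphabet="ACDEFGX", min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_agrees_with_scan(self, seq):
        assert vs.cys_positions(seq) == \
            [i + 1 for i, ch in enumerate(seq) if ch == "C"]


class TestCanonicalPattern:
    @pytest.mark.parametrize("spacers,pattern", [
        ([5, 4, 6, 3, 2], "C-C-C-CX3CX2C"),     # ShKT scaffold
        ([1, 13, 9, 6, 0], "CXC-C-C-CC"),       # beta-defensin scaffold
        ([8, 15, 7, 12, 3], "C-C-C-C-CX3C"),    # Kunitz scaffold
        ([], "C"),
        ([0], "CC"),
        ([2], "CX2C"),
    ])
    def test_spacer_examples(self, spacers, pattern):
        assert vs.canonical_pattern(spacers) == pattern

    def test_sequence_form_matches_spacer_form(self):
        seq = "CAAAAACAAAACAAAAAACAAACAAC"
        assert vs.canonical_pattern(seq) == "C-C-C-CX3CX2C"

    def test_no_cysteines_gives_marker_not_error(self):
        assert vs.canonical_pattern("KKKK") == NO_SCAFFOLD

    def test_oracle_equivalence_10000_random_sequences(self):
        rnd = random.Random(99)
        for _ in range(10_000):
            seq = "".join(rnd.choices("CADEX", weights=[2, 4, 4, 4, 1],
                                      k=rnd.randint(1, 80)))
            assert vs.canonical_pattern(seq) == naive_pattern(seq)

    @given(st.lists(st.integers(0, 20), max_size=12))
    @settings(deadline=None, derandomize=True)
    def test_pure_function_of_spacers(self, spacers):
        """Shuffling non-Cys residue identities never changes the pattern."""
        seq_a = "C" + "".join("A" * s + "C" for s in spacers)
        seq_b = "C" + "".join("XDEX"[:1] * 0 + "D" * s + "C" for s in spacers)
        assert vs.canonical_pattern(seq_a) == vs.canonical_pattern(seq_b)
        assert vs.canonical_pattern(seq_a) == vs.canonical_pattern(spacers)

    @given(st.lists(st.integers(0, 20), max_size=12))
    @settings(deadline=None, derandomize=True)
    def test_parse_then_canonicalize_idempotent(self, spacers):
        pattern = vs.canonical_pattern(spacers)
        parsed = vs.parse_pattern(pattern)
        realized = [s if s is not None else 7 for s in parsed]
        assert vs.canonical_pattern(realized) == pattern


class TestCategories:
    def test_roman_category_from_cys_count(self):
        assert vs.build_scaffold("C" * 6).category == "VI"
        assert vs.build_scaffold("CACACAC A".replace(" ", "")).category == "IV"
        sc = vs.build_scaffold("CACACACAC")
        assert sc.category == "V" and sc.parity == "odd"

    def test_roman_numerals(self):
        assert [roman(n) for n in (4, 5, 6, 8, 9, 12)] == \
            ["IV", "V", "VI", "VIII", "IX", "XII"]

    def test_subcategory_is_lexicographic_rank_within_category(self):
        seqs = ["CAAAAC" + "AAAAC" * 3,   # 5 Cys pattern A
                "CCAAAAACAAAAACAAAAAC",   # 5 Cys pattern B (starts CC)
                "CACA"]                   # 2 Cys
        scaffolds = vs.assign_categories([vs.build_scaffold(s) for s in seqs])
        by_pattern = {s.pattern: s.subcategory for s in scaffolds}
        cat_v = sorted(p for p in by_pattern
                       if p.count("C") == 5)
        assert [by_pattern[p] for p in sorted(cat_v)] == [1, 2]


class TestTemplates:
    def test_exact_matches_for_all_bundled_patterns(self):
        for t in vs.DEFAULT_TEMPLATES:
            hits = vs.match_template(t.pattern)
            assert (t, "exact") in hits

    def test_relaxed_match_is_spacer_length_blind(self):
        hits = vs.match_template("C-C-C-CX2CX2C")
        kinds = {t.family: kind for t, kind in hits}
        assert kinds.get("ShKT") == "relaxed"

    def test_exact_ranks_before_relaxed(self):
        hits = vs.match_template("C-C-C-CX3CX2C")
        assert hits[0][1] == "exact"

    def test_cc_only_matches_nothing(self):
        assert vs.match_template("CC") == []
        assert vs.match_template(vs.build_scaffold("KK")) == []

    def test_relaxed_pattern_collapse(self):
        assert relaxed_pattern("C-CX3CX12C") == "C-CXCXC"

    def test_bundled_yaml_registry_agrees_with_defaults(self):
        loaded = {t.family: t for t in load_templates()}
        for t in vs.DEFAULT_TEMPLATES:
            assert loaded[t.family].pattern == t.pattern
            assert loaded[t.family].connectivity == t.connectivity


class TestConnectivity:
    @pytest.mark.parametrize("family,pairs", [
        ("ShKT", [(1, 6), (2, 4), (3, 5)]),
        ("beta-defensin", [(1, 5), (2, 4), (3, 6)]),
        ("Kunitz-type", [(1, 6), (3, 5), (2, 4)]),
    ])
    def test_template_pairs_returned_verbatim(self, family, pairs):
        tmpl = next(t for t in vs.DEFAULT_TEMPLATES if t.family == family)
        seq = "A".join(["C"] * tmpl.n_cys)
        got, reason = vs.predict_connectivity(vs.build_scaffold(seq), family)
        assert got == pairs and reason == "template"

    def test_count_mismatch_gives_no_prediction(self):
        sc = vs.build_scaffold("CACACACAC")     # 5 Cys
        got, reason = vs.predict_connectivity(sc, "ShKT")
        assert got == [] and "mismatch" in reason

    def test_unknown_family_never_invents_pairs(self):
        sc = vs.build_scaffold("CACACA")
        got, reason = vs.predict_connectivity(sc, "mystery")
        assert got == []


class TestCensus:
    def test_all_four_cys(self):
        scaffolds = [vs.build_scaffold("CACACACA") for _ in range(5)]
        census = vs.pattern_census(scaffolds)
        assert census.loc["IV", "pct"] == 100.00

    def test_hand_computed_percentages(self):
        seqs = ["CC", "CAC", "CACAC", "CACAC"]   # sizes 1,1,2 by category
        census = vs.pattern_census([vs.build_scaffold(s) for s in seqs])
        assert census.loc["II", "count"] == 2
        assert census.loc["II", "pct"] == 50.00
        assert census.loc["III", "pct"] == 50.00

    def test_counts_sum_to_input_and_pct_to_100(self, default_fixture):
        _, records, _, truth, _ = default_fixture
        scaffolds = [vs.build_scaffold(r.seq) for r in records
                     if "C" in r.seq]
        census = vs.pattern_census(scaffolds)
        assert census["count"].sum() == len(scaffolds)
        assert abs(census["pct"].sum() - 100.0) <= 0.02
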