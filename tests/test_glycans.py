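"""Sequence grammar, validation, motif search and sulfation statistics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heparlib import (Aglycone, GrammarError, Oligosaccharide, Residue, Ring,
                      ValidationError, find_at_motif, fixture_names,
                      format_sequence, get_fixture, parse_sequence,
                      sulfation_stats)
from heparlib.simulate import random_sequence

from conftest import C14_SEQ


class TestParse:
    def test_compound_14_string(self):
        oligo = parse_sequence(C14_SEQ)
        assert len(oligo) == 6
        assert oligo.aglycone is Aglycone.PNA_N3
        assert oligo.labels == ("A", "B", "C", "D", "E", "F")
        assert [r.token for r in oligo] == [
            "GlcNS6S", "GlcA", "GlcNS3S6S", "IdoA2S", "GlcNS6S", "GlcA"]

    def test_single_residue_seed(self):
        oligo = parse_sequence("GlcA-pNA-N3")
        assert len(oligo) == 1
        assert oligo.residues[0].ring is Ring.GLUCO_URONIC
        assert oligo.aglycone is Aglycone.PNA_N3

    def test_arrow_variants_accepted(self):
        a = parse_sequence("GlcNS(1-4)GlcA-pNA-N3")
        b = parse_sequence("GlcNS(1->4)GlcA-pNA-N3")
        c = parse_sequence("GlcNS(1→4)GlcA-pNA-N3")
        assert a == b == c

    @pytest.mark.parametrize("bad, exc", [
        ("GlcNS(1-4)GlcNS-pNA-N3", ValidationError),   # adjacent amines
        ("GlcA(1-4)IdoA-pNA-N3", ValidationError),     # adjacent uronics
        ("GlcAX(1-4)GlcNS", GrammarError),             # unknown token
        ("GlcA6S(1-4)GlcNS", GrammarError),            # 6S illegal on uronic
        ("GlcNS2S", GrammarError),                     # 2S illegal on amine
        ("GlcNAc3S6S(1-4)GlcA", ValidationError),      # 3S needs N-sulfo
        ("", GrammarError),
        ("GlcA(1-4)", GrammarError),
    ])
    def test_rejects_invalid(self, bad, exc):
        with pytest.raises(exc):
            parse_sequence(bad)

    def test_anomeric_config_derived(self):
        assert Residue.from_token("GlcA").anomeric_config == "beta"
        assert Residue.from_token("GlcA2S").anomeric_config == "beta"
        assert Residue.from_token("IdoA2S").anomeric_config == "alpha"
        assert Residue.from_token("GlcNS6S").anomeric_config == "alpha"


class TestRoundTrip:
    def test_fixtures_round_trip(self):
        for name in fixture_names():
            fx = get_fixture(name)
            assert format_sequence(parse_sequence(fx.sequence)) == fx.sequence
            assert parse_sequence(format_sequence(fx.oligo)) == fx.oligo

    @settings(max_examples=200, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), length=st.integers(1, 12))
    def test_random_sequences_round_trip(self, seed, length):
        oligo = random_sequence(length, seed,
                                {"allow_transient": seed % 2 == 0})
        assert parse_sequence(format_sequence(oligo)) == oligo

    def test_thousand_random_round_trips(self):
        for i in range(1000):
            oligo = random_sequence(1 + i % 9, i)
            assert parse_sequence(format_sequence(oligo)) == oligo


class TestMotif:
    def test_compound_14_has_one_hit_a_to_e(self, c14):
        hits = find_at_motif(c14)
        assert len(hits) == 1
        assert (hits[0].start_label, hits[0].end_label) == ("A", "E")

    def test_intermediates_have_no_hit(self):
        for name in ["I", "II", "III", "IV", "V", "VI", "VII"]:
            assert find_at_motif(get_fixture(name).oligo) == []

    def test_bare_pentasaccharide_self_match(self):
        penta = parse_sequence(
            "GlcNS6S(1-4)GlcA(1-4)GlcNS3S6S(1-4)IdoA2S(1-4)GlcNS6S")
        hits = find_at_motif(penta)
        assert len(hits) == 1
        assert (hits[0].start_label, hits[0].end_label) == ("A", "E")

    def test_library_compounds_with_at_site(self):
        for name in ["14", "28", "46"]:
            assert len(find_at_motif(get_fixture(name).oligo)) >= 1


class TestSulfationStats:
    def test_compound_14(self, c14):
        s = sulfation_stats(c14)
        assert (s.n_sulfo, s.o2_sulfo, s.o3_sulfo, s.o6_sulfo) == (3, 1, 1, 3)
        assert s.total_sulfo == 8
        assert s.sulfo_per_disaccharide == pytest.approx(8 / 3)
        assert s.pct_idoA_of_uronic == pytest.approx(100 / 3)

    def test_intermediate_iv(self, inter_iv):
        s = sulfation_stats(inter_iv)
        assert s.total_sulfo == 2
        assert s.n_sulfo == 2
        assert s.pct_idoA_of_uronic == 0.0

    def test_unsulfated_backbone(self):
        s = sulfation_stats(parse_sequence("GlcA(1-4)GlcNAc(1-4)GlcA"))
        assert s.total_sulfo == 0
        assert s.sulfo_per_disaccharide == 0.0
        assert s.pct_idoA_of_uronic == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), length=st.integers(1, 10))
    def test_group_counts_conserve_total(self, seed, length):
        oligo = random_sequence(length, seed)
        s = sulfation_stats(oligo)
        assert s.n_sulfo + s.o2_sulfo + s.o3_sulfo + s.o6_sulfo \
            == s.total_sulfo == sum(r.sulfo_count for r in oligo)


class TestFixtures:
    def test_printed_flags(self):
        for name in ["14", "IV", "V", "VI"]:
            assert get_fixture(name).flag == "printed"
        for name in ["I", "II", "III", "VII", "28", "46", "65", "66"]:
            assert get_fixture(name).flag == "reconstructed"

    def test_intermediate_vi_structure(self):
        assert get_fixture("VI").sequence == \
            "GlcA(1-4)GlcNS(1-4)IdoA2S(1-4)GlcNS(1-4)GlcA-pNA-N3"

    def test_intermediate_i_is_diacetylated(self):
        oligo = get_fixture("I").oligo
        amines = [r for r in oligo if not r.is_uronic]
        assert len(amines) == 2
        assert all(r.token == "GlcNAc" for r in amines)

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            get_fixture("999")

    def test_all_fixtures_end_in_tagged_glca(self):
        for name in fixture_names():
            fx = get_fixture(name)
            assert fx.oligo.residues[-1].ring is Ring.GLUCO_URONIC
            assert fx.oligo.aglycone is Aglycone.PNA_N3

    def test_residue_lookup_by_label(self, c14):
        assert c14.residue("D").token == "IdoA2S"
        with pytest.raises(KeyError):
            c14.residue("Z")

    def test_empty_chain_rejected(self):
        with pytest.raises(ValidationError):
            Oligosaccharide(())
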