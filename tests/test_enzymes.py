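"""Enzyme eligibility rules, route planning and the IdoA2S lock."""

import pytest

from heparlib import (InfeasibilityReport, PlannerConfig, PlannerError,
                      Route, RouteStep, apply_action, eligible_sites,
                      enumerate_library, format_sequence, get_fixture,
                      parse_sequence, plan_route, validate_route)
from heparlib.glycans import Ring


class TestEligibility:
    def test_c5_epi_only_internal_glca_between_glcns(self, inter_iv):
        assert eligible_sites(inter_iv, "C5-epi") == ["C"]

    def test_c5_epi_blocked_by_3s_flank(self, c14):
        """Residue B of the finished hexasaccharide sits next to a
        3-O-sulfated glucosamine, so the epimerase cannot touch it."""
        assert eligible_sites(c14, "C5-epi") == []
        with pytest.raises(PlannerError):
            apply_action(c14, "C5-epi")

    def test_3ost1_selects_c_not_e(self, inter_vi):
        """After elongation/N-sulfation/6-O-sulfation of the IdoA2S
        pentasaccharide, only residue C has a GlcA on its non-reducing
        side, so 3-OST-1 acts there rather than on residue E."""
        hexa = apply_action(inter_vi, "pmHS2+GlcNTFA")
        hexa = apply_action(hexa, "deTFA+NST")
        hexa = apply_action(hexa, "6-OST")
        assert eligible_sites(hexa, "3-OST-1") == ["C"]

    def test_3ost1_prefers_idoa2s_reducing_side(self):
        """In the octasaccharide precursor two glucosamines have a GlcA
        on the non-reducing side; the IdoA2S on the reducing side breaks
        the tie."""
        pre46 = parse_sequence(
            "GlcNS6S(1-4)GlcA(1-4)GlcNS6S(1-4)GlcA(1-4)GlcNS6S(1-4)"
            "IdoA2S(1-4)GlcNS6S(1-4)GlcA-pNA-N3")
        assert eligible_sites(pre46, "3-OST-1") == ["E"]

    def test_3ost1_6s_requirement_flag(self, inter_iv):
        assert eligible_sites(inter_iv, "3-OST-1") == []
        relaxed = PlannerConfig(require_6s_for_3ost=False)
        # both glucosamines carry a GlcA on the non-reducing side and no
        # IdoA2S is present to break the tie
        assert eligible_sites(inter_iv, "3-OST-1", relaxed) == ["B", "D"]

    def test_elongation_respects_alternation(self, seed):
        assert eligible_sites(seed, "pmHS2+GlcA") == []
        assert eligible_sites(seed, "pmHS2+GlcNTFA") == ["A"]
        di = apply_action(seed, "pmHS2+GlcNTFA")
        assert eligible_sites(di, "pmHS2+GlcNTFA") == []
        assert eligible_sites(di, "pmHS2+GlcA") == ["A"]

    def test_2ost_on_glca_site_policies(self, inter_iv):
        assert eligible_sites(inter_iv, "2-OST-on-GlcA") == ["A", "C"]
        internal = PlannerConfig(two_ost_site_policy="internal")
        assert eligible_sites(inter_iv, "2-OST-on-GlcA", internal) == ["C"]
        everything = PlannerConfig(two_ost_site_policy="all")
        assert eligible_sites(inter_iv, "2-OST-on-GlcA", everything) \
            == ["A", "C", "E"]

    def test_6ost_targets_ns_and_nac_without_6s(self):
        oligo = parse_sequence(
            "GlcNAc(1-4)GlcA(1-4)GlcNS6S(1-4)GlcA(1-4)GlcNS(1-4)"
            "GlcA-pNA-N3")
        assert eligible_sites(oligo, "6-OST") == ["A", "E"]


class TestApply:
    def test_iv_plus_epi_2ost_gives_vi(self, inter_iv, inter_vi):
        assert apply_action(inter_iv, "C5-epi+2-OST", ["C"]) == inter_vi

    def test_iv_plus_2ost_gives_65_and_66(self, inter_iv):
        one = apply_action(inter_iv, "2-OST-on-GlcA", ["C"])
        two = apply_action(inter_iv, "2-OST-on-GlcA", ["A", "C"])
        assert one == get_fixture("65").oligo
        assert two == get_fixture("66").oligo

    def test_c5_epi_toggles_and_is_reversible(self, inter_iv):
        v = apply_action(inter_iv, "C5-epi")
        assert v == get_fixture("V").oligo
        assert apply_action(v, "C5-epi") == inter_iv

    def test_detfa_nst_is_atomic(self, seed):
        tri = apply_action(apply_action(seed, "pmHS2+GlcNTFA"), "pmHS2+GlcA")
        done = apply_action(tri, "deTFA+NST")
        assert [r.token for r in done] == ["GlcA", "GlcNS", "GlcA"]

    def test_ineligible_site_rejected(self, inter_iv):
        with pytest.raises(PlannerError):
            apply_action(inter_iv, "C5-epi+2-OST", ["A"])

    def test_outputs_always_validate(self, inter_iv):
        from heparlib.enzymes import ACTIONS, _successors, DEFAULT_CONFIG
        for _step, new in _successors(inter_iv, DEFAULT_CONFIG):
            # constructing the Oligosaccharide re-runs all invariants
            assert parse_sequence(format_sequence(new)) == new


class TestPlanner:
    def test_printed_route_to_iv(self, seed, inter_iv):
        route = plan_route(seed, inter_iv)
        assert route.action_names == (
            "pmHS2+GlcNTFA", "pmHS2+GlcA", "pmHS2+GlcNTFA", "pmHS2+GlcA",
            "deTFA+NST")

    def test_printed_route_iv_to_vi(self, inter_iv, inter_vi):
        assert plan_route(inter_iv, inter_vi).action_names \
            == ("C5-epi+2-OST",)

    def test_printed_route_vi_to_14(self, inter_vi, c14):
        route = plan_route(inter_vi, c14)
        assert route.action_names == (
            "pmHS2+GlcNTFA", "deTFA+NST", "6-OST", "3-OST-1")
        assert route.steps[-1].sites == ("C",)

    def test_all_fixtures_reachable_from_seed(self, seed):
        from heparlib import fixture_names
        for name in fixture_names():
            result = plan_route(seed, get_fixture(name).oligo)
            assert isinstance(result, Route), name
            ok, diag = validate_route(result)
            assert ok, (name, diag)
            assert result.end == get_fixture(name).oligo

    def test_route_replay_round_trip(self, seed, c14):
        route = plan_route(seed, c14)
        ok, diag = validate_route(route)
        assert ok and diag is None

    def test_3ost_before_6ost_flagged_under_default_rule(self, inter_vi):
        hexa = apply_action(inter_vi, "pmHS2+GlcNTFA")
        hexa = apply_action(hexa, "deTFA+NST")
        bad = Route(hexa, (RouteStep("3-OST-1", ("C",)),
                           RouteStep("6-OST", ("A", "C", "E"))),
                    apply_action(apply_action(
                        hexa, "3-OST-1", ["C"],
                        PlannerConfig(require_6s_for_3ost=False)), "6-OST"))
        ok, diag = validate_route(bad)
        assert not ok and "3-OST-1" in diag
        ok_relaxed, _ = validate_route(
            bad, PlannerConfig(require_6s_for_3ost=False))
        assert ok_relaxed

    def test_infeasible_target_reported(self, seed):
        # no enzyme action produces a free-amine glucosamine
        target = parse_sequence("GlcA(1-4)GlcN(1-4)GlcA-pNA-N3")
        result = plan_route(seed, target)
        assert isinstance(result, InfeasibilityReport)

    def test_determinism(self, seed, c14):
        r1 = plan_route(seed, c14)
        r2 = plan_route(seed, c14)
        assert r1.action_names == r2.action_names
        assert [s.sites for s in r1.steps] == [s.sites for s in r2.steps]

    def test_identity_route(self, seed):
        route = plan_route(seed, seed)
        assert route.steps == ()


class TestEnumeration:
    def test_depth_zero_is_seed_only(self, seed):
        assert enumerate_library(seed, 0) == [seed]

    def test_negative_depth_rejected(self, seed):
        with pytest.raises(PlannerError):
            enumerate_library(seed, -1)

    def test_deterministic_and_growing(self, seed):
        lib4a = enumerate_library(seed, 4)
        lib4b = enumerate_library(seed, 4)
        assert [format_sequence(o) for o in lib4a] \
            == [format_sequence(o) for o in lib4b]
        lib5 = {format_sequence(o) for o in enumerate_library(seed, 5)}
        assert {format_sequence(o) for o in lib4a} <= lib5

    def test_lock_invariant_depth_8(self, seed):
        """No reachable transition ever demotes a 2-O-sulfated uronic
        acid: IdoA2S is never epimerized back and GlcA2S never converted."""
        from heparlib.enzymes import _successors, DEFAULT_CONFIG
        for state in enumerate_library(seed, 8):
            locked = [(i, r.ring) for i, r in enumerate(state.residues[::-1])
                      if r.is_uronic and 2 in r.o_sulfo]
            for _step, new in _successors(state, DEFAULT_CONFIG):
                rev = new.residues[::-1]
                for i, ring in locked:
                    assert rev[i].ring is ring
                    assert 2 in rev[i].o_sulfo
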