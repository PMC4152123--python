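import numpy as np
import pytest

import spnlab as sl
from spnlab.petri_model import structurally_equal
from spnlab.testing import random_flat_net, random_hierarchical_net

from conftest import (
    all_markings,
    oracle_enabled,
    oracle_fire,
    oracle_flatten_arcs,
    oracle_leaves,
)


def simple_net():
    net = sl.PetriNet()
    net.add_place(sl.Place("A", initial_tokens=2))
    net.add_place(sl.Place("B"))
    net.add_transition(sl.Transition("t"))
    net.add_arc("A", "t")
    net.add_arc("t", "B")
    return net


class TestValidation:
    def test_valid_net_has_no_violations(self):
        assert sl.net_validate(simple_net()) == []

    def test_place_place_arc_violates_bipartiteness(self):
        net = simple_net()
        net.arcs.append(sl.Arc("A", "B"))
        violations = sl.net_validate(net)
        assert len(violations) == 1 and "bipartite" in violations[0]

    def test_place_in_two_coarse_places_violates_forest(self):
        net = sl.PetriNet()
        net.add_place(sl.Place("p"))
        net.add_place(sl.Place("C1", contained=["p"]))
        net.add_place(sl.Place("C2", contained=["p"]))
        violations = sl.net_validate(net)
        assert len(violations) == 1 and "contained in both" in violations[0]

    def test_containment_cycle_detected(self):
        net = sl.PetriNet()
        net.places["C1"] = sl.Place("C1", contained=["C2"])
        net.places["C2"] = sl.Place("C2", contained=["C1"])
        assert any("cycle" in v for v in sl.net_validate(net))

    def test_nonpositive_rate_flagged(self):
        net = simple_net()
        net.transitions["t"].rate_constant = 0.0
        assert any("rate_constant" in v for v in sl.net_validate(net))

    def test_reserved_separator_rejected_at_creation(self):
        net = sl.PetriNet()
        with pytest.raises(sl.ValidationError):
            net.add_place(sl.Place("a::b"))


class TestFlatten:
    def test_coarse_arc_replicates_to_contained_leaves(self):
        net = sl.PetriNet()
        for pid in ("p1", "p2", "p3"):
            net.add_place(sl.Place(pid))
        net.add_place(sl.Place("C", contained=["p1", "p2", "p3"]))
        net.add_transition(sl.Transition("t"))
        net.add_arc("C", "t")
        flat = sl.flatten(net)
        assert sorted((a.source, a.target) for a in flat.arcs) == [
            ("p1", "t"), ("p2", "t"), ("p3", "t")]
        assert "C" not in flat.places

    def test_flat_net_unchanged(self):
        net = simple_net()
        assert structurally_equal(sl.flatten(net), net)

    def test_nested_coarse_expansion(self):
        net = sl.PetriNet()
        for pid in ("p1", "p2", "p3"):
            net.add_place(sl.Place(pid))
        net.add_place(sl.Place("C2", contained=["p1", "p2"]))
        net.add_place(sl.Place("C1", contained=["C2", "p3"]))
        net.add_transition(sl.Transition("t"))
        net.add_arc("C1", "t")
        flat = sl.flatten(net)
        assert sorted((a.source, a.target) for a in flat.arcs) == [
            ("p1", "t"), ("p2", "t"), ("p3", "t")]

    def test_nested_transition_prefixing_and_boundary_unification(self):
        inner = sl.PetriNet()
        inner.add_place(sl.Place("S", initial_tokens=5))
        inner.add_place(sl.Place("I"))
        inner.add_transition(sl.Transition("step"))
        inner.add_arc("S", "step")
        inner.add_arc("step", "I")
        outer = sl.PetriNet()
        outer.add_place(sl.Place("S", initial_tokens=2))
        outer.add_transition(sl.Transition("module", nested=inner))
        flat = sl.flatten(outer)
        assert set(flat.places) == {"S", "module::I"}
        assert set(flat.transitions) == {"module::step"}
        # the outer S is the boundary place and keeps its own marking
        assert flat.places["S"].initial_tokens == 2

    def test_arc_on_container_transition_is_an_error(self):
        inner = sl.PetriNet()
        inner.add_place(sl.Place("p"))
        outer = sl.PetriNet()
        outer.add_place(sl.Place("q"))
        outer.add_transition(sl.Transition("module", nested=inner))
        outer.add_arc("q", "module")
        with pytest.raises(sl.ValidationError, match="container"):
            sl.flatten(outer)

    @pytest.mark.parametrize("seed", range(60))
    def test_flatten_matches_recursive_expansion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_hierarchical_net(rng)
        flat = sl.flatten(net)
        got = {}
        for arc in flat.arcs:
            got[(arc.source, arc.target)] = got.get((arc.source, arc.target), 0) \
                + arc.multiplicity
        assert got == oracle_flatten_arcs(net)
        # leaf places and total initial tokens preserved
        leaf_ids = {p.id for p in net.leaf_places()}
        assert set(flat.places) == leaf_ids
        assert sum(p.initial_tokens for p in flat.places.values()) == \
            sum(net.places[pid].initial_tokens for pid in leaf_ids)
        # idempotence
        assert structurally_equal(sl.flatten(flat), flat)


class TestFiring:
    def test_threshold_enabledness(self):
        net = sl.PetriNet()
        net.add_place(sl.Place("p"))
        net.add_transition(sl.Transition("t"))
        net.add_arc("p", "t", 2)
        assert sl.enabled(net, {"p": 0}) == set()
        assert sl.enabled(net, {"p": 1}) == set()
        assert sl.enabled(net, {"p": 2}) == {"t"}

    def test_simple_fire_moves_token(self):
        net = simple_net()
        assert sl.fire(net, {"A": 2, "B": 0}, "t") == {"A": 1, "B": 1}

    def test_catalytic_loop_preserves_catalyst(self, kinase_net):
        m = sl.fire(kinase_net, {"K": 1, "S": 3, "Sp": 0}, "phos")
        assert m == {"K": 1, "S": 2, "Sp": 1}

    def test_fire_disabled_raises(self):
        net = simple_net()
        with pytest.raises(sl.DisabledFireError):
            sl.fire(net, {"A": 0, "B": 0}, "t")

    def test_nonflat_net_must_be_flattened_first(self):
        net = sl.PetriNet()
        net.add_place(sl.Place("p"))
        net.add_place(sl.Place("C", contained=["p"]))
        net.add_transition(sl.Transition("t"))
        with pytest.raises(sl.MustFlattenError):
            sl.enabled(net, {"p": 0})

    @pytest.mark.parametrize("seed", range(100))
    def test_enabled_and_fire_match_brute_force_oracle(self, seed):
        """Exhaustive agreement on small random nets over all small markings."""
        rng = np.random.default_rng(10_000 + seed)
        net = random_flat_net(rng)
        place_ids = list(net.places)
        for marking in all_markings(place_ids, 3):
            expect = oracle_enabled(net, marking)
            assert sl.enabled(net, marking) == expect
            for tid in expect:
                got = sl.fire(net, marking, tid)
                want = oracle_fire(net, marking, tid)
                assert got == want
                assert all(v >= 0 for v in got.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_conservative_net_total_tokens_invariant_under_random_walks(self, seed):
        """Transitions with equal in/out multiplicity totals conserve tokens."""
        rng = np.random.default_rng(seed)
        net = sl.PetriNet()
        n_places = 4
        for i in range(n_places):
            net.add_place(sl.Place(f"p{i}", initial_tokens=int(rng.integers(0, 5))))
        for j in range(4):
            src, dst = rng.choice(n_places, size=2, replace=False)
            k = int(rng.integers(1, 3))
            net.add_transition(sl.Transition(f"t{j}"))
            net.add_arc(f"p{src}", f"t{j}", k)
            net.add_arc(f"t{j}", f"p{dst}", k)
        marking = sl.initial_marking(net)
        total = sum(marking.values())
        for _ in range(200):
            options = sorted(sl.enabled(net, marking))
            if not options:
                break
            marking = sl.fire(net, marking, options[int(rng.integers(len(options)))])
            assert sum(marking.values()) == total
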