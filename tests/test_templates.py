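import itertools

import pytest

import spnlab as sl
from spnlab.templates import get_builtin

from conftest import all_markings


def tpl(name):
    return get_builtin(name)


class TestInstantiate:
    def test_and_gate_wiring(self):
        net = sl.instantiate(tpl("AND"), {"in1": "p1", "in2": "p2", "out": "q"}, "g::")
        assert set(net.places) == {"p1", "p2", "q"}
        assert set(net.transitions) == {"g::gate"}
        arcs = sorted((a.source, a.target) for a in net.arcs)
        assert arcs == [("g::gate", "q"), ("p1", "g::gate"), ("p2", "g::gate")]

    def test_kinase_motif_preserves_catalyst(self):
        net = sl.instantiate(
            tpl("KINASE_SUBSTRATE"),
            {"kinase": "K", "substrate": "S", "product": "Sp"},
        )
        m = sl.fire(net, {"K": 1, "S": 3, "Sp": 0}, "phosphorylate")
        assert m == {"K": 1, "S": 2, "Sp": 1}

    def test_missing_required_binding_names_the_site(self):
        with pytest.raises(sl.BindingError) as err:
            sl.instantiate(tpl("AND"), {"in1": "p1", "in2": "p2"})
        assert err.value.site == "out"

    def test_unknown_binding_site_rejected(self):
        with pytest.raises(sl.CompositionError):
            sl.instantiate(tpl("SOURCE"), {"nope": "x"})

    @pytest.mark.parametrize("name", [
        "AND", "OR", "SOURCE", "SINK", "REVERSIBLE_BINDING", "KINASE_SUBSTRATE"])
    def test_every_builtin_instantiates_validly(self, name):
        template = tpl(name)
        bindings = {p.name: f"host_{p.name}" for p in template.parameters}
        net = sl.instantiate(template, bindings, "m::")
        assert sl.net_validate(net) == []


class TestGateSemantics:
    def test_and_requires_both_inputs(self):
        net = sl.instantiate(tpl("AND"), {"in1": "a", "in2": "b", "out": "q"})
        assert sl.enabled(net, {"a": 1, "b": 0, "q": 0}) == set()
        assert sl.enabled(net, {"a": 1, "b": 1, "q": 0}) == {"gate"}

    def test_or_fires_on_either_input(self):
        net = sl.instantiate(tpl("OR"), {"in1": "a", "in2": "b", "out": "q"})
        assert sl.enabled(net, {"a": 1, "b": 0, "q": 0}) == {"gate1"}
        assert sl.enabled(net, {"a": 0, "b": 1, "q": 0}) == {"gate2"}

    def test_gate_output_gain_exhaustive(self):
        """Over all markings <= 2 tokens/place: AND's output can only grow
        from markings with both inputs supplied; OR's with at least one."""
        and_net = sl.instantiate(tpl("AND"), {"in1": "a", "in2": "b", "out": "q"})
        or_net = sl.instantiate(tpl("OR"), {"in1": "a", "in2": "b", "out": "q"})
        for m in all_markings(["a", "b", "q"], 2):
            gains_and = any(
                sl.fire(and_net, m, t)["q"] > m["q"]
                for t in sl.enabled(and_net, m)
            )
            assert gains_and == (m["a"] >= 1 and m["b"] >= 1)
            gains_or = any(
                sl.fire(or_net, m, t)["q"] > m["q"]
                for t in sl.enabled(or_net, m)
            )
            assert gains_or == (m["a"] >= 1 or m["b"] >= 1)

    def test_reversible_binding_forward_backward_restores_marking(self):
        net = sl.instantiate(tpl("REVERSIBLE_BINDING"),
                             {"a": "A", "b": "B", "ab": "AB"})
        m0 = {"A": 1, "B": 1, "AB": 0}
        m1 = sl.fire(net, m0, "bind")
        assert m1 == {"A": 0, "B": 0, "AB": 1}
        assert sl.fire(net, m1, "release") == m0

    def test_kinase_catalyst_conserved_along_any_firing_sequence(self):
        net = sl.instantiate(
            tpl("KINASE_SUBSTRATE"),
            {"kinase": "K", "substrate": "S", "product": "Sp"},
        )
        m = {"K": 2, "S": 4, "Sp": 0}
        while True:
            options = sorted(sl.enabled(net, m))
            if not options:
                break
            m = sl.fire(net, m, options[0])
            assert m["K"] == 2
        assert m == {"K": 2, "S": 0, "Sp": 4}


class TestCompose:
    def host(self):
        net = sl.PetriNet(name="host")
        net.add_place(sl.Place("ATP", initial_tokens=5))
        net.add_place(sl.Place("X"))
        net.add_transition(sl.Transition("use"))
        net.add_arc("ATP", "use")
        net.add_arc("use", "X")
        return net

    def fragment(self):
        net = sl.PetriNet(name="frag")
        net.add_place(sl.Place("ATP", initial_tokens=0))
        net.add_place(sl.Place("Y"))
        net.add_transition(sl.Transition("consume"))
        net.add_arc("ATP", "consume")
        net.add_arc("consume", "Y")
        return net

    def test_compose_into_empty_prefixes_everything(self):
        out = sl.compose(sl.PetriNet(), self.fragment(), set(), "m1::")
        assert set(out.places) == {"m1::ATP", "m1::Y"}
        assert set(out.transitions) == {"m1::consume"}

    def test_shared_place_unified_with_host_attributes(self):
        out = sl.compose(self.host(), self.fragment(), {"ATP"}, "m1::")
        assert out.places["ATP"].initial_tokens == 5  # host wins
        inputs = {a.target for a in out.arcs if a.source == "ATP"}
        assert inputs == {"use", "m1::consume"}

    def test_place_count_arithmetic(self):
        host, frag = self.host(), self.fragment()
        out = sl.compose(host, frag, {"ATP"}, "m1::")
        assert len(out.places) == len(host.places) + len(frag.places) - 1

    def test_role_mismatch_rejected(self):
        host = self.host()
        frag = sl.PetriNet()
        frag.add_transition(sl.Transition("ATP"))  # transition named like a place
        with pytest.raises(sl.CompositionError):
            sl.compose(host, frag, {"ATP"}, "m::")

    def test_host_is_not_mutated_and_keeps_its_ids(self):
        host = self.host()
        before = set(host.places) | set(host.transitions)
        out = sl.compose(host, self.fragment(), {"ATP"}, "m::")
        assert set(host.places) | set(host.transitions) == before
        assert before <= (set(out.places) | set(out.transitions))


class TestTemplateFiles:
    def test_template_json_roundtrip(self):
        template = tpl("KINASE_SUBSTRATE")
        text = sl.write_template_json(template)
        back = sl.read_template_json(text)
        assert back.name == template.name
        assert [p.name for p in back.parameters] == \
            [p.name for p in template.parameters]
        bindings = {p.name: p.name.upper() for p in back.parameters}
        assert sl.net_validate(sl.instantiate(back, bindings, "k::")) == []

    def test_future_version_rejected(self):
        import json
        doc = json.loads(sl.write_template_json(tpl("AND")))
        doc["format_version"] = "99.0"
        with pytest.raises(sl.UnsupportedVersionError):
            sl.read_template_json(json.dumps(doc))
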