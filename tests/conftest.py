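import numpy as np
import pytest
from hypothesis import settings

import spnlab as sl

settings.register_profile("repeatable", derandomize=True, max_examples=30)
settings.load_profile("repeatable")


@pytest.fixture
def kinase_net():
    """Catalytic phosphorylation motif: K conserved, S converted to Sp."""
    net = sl.PetriNet(name="kinase")
    net.add_place(sl.Place("K", initial_tokens=1))
    net.add_place(sl.Place("S", initial_tokens=3))
    net.add_place(sl.Place("Sp", initial_tokens=0))
    net.add_transition(sl.Transition("phos", rate_constant=1.0))
    net.add_arc("K", "phos")
    net.add_arc("phos", "K")
    net.add_arc("S", "phos")
    net.add_arc("phos", "Sp")
    return net


@pytest.fixture
def immigration_death_bundle():
    """Birth-death chain with birth rate 10, per-capita death rate 1.

    Its stationary law is Poisson(10): mean and variance both 10.
    """
    return sl.MatrixBundle(
        place_ids=["X"], transition_ids=["birth", "death"],
        pre=[[0, 1]], post=[[1, 0]], initial_marking=[0], rates=[10.0, 1.0],
    )


@pytest.fixture
def isomerization_bundle():
    """A <-> B with equal unit rates and 10 tokens starting in A."""
    return sl.MatrixBundle(
        place_ids=["A", "B"], transition_ids=["ab", "ba"],
        pre=[[1, 0], [0, 1]], post=[[0, 1], [1, 0]],
        initial_marking=[10, 0], rates=[1.0, 1.0],
    )


@pytest.fixture
def two_state_one_token_bundle():
    """A <-> B with one token: a two-state CTMC with known transient law."""
    return sl.MatrixBundle(
        place_ids=["A", "B"], transition_ids=["ab", "ba"],
        pre=[[1, 0], [0, 1]], post=[[0, 1], [1, 0]],
        initial_marking=[1, 0], rates=[1.0, 1.0],
    )


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def oracle_enabled(net, marking):
    """Per-arc exhaustive enabledness check, straight from the arc list."""
    result = set()
    for tid in net.transitions:
        ok = True
        for arc in net.arcs:
            if arc.target == tid and arc.source in net.places:
                if marking.get(arc.source, 0) < _total_mult(net, arc.source, tid, "in"):
                    ok = False
                    break
        if ok:
            result.add(tid)
    return result


def _total_mult(net, pid, tid, direction):
    total = 0
    for arc in net.arcs:
        if direction == "in" and arc.source == pid and arc.target == tid:
            total += arc.multiplicity
        if direction == "out" and arc.source == tid and arc.target == pid:
            total += arc.multiplicity
    return total


def oracle_fire(net, marking, tid):
    """Pre/Post arithmetic applied place by place from the raw arc list."""
    out = dict(marking)
    for pid in net.places:
        out[pid] = (
            marking.get(pid, 0)
            - _total_mult(net, pid, tid, "in")
            + _total_mult(net, pid, tid, "out")
        )
    return out


def oracle_leaves(net, pid):
    """Recursive leaf expansion of a (possibly coarse) place."""
    place = net.places[pid]
    if not place.contained:
        return [pid]
    out = []
    for child in place.contained:
        out.extend(oracle_leaves(net, child))
    return out


def oracle_flatten_arcs(net):
    """Expected flat arc map {(source, target): total multiplicity}."""
    expected = {}
    for arc in net.arcs:
        if arc.source in net.places:
            for leaf in oracle_leaves(net, arc.source):
                key = (leaf, arc.target)
                expected[key] = expected.get(key, 0) + arc.multiplicity
        else:
            for leaf in oracle_leaves(net, arc.target):
                key = (arc.source, leaf)
                expected[key] = expected.get(key, 0) + arc.multiplicity
    return expected


def all_markings(place_ids, max_tokens):
    """Every marking with at most max_tokens per place (cartesian product)."""
    if not place_ids:
        yield {}
        return
    head, *tail = place_ids
    for rest in all_markings(tail, max_tokens):
        for k in range(max_tokens + 1):
            yield {head: k, **rest}
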