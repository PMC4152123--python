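"""Hierarchical stochastic Petri nets.

A Petri net is a bipartite directed graph: *places* hold non-negative integer
token counts (the quantity of a species), *transitions* are actions that
consume tokens from their input places and produce tokens in their output
places, and *arcs* carry integer multiplicities (stoichiometric weights).

Two hierarchy mechanisms are supported, both purely structural:

* **Coarse places** contain other places. An arc between a coarse place and a
  transition is a macro: it stands for one arc (same multiplicity) per leaf
  place contained in it, recursively. Coarse places hold no tokens themselves.
* **Nested transitions** contain a whole sub-net, as a way of organising a
  large model. Flattening replaces the container transition by the contents of
  its nested net, with inner ids prefixed ``"container::inner"``; an inner
  place whose id equals an outer place id is treated as the *same* place
  (boundary unification).

:func:`flatten` removes both mechanisms; simulation-facing operations
(:func:`enabled`, :func:`fire`, matrix conversion) require a flat net.

The namespace separator ``"::"`` is reserved for flattening and composition;
user-facing constructors reject ids containing it.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .errors import (
    DisabledFireError,
    EmptyCoarsePlaceError,
    IdentityCollisionError,
    MustFlattenError,
    ValidationError,
)

__all__ = [
    "Place",
    "Transition",
    "Arc",
    "PetriNet",
    "NAMESPACE_SEPARATOR",
    "net_validate",
    "flatten",
    "enabled",
    "fire",
    "initial_marking",
]

NAMESPACE_SEPARATOR = "::"

Marking = dict[str, int]


@dataclass
class Place:
    """A quantifiable entity. ``contained`` non-empty makes it a coarse place."""

    id: str
    label: str = ""
    initial_tokens: int = 0
    contained: list[str] = field(default_factory=list)
    references: list[str] = field(default_factory=list)

    @property
    def is_coarse(self) -> bool:
        return bool(self.contained)


@dataclass
class Transition:
    """An action moving tokens; ``rate_constant`` is the stochastic rate c_j
    (1/time under the mass-action convention). ``nested`` holds an
    organisational sub-net."""

    id: str
    label: str = ""
    rate_constant: float = 1.0
    nested: "PetriNet | None" = None
    references: list[str] = field(default_factory=list)


@dataclass
class Arc:
    """Directed place<->transition connection with stoichiometric weight."""

    source: str
    target: str
    multiplicity: int = 1


@dataclass
class PetriNet:
    name: str = ""
    description: str = ""
    places: dict[str, Place] = field(default_factory=dict)
    transitions: dict[str, Transition] = field(default_factory=dict)
    arcs: list[Arc] = field(default_factory=list)

    # -- construction ------------------------------------------------------

    def add_place(self, place: Place) -> "PetriNet":
        _check_user_id(place.id)
        self._check_free(place.id)
        self.places[place.id] = place
        return self

    def add_transition(self, transition: Transition) -> "PetriNet":
        _check_user_id(transition.id)
        self._check_free(transition.id)
        self.transitions[transition.id] = transition
        return self

    def add_arc(self, source: str, target: str, multiplicity: int = 1) -> "PetriNet":
        self.arcs.append(Arc(source, target, multiplicity))
        return self

    def _check_free(self, element_id: str) -> None:
        if element_id in self.places or element_id in self.transitions:
            raise IdentityCollisionError(f"id {element_id!r} already in use")

    # -- queries -----------------------------------------------------------

    @property
    def is_flat(self) -> bool:
        return not any(p.is_coarse for p in self.places.values()) and not any(
            t.nested is not None for t in self.transitions.values()
        )

    def leaf_places(self) -> list[Place]:
        return [p for p in self.places.values() if not p.is_coarse]

    def leaves_of(self, place_id: str) -> list[str]:
        """Leaf place ids under ``place_id`` (itself, if it is a leaf)."""
        place = self.places[place_id]
        if not place.is_coarse:
            return [place_id]
        leaves: list[str] = []
        for child in place.contained:
            leaves.extend(self.leaves_of(child))
        return leaves


def _check_user_id(element_id: str) -> None:
    if not element_id:
        raise ValidationError("element id must be non-empty")
    if NAMESPACE_SEPARATOR in element_id:
        raise ValidationError(
            f"id {element_id!r} contains reserved separator {NAMESPACE_SEPARATOR!r}"
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def net_validate(net: PetriNet) -> list[str]:
    """Report every invariant violation; an empty list means the net is valid."""
    problems: list[str] = []
    for pid, place in net.places.items():
        if pid in net.transitions:
            problems.append(f"id {pid!r} used for both a place and a transition")
        if not isinstance(place.initial_tokens, int) or place.initial_tokens < 0:
            problems.append(f"place {pid!r}: initial_tokens must be an integer >= 0")
        for child in place.contained:
            if child not in net.places:
                problems.append(f"coarse place {pid!r} contains unknown place {child!r}")
    for tid, transition in net.transitions.items():
        if transition.rate_constant <= 0:
            problems.append(f"transition {tid!r}: rate_constant must be > 0")
        if transition.nested is not None:
            problems.extend(
                f"nested net of {tid!r}: {p}" for p in net_validate(transition.nested)
            )
    problems.extend(_containment_problems(net))
    for k, arc in enumerate(net.arcs):
        src_place = arc.source in net.places
        src_trans = arc.source in net.transitions
        tgt_place = arc.target in net.places
        tgt_trans = arc.target in net.transitions
        if not (src_place or src_trans):
            problems.append(f"arc #{k}: unknown source {arc.source!r}")
        elif not (tgt_place or tgt_trans):
            problems.append(f"arc #{k}: unknown target {arc.target!r}")
        elif src_place == tgt_place:
            kind = "place-place" if src_place else "transition-transition"
            problems.append(
                f"arc #{k} ({arc.source!r} -> {arc.target!r}): {kind} arc "
                "violates bipartiteness"
            )
        if not isinstance(arc.multiplicity, int) or arc.multiplicity < 1:
            problems.append(f"arc #{k}: multiplicity must be an integer >= 1")
    return problems


def _containment_problems(net: PetriNet) -> list[str]:
    problems: list[str] = []
    parent: dict[str, str] = {}
    for pid, place in net.places.items():
        for child in place.contained:
            if child in parent:
                problems.append(
                    f"place {child!r} contained in both {parent[child]!r} and {pid!r}"
                )
            else:
                parent[child] = pid
    # cycle check: walk up the parent chain from every place
    for pid in net.places:
        seen = {pid}
        cur = pid
        while cur in parent:
            cur = parent[cur]
            if cur in seen:
                problems.append(f"containment cycle through place {pid!r}")
                break
            seen.add(cur)
    return problems


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------

def flatten(net: PetriNet) -> PetriNet:
    """Expand coarse places and nested transitions into a plain flat net.

    The result has the same leaf places (same ids, same initial tokens) and is
    idempotent: flattening a flat net is the identity up to deep copy.
    """
    problems = net_validate(net)
    if problems:
        raise ValidationError("cannot flatten an invalid net: " + "; ".join(problems))
    expanded = _expand_nested_transitions(net)
    return _expand_coarse_places(expanded)


def _expand_nested_transitions(net: PetriNet) -> PetriNet:
    out = PetriNet(name=net.name, description=net.description)
    out.places = {pid: copy.deepcopy(p) for pid, p in net.places.items()}
    out.arcs = [copy.deepcopy(a) for a in net.arcs]
    for tid, transition in net.transitions.items():
        if transition.nested is None:
            out.transitions[tid] = copy.deepcopy(transition)
            continue
        # container transitions are organisational only: they vanish, so any
        # arc attached to one has no defined meaning
        attached = [a for a in out.arcs if tid in (a.source, a.target)]
        if attached:
            raise ValidationError(
                f"container transition {tid!r} has {len(attached)} attached arc(s); "
                "connect the inner net's own places/transitions instead"
            )
        inner = _expand_coarse_places(_expand_nested_transitions(transition.nested))
        rename: dict[str, str] = {}
        for pid, place in inner.places.items():
            if pid in out.places:
                rename[pid] = pid  # boundary unification with the outer place
                continue
            if pid in net.transitions:
                raise IdentityCollisionError(
                    f"nested place {pid!r} collides with outer transition id"
                )
            new_id = f"{tid}{NAMESPACE_SEPARATOR}{pid}"
            if new_id in out.places or new_id in out.transitions:
                raise IdentityCollisionError(f"id collision after prefixing: {new_id!r}")
            rename[pid] = new_id
            prefixed = copy.deepcopy(place)
            prefixed.id = new_id
            out.places[new_id] = prefixed
        for inner_tid, inner_transition in inner.transitions.items():
            new_id = f"{tid}{NAMESPACE_SEPARATOR}{inner_tid}"
            if new_id in out.places or new_id in out.transitions:
                raise IdentityCollisionError(f"id collision after prefixing: {new_id!r}")
            rename[inner_tid] = new_id
            prefixed_t = copy.deepcopy(inner_transition)
            prefixed_t.id = new_id
            out.transitions[new_id] = prefixed_t
        for arc in inner.arcs:
            out.arcs.append(Arc(rename[arc.source], rename[arc.target], arc.multiplicity))
    return out


def _expand_coarse_places(net: PetriNet) -> PetriNet:
    out = PetriNet(name=net.name, description=net.description)
    out.places = {p.id: copy.deepcopy(p) for p in net.leaf_places()}
    out.transitions = {tid: copy.deepcopy(t) for tid, t in net.transitions.items()}
    merged: dict[tuple[str, str], int] = {}
    order: list[tuple[str, str]] = []
    for arc in net.arcs:
        if arc.source in net.places:
            place_end, transition_end, place_is_source = arc.source, arc.target, True
        else:
            place_end, transition_end, place_is_source = arc.target, arc.source, False
        leaves = net.leaves_of(place_end)
        if not leaves:
            raise EmptyCoarsePlaceError(
                f"coarse place {place_end!r} expands to zero leaf places"
            )
        for leaf in leaves:
            key = (leaf, transition_end) if place_is_source else (transition_end, leaf)
            if key not in merged:
                merged[key] = 0
                order.append(key)
            merged[key] += arc.multiplicity
    for source, target in order:
        out.arcs.append(Arc(source, target, merged[(source, target)]))
    return out


# ---------------------------------------------------------------------------
# Firing semantics
# ---------------------------------------------------------------------------

def _require_flat(net: PetriNet) -> None:
    if not net.is_flat:
        raise MustFlattenError("operation requires a flat net; call flatten() first")


def input_arcs(net: PetriNet, transition_id: str) -> dict[str, int]:
    """Pre multiplicities of a transition (summing duplicate arcs)."""
    pre: dict[str, int] = {}
    for arc in net.arcs:
        if arc.target == transition_id and arc.source in net.places:
            pre[arc.source] = pre.get(arc.source, 0) + arc.multiplicity
    return pre


def output_arcs(net: PetriNet, transition_id: str) -> dict[str, int]:
    """Post multiplicities of a transition (summing duplicate arcs)."""
    post: dict[str, int] = {}
    for arc in net.arcs:
        if arc.source == transition_id and arc.target in net.places:
            post[arc.target] = post.get(arc.target, 0) + arc.multiplicity
    return post


def enabled(net: PetriNet, marking: Marking) -> set[str]:
    """Transitions whose every input place holds at least the arc multiplicity."""
    _require_flat(net)
    result: set[str] = set()
    for tid in net.transitions:
        pre = input_arcs(net, tid)
        if all(marking.get(pid, 0) >= k for pid, k in pre.items()):
            result.add(tid)
    return result


def fire(net: PetriNet, marking: Marking, transition_id: str) -> Marking:
    """Fire one transition: new[p] = old[p] - Pre(p,t) + Post(p,t)."""
    _require_flat(net)
    if transition_id not in net.transitions:
        raise DisabledFireError(f"unknown transition {transition_id!r}")
    if transition_id not in enabled(net, marking):
        raise DisabledFireError(f"transition {transition_id!r} is not enabled")
    new_marking = dict(marking)
    for pid, k in input_arcs(net, transition_id).items():
        new_marking[pid] = new_marking.get(pid, 0) - k
    for pid, k in output_arcs(net, transition_id).items():
        new_marking[pid] = new_marking.get(pid, 0) + k
    return new_marking


def initial_marking(net: PetriNet) -> Marking:
    """Marking over the leaf places, from each place's initial token count."""
    return {p.id: p.initial_tokens for p in net.leaf_places()}


def structurally_equal(a: PetriNet, b: PetriNet) -> bool:
    """Same places (id, tokens, containment), transitions (id, rate) and arc
    multiset, ignoring element order."""
    if set(a.places) != set(b.places) or set(a.transitions) != set(b.transitions):
        return False
    for pid in a.places:
        pa, pb = a.places[pid], b.places[pid]
        if pa.initial_tokens != pb.initial_tokens or sorted(pa.contained) != sorted(pb.contained):
            return False
    for tid in a.transitions:
        if a.transitions[tid].rate_constant != b.transitions[tid].rate_constant:
            return False
    arcs_a = sorted((x.source, x.target, x.multiplicity) for x in a.arcs)
    arcs_b = sorted((x.source, x.target, x.multiplicity) for x in b.arcs)
    return arcs_a == arcs_b
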