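"""Biological interaction graphs.

Nodes are biological entities (genes, proteins, molecules...) and may contain a
nested sub-network; edges are directed or undirected, carry a free-text type
(e.g. ``"physical"``, ``"genetic"``) and a list of literature references
(typically PubMed identifiers). Two edges with the same endpoints (unordered
for undirected edges), the same direction and the same type are considered the
*same* piece of evidence-bearing structure: adding one merges reference lists
instead of duplicating the edge.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

from .errors import DanglingEdgeError, IdentityCollisionError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["GraphNode", "GraphEdge", "InteractionGraph"]


@dataclass
class GraphNode:
    """A biological entity; may itself contain a nested network."""

    id: str
    label: str = ""
    entity_kind: str = ""
    nested: "InteractionGraph | None" = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.id:
            raise ValidationError("node id must be non-empty")


@dataclass
class GraphEdge:
    """A typed, reference-annotated interaction between two nodes."""

    source: str
    target: str
    directed: bool = False
    edge_type: str = "physical"
    references: list[str] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for r in self.references:
            if not r:
                raise ValidationError("edge references must be non-empty strings")

    def identity(self) -> tuple:
        """Identity key used for duplicate collapse.

        Undirected edges are unordered pairs: (a, b) and (b, a) collide.
        """
        if self.directed:
            ends: tuple = (self.source, self.target)
        else:
            ends = tuple(sorted((self.source, self.target)))
        return (ends, self.directed, self.edge_type)


@dataclass
class InteractionGraph:
    """A named interaction network: unique nodes plus collapsed typed edges."""

    name: str = ""
    description: str = ""
    nodes: dict[str, GraphNode] = field(default_factory=dict)
    edges: list[GraphEdge] = field(default_factory=list)

    # -- construction ------------------------------------------------------

    def add_node(self, node: GraphNode) -> "InteractionGraph":
        if node.id in self.nodes:
            raise IdentityCollisionError(f"node id {node.id!r} already present")
        self.nodes[node.id] = node
        return self

    def add_edge(self, edge: GraphEdge) -> "InteractionGraph":
        for endpoint in (edge.source, edge.target):
            if endpoint not in self.nodes:
                raise DanglingEdgeError(
                    f"edge ({edge.source!r}, {edge.target!r}) references "
                    f"unknown node {endpoint!r}"
                )
        existing = self._find_edge(edge.identity())
        if existing is not None:
            _merge_references(existing, edge.references)
            for k, v in edge.attributes.items():
                existing.attributes.setdefault(k, v)
        else:
            self.edges.append(edge)
        return self

    def _find_edge(self, identity: tuple) -> GraphEdge | None:
        for e in self.edges:
            if e.identity() == identity:
                return e
        return None

    # -- queries -----------------------------------------------------------

    def node_count(self) -> int:
        return len(self.nodes)

    def edge_count(self) -> int:
        return len(self.edges)

    def validate(self) -> list[str]:
        """Return human-readable invariant violations (empty list == valid)."""
        problems: list[str] = []
        for node_id, node in self.nodes.items():
            if not node_id:
                problems.append("empty node id")
            if node.id != node_id:
                problems.append(f"node keyed {node_id!r} has id {node.id!r}")
            if node.nested is not None:
                problems.extend(
                    f"nested graph of {node_id!r}: {p}" for p in node.nested.validate()
                )
        seen: set[tuple] = set()
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                problems.append(f"dangling edge ({e.source!r}, {e.target!r})")
            key = e.identity()
            if key in seen:
                problems.append(f"duplicate edge {key!r} not collapsed")
            seen.add(key)
            for r in e.references:
                if not r:
                    problems.append(f"empty reference on edge {key!r}")
        return problems

    # -- merging -----------------------------------------------------------

    def merge(self, other: "InteractionGraph") -> "InteractionGraph":
        """Union of two graphs: nodes by id, edges with duplicate collapse.

        Attributes of ``self`` win on node conflicts; each conflict is logged
        as a warning, never an error. The inputs are left untouched.
        """
        result = copy.deepcopy(self)
        for node_id, node in other.nodes.items():
            if node_id in result.nodes:
                ours = result.nodes[node_id]
                for k, v in node.attributes.items():
                    if k in ours.attributes and ours.attributes[k] != v:
                        logger.warning(
                            "node %r attribute %r conflict: keeping %r, dropping %r",
                            node_id, k, ours.attributes[k], v,
                        )
                    else:
                        ours.attributes.setdefault(k, v)
                if ours.nested is None and node.nested is not None:
                    ours.nested = copy.deepcopy(node.nested)
            else:
                result.nodes[node_id] = copy.deepcopy(node)
        for e in other.edges:
            result.add_edge(copy.deepcopy(e))
        return result

    def structurally_equal(self, other: "InteractionGraph") -> bool:
        """Equality on node ids and collapsed edge content (order-insensitive)."""
        if set(self.nodes) != set(other.nodes):
            return False
        mine = {e.identity(): sorted(set(e.references)) for e in self.edges}
        theirs = {e.identity(): sorted(set(e.references)) for e in other.edges}
        return mine == theirs


def _merge_references(edge: GraphEdge, new_refs: list[str]) -> None:
    known = set(edge.references)
    for r in new_refs:
        if r not in known:
            edge.references.append(r)
            known.add(r)
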