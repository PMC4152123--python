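"""Seeded random model generators for property testing and validation runs.

All generators take a :class:`numpy.random.Generator` so callers control the
stream; the same generator state always yields the same object.
"""

from __future__ import annotations

import numpy as np

from .graph_model import GraphEdge, GraphNode, InteractionGraph
from .matrix_engine import MatrixBundle
from .petri_model import Arc, PetriNet, Place, Transition

__all__ = [
    "random_flat_net",
    "random_hierarchical_net",
    "random_flat_graph",
    "random_bundle",
    "random_conservative_bundle",
]


def random_flat_net(
    rng: np.random.Generator,
    max_places: int = 3,
    max_transitions: int = 3,
    max_multiplicity: int = 2,
    max_tokens: int = 3,
) -> PetriNet:
    """A small flat net with random arcs, multiplicities and markings."""
    n_places = int(rng.integers(1, max_places + 1))
    n_transitions = int(rng.integers(1, max_transitions + 1))
    net = PetriNet(name="random-flat")
    for i in range(n_places):
        net.add_place(Place(id=f"p{i}", initial_tokens=int(rng.integers(0, max_tokens + 1))))
    for j in range(n_transitions):
        net.add_transition(Transition(id=f"t{j}", rate_constant=float(rng.uniform(0.1, 2.0))))
    for i in range(n_places):
        for j in range(n_transitions):
            if rng.random() < 0.4:
                net.add_arc(f"p{i}", f"t{j}", int(rng.integers(1, max_multiplicity + 1)))
            if rng.random() < 0.4:
                net.add_arc(f"t{j}", f"p{i}", int(rng.integers(1, max_multiplicity + 1)))
    return net


def random_hierarchical_net(
    rng: np.random.Generator,
    max_depth: int = 3,
    n_leaves: int = 6,
    n_transitions: int = 3,
) -> PetriNet:
    """A net whose places form a random containment forest of bounded depth.

    Arcs are attached to random places at *any* level (leaf or coarse), so
    flattening exercises the replication semantics.
    """
    net = PetriNet(name="random-hierarchical")
    leaves = [f"p{i}" for i in range(n_leaves)]
    for pid in leaves:
        net.add_place(Place(id=pid, initial_tokens=int(rng.integers(0, 4))))
    # build coarse layers bottom-up: each layer groups some of the previous
    current = list(leaves)
    coarse_counter = 0
    for _ in range(int(rng.integers(1, max_depth))):
        if len(current) < 2:
            break
        next_layer: list[str] = []
        rng.shuffle(current)
        k = 0
        while k < len(current):
            group_size = int(rng.integers(1, 4))
            group = current[k:k + group_size]
            k += group_size
            if len(group) >= 2 and rng.random() < 0.7:
                cid = f"C{coarse_counter}"
                coarse_counter += 1
                net.add_place(Place(id=cid, contained=list(group)))
                next_layer.append(cid)
            else:
                next_layer.extend(group)
        current = next_layer
    for j in range(n_transitions):
        net.add_transition(Transition(id=f"t{j}", rate_constant=1.0))
    all_places = list(net.places)
    for j in range(n_transitions):
        for pid in rng.choice(all_places, size=min(2, len(all_places)), replace=False):
            mult = int(rng.integers(1, 3))
            if rng.random() < 0.5:
                net.add_arc(str(pid), f"t{j}", mult)
            else:
                net.add_arc(f"t{j}", str(pid), mult)
    return net


def random_flat_graph(
    rng: np.random.Generator,
    max_nodes: int = 8,
    edge_prob: float = 0.3,
) -> InteractionGraph:
    """A random interaction graph with mixed directed/undirected typed edges."""
    n = int(rng.integers(2, max_nodes + 1))
    graph = InteractionGraph(name="random-graph")
    for i in range(n):
        graph.add_node(GraphNode(
            id=f"g{i}",
            label=f"gene {i}",
            entity_kind=str(rng.choice(["gene", "protein", "molecule"])),
        ))
    types = ["physical", "genetic", "regulatory"]
    for i in range(n):
        for j in range(i, n):
            if rng.random() < edge_prob:
                refs = [f"PMID:{int(rng.integers(1, 99999))}"
                        for _ in range(int(rng.integers(0, 3)))]
                graph.add_edge(GraphEdge(
                    source=f"g{i}",
                    target=f"g{j}",
                    directed=bool(rng.random() < 0.5),
                    edge_type=str(rng.choice(types)),
                    references=refs,
                ))
    return graph


def random_bundle(
    rng: np.random.Generator,
    max_places: int = 4,
    max_transitions: int = 4,
) -> MatrixBundle:
    """A random valid matrix bundle (integer matrices, positive rates)."""
    p = int(rng.integers(1, max_places + 1))
    t = int(rng.integers(1, max_transitions + 1))
    pre = rng.integers(0, 3, size=(p, t))
    post = rng.integers(0, 3, size=(p, t))
    return MatrixBundle(
        place_ids=[f"p{i}" for i in range(p)],
        transition_ids=[f"t{j}" for j in range(t)],
        pre=pre,
        post=post,
        initial_marking=rng.integers(0, 5, size=p),
        rates=rng.uniform(0.1, 3.0, size=t),
    )


def random_conservative_bundle(
    rng: np.random.Generator,
    n_places: int = 4,
    n_transitions: int = 5,
    total_tokens: int = 12,
) -> MatrixBundle:
    """A bundle whose every transition conserves the total token count.

    Each transition moves k tokens from one place to another (column sums of
    the stoichiometry matrix are zero), so the total marking is invariant.
    """
    pre = np.zeros((n_places, n_transitions), dtype=np.int64)
    post = np.zeros_like(pre)
    for j in range(n_transitions):
        src, dst = rng.choice(n_places, size=2, replace=False)
        k = int(rng.integers(1, 3))
        pre[src, j] = k
        post[dst, j] = k
    m0 = rng.multinomial(total_tokens, np.full(n_places, 1.0 / n_places))
    return MatrixBundle(
        place_ids=[f"p{i}" for i in range(n_places)],
        transition_ids=[f"t{j}" for j in range(n_transitions)],
        pre=pre,
        post=post,
        initial_marking=m0,
        rates=rng.uniform(0.5, 2.0, size=n_transitions),
    )
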