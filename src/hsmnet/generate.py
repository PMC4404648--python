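"""Synthetic directed networks: planted command hierarchies, upward-edge
perturbations, and Erdős–Rényi G(n, m) digraphs.

The planted hierarchies emulate a military-style command structure: L
ranked levels, every edge pointing strictly downward, every
non-bottom officer commanding at least one subordinate in the level
directly below.  The default fixture is a 19-node, five-level tree
with level sizes (1, 2, 4, 5, 7) bottom-to-top order (7, 5, 4, 2, 1).
Perturbations inject new upward edges, the canonical way to erode a
perfect hierarchy while keeping the original command edges intact.
G(n, m) digraphs (m distinct ordered pairs sampled uniformly without
replacement) are the null model for hierarchy significance.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .network import DirectedNetwork
from .scoring import LevelAssignment

__all__ = [
    "PlantedHierarchy",
    "generate_perfect_hierarchy",
    "perturb_with_upward_edges",
    "generate_erdos_renyi",
    "DEFAULT_MILITARY_SIZES",
]

# bottom-to-top: 7 privates, ..., 1 commander — 19 nodes over 5 levels
DEFAULT_MILITARY_SIZES: tuple[int, ...] = (7, 5, 4, 2, 1)


@dataclass
class PlantedHierarchy:
    """A perfect hierarchy plus its ground-truth level assignment."""

    network: DirectedNetwork
    truth: LevelAssignment


def generate_perfect_hierarchy(level_sizes=DEFAULT_MILITARY_SIZES,
                               branching: str = "tree",
                               seed: int | None = None,
                               extra_edge_fraction: float = 1.0,
                               ) -> PlantedHierarchy:
    """Build a perfect L-level hierarchy with all edges downward.

    ``level_sizes`` is bottom-to-top (index 0 = level 1).  In ``tree``
    mode every non-top node has exactly one parent in the level above;
    in ``layered_random`` mode extra downward edges between adjacent
    levels are added on top of the tree, ``extra_edge_fraction`` times
    the node count of them (denser hierarchies keep their ER nulls
    cyclic, which sharpens significance tests).

    Every node of level i >= 2 is guaranteed at least one child at
    level i - 1 (each level must be at least as large as the one
    above it for this to be possible); with that guarantee the planted
    leveling is the unique all-downward assignment at L levels, so the
    probability matrix of a well-converged HSM run is one-hot at the
    truth.
    """
    sizes = [int(s) for s in level_sizes]
    if len(sizes) < 2:
        raise ValueError("need at least 2 levels")
    if any(s < 1 for s in sizes):
        raise ValueError("every level needs at least one node")
    if branching not in ("tree", "layered_random"):
        raise ValueError(f"unknown branching mode {branching!r}")
    for lower, upper in zip(sizes, sizes[1:]):
        if lower < upper:
            raise ValueError(
                "level sizes must be non-increasing bottom-to-top so every "
                "superior can command a distinct subordinate")
    rng = random.Random(seed)
    L = len(sizes)
    nodes: list[str] = []
    by_level: list[list[str]] = []
    for li, size in enumerate(sizes, start=1):
        level_nodes = [f"L{li}N{j}" for j in range(1, size + 1)]
        by_level.append(level_nodes)
        nodes.extend(level_nodes)
    levels = {n: li for li, lvl in enumerate(by_level, start=1) for n in lvl}

    edges: list[tuple[str, str]] = []
    for li in range(1, L):  # parents at level li+1, children at level li
        children = by_level[li - 1].copy()
        parents = by_level[li]
        rng.shuffle(children)
        # each parent commands one distinct child -> child invariant holds
        for parent, child in zip(parents, children):
            edges.append((parent, child))
        for child in children[len(parents):]:
            edges.append((rng.choice(parents), child))

    if branching == "layered_random":
        n_extra = round(extra_edge_fraction * len(nodes))
        existing = set(edges)
        candidates = [
            (p, c)
            for li in range(1, L)
            for p in by_level[li]
            for c in by_level[li - 1]
            if (p, c) not in existing
        ]
        rng.shuffle(candidates)
        edges.extend(candidates[:n_extra])

    net = DirectedNetwork(nodes, edges)
    return PlantedHierarchy(net, LevelAssignment(levels, L))


def perturb_with_upward_edges(ph: PlantedHierarchy, n_upward: int,
                              seed: int | None = None,
                              mode: str = "add") -> DirectedNetwork:
    """Inject ``n_upward`` random upward edges into a planted hierarchy.

    ``add`` mode (default) samples new edges u -> v with
    truth-level(u) < truth-level(v) uniformly among absent such pairs,
    keeping every original edge; ``reverse`` mode instead flips
    ``n_upward`` randomly chosen existing downward edges.
    """
    if n_upward < 0:
        raise ValueError("n_upward must be >= 0")
    net, truth = ph.network, ph.truth
    rng = random.Random(seed)
    if mode == "add":
        existing = set(net.edges)
        candidates = [
            (u, v)
            for u in net.nodes
            for v in net.nodes
            if truth.levels[u] < truth.levels[v] and (u, v) not in existing
        ]
        if n_upward > len(candidates):
            raise ValueError(
                f"only {len(candidates)} upward non-edges available, "
                f"{n_upward} requested")
        new_edges = rng.sample(candidates, n_upward)
        return DirectedNetwork(list(net.nodes), list(net.edges) + new_edges)
    if mode == "reverse":
        downward = [(u, v) for u, v in net.edges
                    if truth.levels[u] > truth.levels[v]]
        if n_upward > len(downward):
            raise ValueError("not enough downward edges to reverse")
        flipped = set(map(tuple, rng.sample(downward, n_upward)))
        edges = [(v, u) if (u, v) in flipped else (u, v) for u, v in net.edges]
        return DirectedNetwork(list(net.nodes), edges)
    raise ValueError(f"unknown mode {mode!r}")


def generate_erdos_renyi(n_nodes: int, n_edges: int,
                         allow_self_loops: bool = False,
                         seed: int | None = None) -> DirectedNetwork:
    """G(n, m): ``n_edges`` distinct ordered pairs, uniform without
    replacement.

    Pair indices are drawn with :func:`random.Random.sample` over the
    flattened ordered-pair space, so every admissible edge set is
    equally likely.
    """
    if n_nodes < 1:
        raise ValueError("need at least one node")
    n_pairs = n_nodes * n_nodes if allow_self_loops else n_nodes * (n_nodes - 1)
    if n_edges > n_pairs:
        raise ValueError(f"{n_edges} edges infeasible: only {n_pairs} "
                         "ordered pairs available")
    rng = random.Random(seed)
    nodes = [f"v{i}" for i in range(n_nodes)]
    picks = rng.sample(range(n_pairs), n_edges)
    edges = []
    for p in picks:
        if allow_self_loops:
            u, v = divmod(p, n_nodes)
        else:
            u, r = divmod(p, n_nodes - 1)
            v = r if r < u else r + 1
        edges.append((nodes[u], nodes[v]))
    return DirectedNetwork(nodes, edges)
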