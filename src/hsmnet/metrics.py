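"""Reachability-based asymmetry and hierarchy metrics.

Dyadic reciprocity and the Krackhardt hierarchy score quantify how
*asymmetric* a directed network is — whether node pairs are mutually
reachable — while global reaching centrality (GRC) quantifies how
unevenly reach is distributed over nodes.  None of them carries the
top-to-bottom orientation that a leveled hierarchy does; they are the
standard points of comparison for the HS/CHS scores.

Reachability here means a directed path of length >= 1; a node does
not reach itself unless it lies on a cycle.  Self-loops are ignored.
The reciprocity/Krackhardt denominator is the set of unordered pairs
connected in at least one direction (the sna-style
connectedness-conditioned convention); raw fractions over all pairs
are exposed alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import DirectedNetwork

__all__ = [
    "ReciprocityResult",
    "reachability_matrix",
    "dyadic_reciprocity",
    "krackhardt_hierarchy",
    "global_reaching_centrality",
    "summarize_metrics",
]


@dataclass(frozen=True)
class ReciprocityResult:
    reciprocity: float          # both directions / connected pairs
    one_minus_dr: float         # 1 - reciprocity
    krackhardt: float           # exactly one direction / connected pairs
    n_connected_pairs: int
    n_symmetric_pairs: int
    n_pairs: int
    # unconditioned companions (denominator = all unordered pairs)
    reciprocity_all_pairs: float
    krackhardt_all_pairs: float


def reachability_matrix(net: DirectedNetwork) -> np.ndarray:
    """Boolean matrix R[i, j]: j reachable from i via a path of length
    >= 1 (diagonal true only for nodes on a cycle)."""
    g = nx.DiGraph()
    g.add_nodes_from(range(net.n_nodes))
    idx = net.node_index()
    g.add_edges_from((idx[u], idx[v]) for u, v in net.edges if u != v)
    n = net.n_nodes
    reach = np.zeros((n, n), dtype=bool)
    for i in range(n):
        desc = nx.descendants(g, i)
        for j in desc:
            reach[i, j] = True
    return reach


def _pair_counts(net: DirectedNetwork) -> tuple[int, int, int, int]:
    reach = reachability_matrix(net)
    either = reach | reach.T
    both = reach & reach.T
    iu = np.triu_indices(net.n_nodes, k=1)
    n_connected = int(either[iu].sum())
    n_symmetric = int(both[iu].sum())
    n_pairs = net.n_nodes * (net.n_nodes - 1) // 2
    n_one_way = n_connected - n_symmetric
    return n_connected, n_symmetric, n_one_way, n_pairs


def _reciprocity_result(net: DirectedNetwork) -> ReciprocityResult:
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    n_connected, n_symmetric, n_one_way, n_pairs = _pair_counts(net)
    if n_connected == 0:
        raise ValueError("no reachable node pair: reciprocity undefined")
    dr = n_symmetric / n_connected
    return ReciprocityResult(
        reciprocity=dr,
        one_minus_dr=1.0 - dr,
        krackhardt=n_one_way / n_connected,
        n_connected_pairs=n_connected,
        n_symmetric_pairs=n_symmetric,
        n_pairs=n_pairs,
        reciprocity_all_pairs=n_symmetric / n_pairs,
        krackhardt_all_pairs=n_one_way / n_pairs,
    )


def dyadic_reciprocity(net: DirectedNetwork) -> ReciprocityResult:
    """Fraction of connected unordered pairs reachable in both
    directions, with the ``1 - DR`` companion reported in network
    comparisons."""
    return _reciprocity_result(net)


def krackhardt_hierarchy(net: DirectedNetwork) -> float:
    """Fraction of connected unordered pairs reachable in exactly one
    direction (1 on any DAG)."""
    return _reciprocity_result(net).krackhardt


def global_reaching_centrality(net: DirectedNetwork) -> float:
    """GRC = sum_i (C_R^max - C_R(i)) / (N - 1), where C_R(i) is the
    fraction of other nodes reachable from i.  1 for an out-star, 0
    when every node reaches the same share."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("GRC needs at least 2 nodes")
    reach = reachability_matrix(net)
    np.fill_diagonal(reach, False)  # local reach counts *other* nodes
    local = reach.sum(axis=1) / (n - 1)
    return float((local.max() - local).sum() / (n - 1))


def summarize_metrics(net: DirectedNetwork) -> dict[str, float]:
    """The metric triple used for cross-network comparison tables."""
    rec = _reciprocity_result(net)
    return {
        "one_minus_dr": rec.one_minus_dr,
        "khs": rec.krackhardt,
        "grc": global_reaching_centrality(net),
    }
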