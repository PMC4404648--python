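"""Directed-network container and file I/O.

Networks are unweighted directed graphs over opaque string node
identifiers.  Duplicate edges are collapsed on load (the hierarchy
scores are defined on binary interaction sets); self-loops are legal
and preserved — in a phosphorylation network they are the
auto-phosphorylation interactions.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["DirectedNetwork", "read_network", "write_results"]


@dataclass
class DirectedNetwork:
    """An unweighted directed graph with ordered string nodes.

    Parameters
    ----------
    nodes : sequence of str
        Node identifiers in a stable order (defines row order of every
        derived matrix).  Case-sensitive opaque strings.
    edges : sequence of (str, str)
        Directed edges ``source -> target``.  Self-loops allowed.
        Duplicates are collapsed; the number removed is logged.
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    n_duplicates_removed: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        seen_nodes: dict[str, None] = dict.fromkeys(self.nodes)
        self.nodes = list(seen_nodes)
        node_set = set(self.nodes)
        deduped: dict[tuple[str, str], None] = {}
        dups = 0
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not in node set: {(u, v)!r}")
            if (u, v) in deduped:
                dups += 1
            else:
                deduped[(u, v)] = None
        if dups:
            logger.warning("collapsed %d duplicate edge(s)", dups)
        self.edges = list(deduped)
        self.n_duplicates_removed = dups

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   extra_nodes: Iterable[str] = ()) -> "DirectedNetwork":
        edges = [(str(u), str(v)) for u, v in edges]
        nodes: dict[str, None] = {}
        for u, v in edges:
            nodes.setdefault(u)
            nodes.setdefault(v)
        for n in extra_nodes:
            nodes.setdefault(str(n))
        return cls(list(nodes), edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def self_loops(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v in self.edges if u == v]

    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedNetwork":
        return cls([str(n) for n in g.nodes], [(str(u), str(v)) for u, v in g.edges])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DirectedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


class NetworkParseError(ValueError):
    """Raised when an input file cannot be parsed as a directed network."""


def _parse_edgelist(path: str) -> DirectedNetwork:
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) != 2:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            edges.append((parts[0], parts[1]))
    return DirectedNetwork.from_edges(edges)


def _parse_sif(path: str) -> DirectedNetwork:
    # SIF: "source relation target [target2 ...]"; a lone token is an
    # isolated node declaration.
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            parts = [p for p in parts if p]
            if len(parts) == 1:
                isolated.append(parts[0])
            elif len(parts) >= 3:
                src = parts[0]
                for tgt in parts[2:]:
                    edges.append((src, tgt))
            else:
                raise NetworkParseError(
                    f"{path}:{lineno}: SIF line needs 1 or >=3 columns"
                )
    return DirectedNetwork.from_edges(edges, extra_nodes=isolated)


def read_network(path: str, format: str | None = None) -> DirectedNetwork:
    """Read a directed network from ``edgelist``, ``sif`` or ``graphml``.

    ``format=None`` infers from the file extension (``.sif``,
    ``.graphml``/``.xml``; anything else is treated as a two-column
    edge list).  Empty networks are rejected.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {"sif": "sif", ".sif": "sif",
                  ".graphml": "graphml", ".xml": "graphml"}.get(ext, "edgelist")
    if format == "edgelist":
        net = _parse_edgelist(path)
    elif format == "sif":
        net = _parse_sif(path)
    elif format == "graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as exc:  # noqa: BLE001 - surface parser detail
            raise NetworkParseError(f"{path}: invalid GraphML: {exc}") from exc
        if not g.is_directed():
            g = g.to_directed()
        net = DirectedNetwork.from_networkx(g)
    else:
        raise ValueError(f"unknown format {format!r}")
    if net.n_nodes == 0:
        raise NetworkParseError(f"{path}: empty network")
    return net


def write_network(net: DirectedNetwork, path: str, format: str = "edgelist") -> None:
    """Write a network back out (edge list, SIF, or GraphML)."""
    if format == "edgelist":
        with open(path, "w") as fh:
            for u, v in net.edges:
                fh.write(f"{u}\t{v}\n")
    elif format == "sif":
        with open(path, "w") as fh:
            with_edge = {u for u, _ in net.edges} | {v for _, v in net.edges}
            for u, v in net.edges:
                fh.write(f"{u}\tdirected\t{v}\n")
            for n in net.nodes:
                if n not in with_edge:
                    fh.write(f"{n}\n")
    elif format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_results(result, out_dir: str) -> dict[str, str]:
    """Write a :class:`~hsmnet.hsm.HierarchyResult` to ``out_dir``.

    Emits three files and returns their paths:

    * ``levels.tsv`` — node, assigned_level, max_probability
    * ``probability_matrix.tsv`` — node x level assignment frequencies
    * ``scores.json`` — HS/CHS/PHS, level count, significance and run
      metadata (seed, steps, runs)
    """
    os.makedirs(out_dir, exist_ok=True)
    pm = result.probability_matrix
    levels_path = os.path.join(out_dir, "levels.tsv")
    with open(levels_path, "w") as fh:
        fh.write("node\tassigned_level\tmax_probability\n")
        for node in pm.nodes:
            lvl = result.best_assignment.levels[node]
            fh.write(f"{node}\t{lvl}\t{pm.probs[pm.node_index[node], lvl - 1]:.10g}\n")
    pm_path = os.path.join(out_dir, "probability_matrix.tsv")
    with open(pm_path, "w") as fh:
        header = "\t".join(["node"] + [f"level_{i}" for i in range(1, pm.n_levels + 1)])
        fh.write(header + "\n")
        for node in pm.nodes:
            row = pm.probs[pm.node_index[node]]
            fh.write("\t".join([node] + [f"{p:.10g}" for p in row]) + "\n")
    scores_path = os.path.join(out_dir, "scores.json")
    payload = {
        "n_levels": pm.n_levels,
        "n_runs": pm.n_runs,
        "hs": _score_json(result.hs),
        "chs": _score_json(result.chs),
        "phs": _score_json(result.phs),
        "metadata": dict(result.metadata),
    }
    if result.significance is not None:
        payload["significance"] = result.significance.to_dict()
    with open(scores_path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    return {"levels": levels_path, "probability_matrix": pm_path,
            "scores": scores_path}


def _score_json(score) -> dict:
    return {
        "value": None if not score.is_finite else float(score),
        "infinite": not score.is_finite,
        "numerator": float(score.numerator),
        "denominator": float(score.denominator),
    }


def read_probability_matrix(path: str):
    """Re-read a probability-matrix TSV written by :func:`write_results`."""
    import numpy as np

    from .scoring import ProbabilityMatrix

    nodes, rows = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_levels = len(header) - 1
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            nodes.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return ProbabilityMatrix(nodes=nodes, probs=np.array(rows), n_levels=n_levels,
                             n_runs=0)
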