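"""Edge classification and the hierarchy scores HS, CHS and PHS.

A leveled directed network has three edge classes: *downward* edges
point from a higher level to a lower one, *upward* edges from a lower
level to a higher one, and *horizontal* edges connect two nodes in the
same level (self-loops included).  Levels are indexed bottom-up: level
``i`` is above level ``j`` iff ``i > j``.

The hierarchy score of an assignment is

    HS = (N_d + N_h) / (N_u + N_h)

with ``N_d``, ``N_u``, ``N_h`` the downward / upward / horizontal edge
counts; it equals +inf when ``N_u = N_h = 0`` (a perfect hierarchy).
The corrected score CHS divides each observed count by its expectation
under random placement given the level sizes, making values comparable
across level counts and across networks; the probabilistic score PHS
replaces hard counts with per-edge class probabilities under a
node-level probability matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import DirectedNetwork

__all__ = [
    "ScoreValue",
    "LevelAssignment",
    "EdgeClassCounts",
    "ProbabilityMatrix",
    "classify_edges",
    "hierarchy_score",
    "expected_edge_counts",
    "corrected_hierarchy_score",
    "probabilistic_hierarchy_score",
]


@dataclass(frozen=True, eq=False)
class ScoreValue:
    """A ratio score kept as an exact numerator/denominator pair.

    ``value = numerator / denominator``; when the denominator is zero
    and the numerator positive the score is +inf.  Comparisons are done
    by cross-multiplication so that integer-count scores (HS) compare
    exactly and +inf never enters float arithmetic.
    """

    numerator: float
    denominator: float

    def __post_init__(self) -> None:
        if self.denominator < 0 or self.numerator < 0:
            raise ValueError("score terms must be non-negative")
        if self.denominator == 0 and self.numerator == 0:
            raise ValueError("indeterminate score 0/0")

    @property
    def is_finite(self) -> bool:
        return self.denominator > 0

    def __float__(self) -> float:
        return self.numerator / self.denominator if self.denominator else math.inf

    # ordering via cross-multiplication; inf == inf, inf > finite
    def _cmp(self, other: "ScoreValue") -> int:
        lhs = self.numerator * other.denominator
        rhs = other.numerator * self.denominator
        return (lhs > rhs) - (lhs < rhs)

    def __lt__(self, other): return self._cmp(other) < 0
    def __le__(self, other): return self._cmp(other) <= 0
    def __gt__(self, other): return self._cmp(other) > 0
    def __ge__(self, other): return self._cmp(other) >= 0

    def __eq__(self, other):
        if not isinstance(other, ScoreValue):
            return NotImplemented
        return self._cmp(other) == 0

    def __hash__(self):
        return hash(float(self))

    def __repr__(self) -> str:
        return f"ScoreValue({float(self):g})"


@dataclass
class LevelAssignment:
    """Map node -> level in ``1..n_levels`` (1 = bottom, top = n_levels)."""

    levels: dict[str, int]
    n_levels: int

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("a hierarchy needs at least 2 levels")
        bad = {n: l for n, l in self.levels.items()
               if not (1 <= int(l) <= self.n_levels)}
        if bad:
            raise ValueError(f"levels out of range 1..{self.n_levels}: {bad}")
        self.levels = {n: int(l) for n, l in self.levels.items()}

    def level_sizes(self) -> list[int]:
        """Node count per level, index 0 = level 1 (bottom)."""
        sizes = [0] * self.n_levels
        for lvl in self.levels.values():
            sizes[lvl - 1] += 1
        return sizes

    def as_array(self, nodes: Sequence[str]) -> np.ndarray:
        return np.array([self.levels[n] for n in nodes], dtype=int)


@dataclass(frozen=True)
class EdgeClassCounts:
    n_down: int
    n_up: int
    n_horizontal: int

    def __post_init__(self) -> None:
        if min(self.n_down, self.n_up, self.n_horizontal) < 0:
            raise ValueError("edge counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_down + self.n_up + self.n_horizontal


@dataclass
class ProbabilityMatrix:
    """Per-node level-assignment frequencies over ``n_runs`` runs.

    ``probs[i, l-1]`` is the probability that node ``nodes[i]`` sits at
    level ``l``.  Rows sum to 1; when built by count aggregation every
    entry is a multiple of ``1 / n_runs`` (``n_runs = 0`` marks a
    matrix of unknown provenance, e.g. re-read from disk).
    """

    nodes: list[str]
    probs: np.ndarray
    n_levels: int
    n_runs: int
    node_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.nodes), self.n_levels):
            raise ValueError("probability matrix shape mismatch")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative probability")
        rows = self.probs.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("probability rows must sum to 1")
        self.node_index = {n: i for i, n in enumerate(self.nodes)}

    @classmethod
    def from_counts(cls, nodes: Sequence[str], counts: np.ndarray,
                    n_runs: int) -> "ProbabilityMatrix":
        counts = np.asarray(counts)
        if counts.sum(axis=1).tolist() != [n_runs] * len(nodes):
            raise ValueError("each row of counts must sum to n_runs")
        return cls(list(nodes), counts / float(n_runs), counts.shape[1], n_runs)

    def row(self, node: str) -> np.ndarray:
        return self.probs[self.node_index[node]]


def classify_edges(net: DirectedNetwork, asg: LevelAssignment) -> EdgeClassCounts:
    """Count downward / upward / horizontal edges under an assignment.

    Self-loops are horizontal (both endpoints share a level by
    definition).  Raises if a network node is missing from ``asg``.
    """
    levels = asg.levels
    missing = [n for n in net.nodes if n not in levels]
    if missing:
        raise ValueError(f"nodes without a level: {missing[:5]}")
    nd = nu = nh = 0
    for u, v in net.edges:
        lu, lv = levels[u], levels[v]
        if lu > lv:
            nd += 1
        elif lu < lv:
            nu += 1
        else:
            nh += 1
    return EdgeClassCounts(nd, nu, nh)


def hierarchy_score(counts: EdgeClassCounts) -> ScoreValue:
    """HS = (N_d + N_h) / (N_u + N_h); +inf for a perfect hierarchy."""
    if counts.total == 0:
        raise ValueError("hierarchy score undefined for an edgeless network")
    return ScoreValue(counts.n_down + counts.n_horizontal,
                      counts.n_up + counts.n_horizontal)


def expected_edge_counts(level_sizes: Sequence[int]) -> tuple[int, int, int]:
    """Expected (E_d, E_u, E_h) edge-slot counts for given level sizes.

    E_d = sum_{i>j} S_i S_j, E_u = sum_{i<j} S_i S_j, E_h = sum_i S_i^2
    — the number of ordered node pairs in each class, i.e. the class
    sizes a uniformly random edge placement would be proportional to.
    Empty levels contribute zero.
    """
    sizes = [int(s) for s in level_sizes]
    if any(s < 0 for s in sizes):
        raise ValueError("level sizes must be non-negative")
    total = sum(sizes)
    cross = (total * total - sum(s * s for s in sizes)) // 2
    e_h = sum(s * s for s in sizes)
    return cross, cross, e_h


def corrected_hierarchy_score(counts: EdgeClassCounts,
                              level_sizes: Sequence[int]) -> ScoreValue:
    """CHS = [O_d/E_d + O_h/E_h] / [O_u/E_u + O_h/E_h].

    Each observed count is normalized by its expectation under random
    edge placement; a random assignment therefore scores about 1 and a
    perfect hierarchy +inf.  A class with ``E = 0`` must have ``O = 0``
    (its term contributes 0); ``E = 0`` with ``O > 0`` is impossible
    for a valid assignment and raises.
    """
    e_d, e_u, e_h = expected_edge_counts(level_sizes)
    for obs, exp, name in ((counts.n_down, e_d, "downward"),
                           (counts.n_up, e_u, "upward"),
                           (counts.n_horizontal, e_h, "horizontal")):
        if exp == 0 and obs > 0:
            raise ValueError(f"{name} edges observed but impossible "
                             f"under level sizes {list(level_sizes)}")
    num = (counts.n_down / e_d if e_d else 0.0) + \
          (counts.n_horizontal / e_h if e_h else 0.0)
    den = (counts.n_up / e_u if e_u else 0.0) + \
          (counts.n_horizontal / e_h if e_h else 0.0)
    return ScoreValue(num, den)


def probabilistic_hierarchy_score(net: DirectedNetwork,
                                  pm: ProbabilityMatrix) -> ScoreValue:
    """PHS from per-edge downward/upward/horizontal probabilities.

    For edge ``i -> j`` the class probabilities are
    ``p_down = sum_{a>b} P(a,i) P(b,j)`` etc.; PHS is
    ``(sum p_down + sum p_horiz) / (sum p_up + sum p_horiz)`` over all
    edges.  With a one-hot matrix this reduces exactly to HS.  A
    self-loop is horizontal with probability 1.
    """
    missing = [n for n in net.nodes if n not in pm.node_index]
    if missing:
        raise ValueError(f"nodes without probability rows: {missing[:5]}")
    if net.n_edges == 0:
        raise ValueError("PHS undefined for an edgeless network")
    total_down = total_up = total_horiz = 0.0
    probs = pm.probs
    idx = pm.node_index
    for u, v in net.edges:
        if u == v:
            total_horiz += 1.0
            continue
        pi, pj = probs[idx[u]], probs[idx[v]]
        outer = np.outer(pi, pj)
        total_down += float(np.tril(outer, -1).sum())  # level(u) > level(v)
        total_up += float(np.triu(outer, 1).sum())
        total_horiz += float(np.trace(outer))
    return ScoreValue(total_down + total_horiz, total_up + total_horiz)
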