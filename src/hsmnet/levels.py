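"""Downstream statistics over an inferred hierarchy.

Once nodes carry top/middle/bottom (T/M/B) bands, four questions
recur: are undirected interactions enriched within or between bands
(binomial model); do node pairs share significantly many interaction
partners, and where do such "cooperative" pairs sit (hypergeometric
overlap + the same binomial model); how do feed-forward loops
distribute over the nine ordered band pairs; and are self-loops
(auto-phosphorylation) over-represented.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .network import DirectedNetwork
from .scoring import LevelAssignment

__all__ = [
    "EnrichmentCell",
    "band_assignment",
    "level_pair_enrichment",
    "shared_partner_cooperativity",
    "classify_ffls",
    "self_loop_overrepresentation",
]

BANDS = ("T", "M", "B")
UNORDERED_BAND_PAIRS = ("TT", "TM", "TB", "MM", "MB", "BB")
ORDERED_BAND_PAIRS = ("TT", "TM", "TB", "MT", "MM", "MB", "BT", "BM", "BB")


@dataclass(frozen=True)
class EnrichmentCell:
    """One band-pair cell of a binomial enrichment test.

    ``observed`` interactions out of ``possible_pairs`` slots, each
    interacting with ``background_p`` under the null; ``p_enrich`` is
    P(X >= observed), ``p_deplete`` is P(X <= observed) for
    X ~ Binomial(possible_pairs, background_p).
    """

    label: str
    observed: int
    possible_pairs: int
    background_p: float
    p_enrich: float
    p_deplete: float


def band_assignment(asg: LevelAssignment,
                    banding: Mapping[int, str] | None = None) -> dict[str, str]:
    """Collapse an L-level assignment to T/M/B bands.

    With exactly 3 levels, bottom/middle/top map to B/M/T.  For other
    L the default sends the top level to T, the bottom level to B and
    everything between to M; ``banding`` (level -> band) overrides.
    """
    L = asg.n_levels
    if banding is None:
        if L == 3:
            banding = {1: "B", 2: "M", 3: "T"}
        else:
            banding = {lvl: ("B" if lvl == 1 else "T" if lvl == L else "M")
                       for lvl in range(1, L + 1)}
    bad = set(banding.values()) - set(BANDS)
    if bad:
        raise ValueError(f"bands must be T/M/B, got {bad}")
    return {node: banding[lvl] for node, lvl in asg.levels.items()}


def _unordered_label(a: str, b: str) -> str:
    pair = "".join(sorted((a, b), key=BANDS.index))
    return pair


def level_pair_enrichment(interactions: Iterable[tuple[str, str]],
                          bands: Mapping[str, str],
                          universe_n: int | None = None,
                          n_interactions: int | None = None,
                          ) -> list[EnrichmentCell]:
    """Binomial enrichment of undirected interactions per band pair.

    The background probability that a random gene pair interacts is
    ``p = e / [n (n - 1) / 2]`` with ``n`` the universe size
    (default: number of banded nodes) and ``e`` the interaction count
    (default: pairs given).  Cell TT/MM/BB has
    ``b = m (m + 1) / 2`` possible pairs (self-pairs counted, so
    self-interactions are admissible); TM/TB/MB has ``b = m1 * m2``.
    A self-interaction (u, u) lands in its band's intra cell.
    """
    pairs = [(str(u), str(v)) for u, v in interactions]
    for u, v in pairs:
        if u not in bands or v not in bands:
            raise ValueError(f"interaction endpoint without band: {(u, v)!r}")
    n = universe_n if universe_n is not None else len(bands)
    if n < 2:
        raise ValueError("universe must contain at least 2 members")
    e = n_interactions if n_interactions is not None else len(pairs)
    p = e / (n * (n - 1) / 2)
    p = min(p, 1.0)
    sizes = {b: sum(1 for x in bands.values() if x == b) for b in BANDS}
    observed = dict.fromkeys(UNORDERED_BAND_PAIRS, 0)
    for u, v in pairs:
        observed[_unordered_label(bands[u], bands[v])] += 1
    cells = []
    for label in UNORDERED_BAND_PAIRS:
        a, b_ = label[0], label[1]
        if a == b_:
            m = sizes[a]
            slots = m * (m + 1) // 2
        else:
            slots = sizes[a] * sizes[b_]
        i = observed[label]
        if slots == 0:
            cells.append(EnrichmentCell(label, i, 0, p, 1.0, 1.0))
            continue
        p_enrich = float(stats.binom.sf(i - 1, slots, p))
        p_deplete = float(stats.binom.cdf(i, slots, p))
        cells.append(EnrichmentCell(label, i, slots, p, p_enrich, p_deplete))
    return cells


def overlap_significance(set_a: Iterable[str], set_b: Iterable[str],
                         universe_n: int) -> float:
    """Hypergeometric upper-tail P(overlap >= observed) for two
    partner sets drawn from a universe of ``universe_n`` members
    (Fisher's exact test, greater alternative)."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_n or len(b) > universe_n:
        raise ValueError("partner set larger than the universe")
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, universe_n, len(a), len(b)))


def shared_partner_cooperativity(partner_sets: Mapping[str, Iterable[str]],
                                 bands: Mapping[str, str],
                                 universe_n: int,
                                 alpha: float = 0.05,
                                 ) -> tuple[list[EnrichmentCell],
                                            list[tuple[str, str]]]:
    """Where do cooperative node pairs sit in the hierarchy?

    A pair is *cooperative* when its partner-set overlap clears the
    hypergeometric test at ``alpha``.  Cooperative pairs are then fed
    to the same binomial band-pair model, with background p = fraction
    of all pairs that are cooperative.  Returns the enrichment cells
    and the cooperative pairs themselves.
    """
    nodes = sorted(partner_sets)
    sets = {}
    for node in nodes:
        if node not in bands:
            raise ValueError(f"node without band: {node!r}")
        s = set(partner_sets[node])
        if len(s) > universe_n:
            raise ValueError(f"partner set of {node!r} exceeds the universe")
        sets[node] = s
    cooperative = []
    for u, v in itertools.combinations(nodes, 2):
        if overlap_significance(sets[u], sets[v], universe_n) < alpha:
            cooperative.append((u, v))
    n = len(nodes)
    n_pairs = n * (n - 1) // 2
    cells = level_pair_enrichment(
        cooperative, {k: bands[k] for k in nodes},
        universe_n=n, n_interactions=len(cooperative)) if n_pairs else []
    return cells, cooperative


def classify_ffls(phospho_net: DirectedNetwork,
                  substrate_map: Mapping[str, Iterable[str]],
                  bands: Mapping[str, str],
                  ) -> dict[str, int]:
    """Count feed-forward loops per ordered band pair of (X, Y).

    A feed-forward loop is a kinase edge X -> Y together with a shared
    substrate Z of X and Y (Z distinct from both; Z may be a
    non-kinase).  Each shared substrate counts as one motif.  The cell
    is (band(X), band(Y)); totals over downward (TM, TB, MB), upward
    (MT, BT, BM) and horizontal (TT, MM, BB) pairs are included under
    the keys ``downward``/``upward``/``horizontal``.
    """
    substrates = {k: set(v) for k, v in substrate_map.items()}
    counts = dict.fromkeys(ORDERED_BAND_PAIRS, 0)
    for x, y in phospho_net.edges:
        if x == y:
            continue
        if x not in substrates or y not in substrates:
            raise ValueError(f"kinase without substrate set: {x!r} or {y!r}")
        if x not in bands or y not in bands:
            raise ValueError(f"kinase without band: {x!r} or {y!r}")
        shared = (substrates[x] & substrates[y]) - {x, y}
        counts[bands[x] + bands[y]] += len(shared)
    counts["downward"] = counts["TM"] + counts["TB"] + counts["MB"]
    counts["upward"] = counts["MT"] + counts["BT"] + counts["BM"]
    counts["horizontal"] = counts["TT"] + counts["MM"] + counts["BB"]
    return counts


def self_loop_overrepresentation(net: DirectedNetwork,
                                 ) -> tuple[int, float, float]:
    """Test whether self-loops are over-represented.

    Null: each of the e edges independently falls on a uniformly
    random ordered node pair with self-pairs allowed, so each edge is
    a self-loop with probability 1/n.  Returns (observed, expected,
    upper-tail binomial p).
    """
    n, e = net.n_nodes, net.n_edges
    if n == 0:
        raise ValueError("empty network")
    observed = len(net.self_loops)
    expected = e / n
    if e == 0:
        return 0, 0.0, 1.0
    p = float(stats.binom.sf(observed - 1, e, 1.0 / n))
    return observed, expected, p
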