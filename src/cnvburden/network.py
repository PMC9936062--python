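"""Hub-gene detection on a protein-protein interaction graph.

Implements Maximal Clique Centrality (MCC): for a node ``v``,
``MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!``.
A node whose only maximal clique is the singleton ``{v}`` (an isolated
vertex) scores ``0! = 1``.  Candidate genes ranking at the top of the MCC
list are reported as hub nodes.

The graph is an undirected simple graph consumed from any edge list; how
the edges were obtained (e.g. a STRING export at some confidence cutoff)
is the caller's concern.  Clique enumeration is exponential in the worst
case, so it is guarded by a configurable budget.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "CliqueBudgetExceeded",
    "build_graph",
    "maximal_cliques",
    "mcc_scores",
    "mcc_score",
    "rank_hubs",
]


class CliqueBudgetExceeded(RuntimeError):
    """Raised when clique enumeration exceeds the configured budget."""


def build_graph(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Undirected simple graph from an edge list (self-loops rejected)."""
    g = nx.Graph()
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop edge {a!r}")
        g.add_edge(a, b)
    return g


def maximal_cliques(
    g: nx.Graph, max_cliques: int = 1_000_000
) -> list[frozenset[str]]:
    """All maximal cliques (Bron-Kerbosch with pivoting via networkx).

    Isolated vertices yield singleton cliques.  Raises
    :class:`CliqueBudgetExceeded` beyond *max_cliques* cliques.
    """
    out: list[frozenset[str]] = []
    for clique in nx.find_cliques(g):
        out.append(frozenset(clique))
        if len(out) > max_cliques:
            raise CliqueBudgetExceeded(
                f"more than {max_cliques} maximal cliques; raise the budget "
                "or reduce the graph"
            )
    return out


def mcc_scores(
    g: nx.Graph, max_cliques: int = 1_000_000
) -> dict[str, int]:
    """MCC score for every node of *g*."""
    scores: dict[str, int] = {v: 0 for v in g.nodes}
    for clique in maximal_cliques(g, max_cliques):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def mcc_score(g: nx.Graph, v: str) -> int:
    """MCC of a single node (1 for an isolated vertex)."""
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    return mcc_scores(g)[v]


@dataclass(frozen=True)
class HubEntry:
    node: str
    mcc: int
    degree: int
    in_graph: bool


def rank_hubs(
    g: nx.Graph,
    nodes_of_interest: Sequence[str] | None = None,
    top_k: int | None = None,
    max_cliques: int = 1_000_000,
) -> list[HubEntry]:
    """Rank nodes by descending MCC; ties by degree, then name.

    Restricted to *nodes_of_interest* when given; names absent from the
    graph are reported with score 0 (and ``in_graph=False``).  *top_k*
    truncates the ranking; a value larger than the candidate set returns
    the full ranking.
    """
    scores = mcc_scores(g, max_cliques)
    nodes = list(nodes_of_interest) if nodes_of_interest is not None else list(g.nodes)
    absent = [v for v in nodes if v not in g]
    if absent:
        warnings.warn(
            f"{len(absent)} candidate node(s) absent from the graph "
            f"(e.g. {absent[0]!r}); scored 0",
            stacklevel=2,
        )
    entries = [
        HubEntry(v, scores.get(v, 0), g.degree(v) if v in g else 0, v in g)
        for v in nodes
    ]
    entries.sort(key=lambda e: (-e.mcc, -e.degree, e.node))
    if top_k is not None:
        entries = entries[:top_k]
    return entries
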