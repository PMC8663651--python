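"""Token co-occurrence graphs and hop-distance queries.

A post's tokens are linked into an undirected graph in which two tokens
share an edge when they occur within a configurable window of each other.
Relevance filtering asks whether a descriptor lies within ``k`` hops of
the anchor token ``pain``; the bound is inclusive (distance <= k).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

UNREACHABLE: float = float("inf")
"""Sentinel returned by :func:`hop_distance` when no path exists."""


@dataclass(frozen=True)
class WordGraph:
    """Undirected token adjacency graph.

    Attributes
    ----------
    nodes : frozenset of str
        Unique tokens of the originating sequence.
    edges : frozenset of frozenset pairs
        Unordered token pairs; no self-loops.
    """

    nodes: frozenset = field(default_factory=frozenset)
    edges: frozenset = field(default_factory=frozenset)

    def neighbors(self, token: str) -> set:
        """Return the adjacent tokens of *token* (empty set if absent)."""
        out = set()
        for e in self.edges:
            if token in e:
                out.update(e - {token})
        return out

    def adjacency(self) -> dict:
        """Full adjacency map token -> set of neighbor tokens."""
        adj: dict[str, set] = {n: set() for n in self.nodes}
        for e in self.edges:
            a, b = tuple(e)
            adj[a].add(b)
            adj[b].add(a)
        return adj


def build_word_graph(tokens: Sequence[str], window: int = 1) -> WordGraph:
    """Build a :class:`WordGraph` from a token sequence.

    Tokens ``tokens[i]`` and ``tokens[j]`` are linked iff
    ``0 < |i - j| <= window`` for some pair of positions. Repeated tokens
    collapse onto a single node; self-loops are dropped.

    Parameters
    ----------
    tokens : sequence of str
        Cleaned, lowercased tokens in post order.
    window : int, default 1
        Positional co-occurrence window; 1 links consecutive tokens only.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    nodes = frozenset(tokens)
    edges = set()
    n = len(tokens)
    for i in range(n):
        for j in range(i + 1, min(i + window + 1, n)):
            if tokens[i] != tokens[j]:
                edges.add(frozenset((tokens[i], tokens[j])))
    return WordGraph(nodes=nodes, edges=frozenset(edges))


def hop_distance(graph: WordGraph, source: str, target: str) -> float:
    """Shortest-path edge count between two tokens via breadth-first search.

    Returns 0 when ``source == target`` and the token is present, and
    :data:`UNREACHABLE` when either endpoint is absent or no path exists.
    """
    if source not in graph.nodes or target not in graph.nodes:
        return UNREACHABLE
    if source == target:
        return 0
    adj = graph.adjacency()
    seen = {source}
    frontier = deque([(source, 0)])
    while frontier:
        node, d = frontier.popleft()
        for nxt in adj[node]:
            if nxt == target:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, d + 1))
    return UNREACHABLE


def within_hops(graph: WordGraph, source: str, target: str, k: int) -> bool:
    """True iff ``hop_distance(graph, source, target) <= k`` (inclusive)."""
    if k < 0:
        raise ValueError(f"hop limit must be >= 0, got {k}")
    return hop_distance(graph, source, target) <= k


def export_edge_list(graph: WordGraph) -> str:
    """Render the edge set as a sorted two-column TSV string (debug aid)."""
    rows = sorted(tuple(sorted(e)) for e in graph.edges)
    return "\n".join(f"{a}\t{b}" for a, b in rows)
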