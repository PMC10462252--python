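"""Mixed-mark graphs for constraint-based network learning.

The learned metabolite network is a partially directed graph: directed
edges where the data (plus background knowledge) identify a direction,
undirected edges for Markov-equivalent directions, and bidirected edges
marking directions that failed the variable-reduction stability test.
At most one edge connects any pair of nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx

DIRECTED = "directed"
UNDIRECTED = "undirected"
BIDIRECTED = "bidirected"

_MARKS = (DIRECTED, UNDIRECTED, BIDIRECTED)


def _pair(u, v) -> frozenset:
    if u == v:
        raise ValueError(f"self-loop on node {u!r}")
    return frozenset((u, v))


class MixedGraph:
    """Graph over metabolite and factor nodes with directed, undirected
    and bidirected edges, plus per-edge retention p-values and the
    separating sets recorded during skeleton learning."""

    def __init__(self, nodes: Iterable = (), kinds: dict | None = None):
        self._kinds: dict = {}
        self._state: dict[frozenset, tuple] = {}
        self._adj: dict[object, set] = {}
        self.edge_pvalues: dict[frozenset, float] = {}
        self.separating_sets: dict[frozenset, frozenset] = {}
        for n in nodes:
            self.add_node(n, (kinds or {}).get(n, "metabolite"))

    # -- nodes ---------------------------------------------------------
    def add_node(self, n, kind: str = "metabolite") -> None:
        if n not in self._kinds:
            self._kinds[n] = kind
            self._adj[n] = set()

    @property
    def nodes(self) -> list:
        return sorted(self._kinds)

    def kind(self, n) -> str:
        return self._kinds[n]

    def set_kind(self, n, kind: str) -> None:
        if n not in self._kinds:
            raise KeyError(f"unknown node {n!r}")
        self._kinds[n] = kind

    def __contains__(self, n) -> bool:
        return n in self._kinds

    def __len__(self) -> int:
        return len(self._kinds)

    # -- edges ---------------------------------------------------------
    def add_edge(self, u, v, mark: str = UNDIRECTED) -> None:
        """Add an edge; for ``mark='directed'`` the direction is u -> v."""
        if mark not in _MARKS:
            raise ValueError(f"unknown edge mark {mark!r}")
        if u not in self._kinds or v not in self._kinds:
            raise KeyError(f"unknown node in edge ({u!r}, {v!r})")
        p = _pair(u, v)
        self._state[p] = (mark, u, v) if mark == DIRECTED else (mark,)
        self._adj[u].add(v)
        self._adj[v].add(u)

    def remove_edge(self, u, v) -> None:
        p = _pair(u, v)
        del self._state[p]
        self._adj[u].discard(v)
        self._adj[v].discard(u)
        self.edge_pvalues.pop(p, None)

    def has_edge(self, u, v) -> bool:
        return _pair(u, v) in self._state

    def mark(self, u, v) -> str:
        return self._state[_pair(u, v)][0]

    def is_directed_edge(self, u, v) -> bool:
        """True iff the edge u -> v exists with that direction."""
        st = self._state.get(_pair(u, v))
        return st is not None and st[0] == DIRECTED and st[1] == u

    def orient(self, u, v) -> None:
        """Turn the existing edge between u and v into u -> v."""
        if not self.has_edge(u, v):
            raise KeyError(f"no edge between {u!r} and {v!r}")
        self._state[_pair(u, v)] = (DIRECTED, u, v)

    def set_undirected(self, u, v) -> None:
        if not self.has_edge(u, v):
            raise KeyError(f"no edge between {u!r} and {v!r}")
        self._state[_pair(u, v)] = (UNDIRECTED,)

    def set_bidirected(self, u, v) -> None:
        if not self.has_edge(u, v):
            raise KeyError(f"no edge between {u!r} and {v!r}")
        self._state[_pair(u, v)] = (BIDIRECTED,)

    def edges(self) -> Iterator[tuple]:
        """Yield (u, v, mark); directed edges as (parent, child), others
        with endpoints in sorted order."""
        for p, st in self._state.items():
            if st[0] == DIRECTED:
                yield st[1], st[2], DIRECTED
            else:
                u, v = sorted(p)
                yield u, v, st[0]

    def n_edges(self) -> int:
        return len(self._state)

    # -- neighborhoods -------------------------------------------------
    def adjacent(self, n) -> set:
        return set(self._adj[n])

    def parents(self, n) -> set:
        return {m for m in self._adj[n] if self.is_directed_edge(m, n)}

    def children(self, n) -> set:
        return {m for m in self._adj[n] if self.is_directed_edge(n, m)}

    def undirected_neighbors(self, n) -> set:
        return {m for m in self._adj[n] if self.mark(n, m) == UNDIRECTED}

    def bidirected_neighbors(self, n) -> set:
        return {m for m in self._adj[n] if self.mark(n, m) == BIDIRECTED}

    # -- views ---------------------------------------------------------
    def directed_part(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._kinds)
        for u, v, mark in self.edges():
            if mark == DIRECTED:
                g.add_edge(u, v)
        return g

    def skeleton(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._kinds)
        g.add_edges_from(tuple(sorted(p)) for p in self._state)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.directed_part())

    def creates_cycle(self, u, v) -> bool:
        """Would orienting u -> v create a directed cycle?"""
        d = self.directed_part()
        if d.has_edge(u, v):
            return False
        return v in d and u in d and nx.has_path(d, v, u)

    def copy(self) -> "MixedGraph":
        g = MixedGraph()
        g._kinds = dict(self._kinds)
        g._state = dict(self._state)
        g._adj = {n: set(s) for n, s in self._adj.items()}
        g.edge_pvalues = dict(self.edge_pvalues)
        g.separating_sets = dict(self.separating_sets)
        return g

    def subgraph(self, keep: Iterable) -> "MixedGraph":
        keep = set(keep)
        g = MixedGraph(sorted(keep), kinds={n: self._kinds[n] for n in keep})
        for u, v, mark in self.edges():
            if u in keep and v in keep:
                g.add_edge(u, v, mark)
                p = _pair(u, v)
                if p in self.edge_pvalues:
                    g.edge_pvalues[p] = self.edge_pvalues[p]
        return g

    def edge_states(self) -> dict[frozenset, tuple]:
        """Mapping pair -> mark state, for equality and distance checks."""
        return dict(self._state)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MixedGraph):
            return NotImplemented
        return self._kinds == other._kinds and self._state == other._state

    def __repr__(self) -> str:
        return (f"MixedGraph({len(self._kinds)} nodes, "
                f"{len(self._state)} edges)")


@dataclass(frozen=True)
class BackgroundKnowledge:
    """Structural prior knowledge: exogenous nodes (essential amino acids,
    polygenic factors) receive no edges, plus optional explicit forbidden
    edges and required directions (ordered pairs)."""

    exogenous_nodes: frozenset = frozenset()
    forbidden_edges: frozenset = frozenset()
    required_directions: frozenset = frozenset()

    def __post_init__(self):
        if self.required_directions & self.forbidden_edges:
            raise ValueError("required and forbidden edge sets overlap")

    def forbids(self, u, v) -> bool:
        """True if the directed edge u -> v is disallowed."""
        if (u, v) in self.forbidden_edges:
            return True
        # an edge may never point into an exogenous node from outside
        # the exogenous set (edges among exogenous nodes stay undirected)
        return v in self.exogenous_nodes and u not in self.exogenous_nodes


def shd(g1: MixedGraph, g2: MixedGraph) -> int:
    """Structural Hamming distance between two mixed graphs.

    Each node pair contributes 1 when its edge state differs: a missing
    or extra adjacency costs 1, and so does any mark disagreement
    (direction flip, directed vs undirected vs bidirected).
    """
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs must share the same node set")
    s1, s2 = g1.edge_states(), g2.edge_states()
    dist = 0
    for p in set(s1) | set(s2):
        if s1.get(p) != s2.get(p):
            dist += 1
    return dist
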