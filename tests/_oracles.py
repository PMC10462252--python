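"""Brute-force reference implementations used only as test oracles.

Everything here is deliberately naive (exhaustive enumeration, path
listing) and independent of the algorithms it checks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from metabonet.graph import DIRECTED, UNDIRECTED, MixedGraph


def all_dags(nodes: list) -> list[nx.DiGraph]:
    """Every labeled DAG on ``nodes`` by filtering all orientations of
    all undirected graphs.  Only feasible for ≤4 nodes."""
    pairs = list(itertools.combinations(nodes, 2))
    out = []
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for (u, v), s in zip(pairs, states):
            if s == 1:
                g.add_edge(u, v)
            elif s == 2:
                g.add_edge(v, u)
        if nx.is_directed_acyclic_graph(g):
            out.append(g)
    return out


def random_dag(n_nodes: int, p_edge: float,
               rng: np.random.Generator) -> nx.DiGraph:
    nodes = [f"n{i}" for i in range(n_nodes)]
    order = list(rng.permutation(nodes))
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            g.add_edge(order[i], order[j])
    return g


def vstructures(dag: nx.DiGraph) -> set:
    """Unshielded colliders as frozenset({x, y}) -> z triples."""
    out = set()
    for z in dag.nodes:
        for x, y in itertools.combinations(sorted(dag.predecessors(z)), 2):
            if not (dag.has_edge(x, y) or dag.has_edge(y, x)):
                out.add((frozenset((x, y)), z))
    return out


def cpdag_by_enumeration(dag: nx.DiGraph) -> MixedGraph:
    """CPDAG via exhaustive Markov-equivalence enumeration: orient every
    skeleton edge in all ways, keep acyclic digraphs with the same
    skeleton and v-structures, mark an edge directed iff every
    equivalent DAG agrees on it."""
    edges = sorted(tuple(sorted(e)) for e in dag.to_undirected().edges)
    target_v = vstructures(dag)
    consistent = []
    for orient in itertools.product((0, 1), repeat=len(edges)):
        g = nx.DiGraph()
        g.add_nodes_from(dag.nodes)
        for (u, v), o in zip(edges, orient):
            g.add_edge(u, v) if o == 0 else g.add_edge(v, u)
        if nx.is_directed_acyclic_graph(g) and vstructures(g) == target_v:
            consistent.append(g)
    assert consistent, "no consistent extension found"
    out = MixedGraph(sorted(dag.nodes))
    for u, v in edges:
        fwd = all(g.has_edge(u, v) for g in consistent)
        rev = all(g.has_edge(v, u) for g in consistent)
        if fwd:
            out.add_edge(u, v, DIRECTED)
        elif rev:
            out.add_edge(v, u, DIRECTED)
        else:
            out.add_edge(u, v, UNDIRECTED)
    return out


def consistent_extensions(g: MixedGraph) -> list[nx.DiGraph]:
    """All orientations of a PDAG's undirected edges that are acyclic
    and create no new unshielded collider."""
    und = sorted((u, v) for u, v, m in g.edges() if m == UNDIRECTED)
    base = [(u, v) for u, v, m in g.edges() if m == DIRECTED]
    start = nx.DiGraph()
    start.add_nodes_from(g.nodes)
    start.add_edges_from(base)
    # v-structures of the PDAG itself: both arrows directed, parents
    # nonadjacent in the FULL skeleton (undirected edges shield too)
    base_v = set()
    for z in g.nodes:
        for x, y in itertools.combinations(sorted(g.parents(z)), 2):
            if not g.has_edge(x, y):
                base_v.add((frozenset((x, y)), z))

    out = []
    for orient in itertools.product((0, 1), repeat=len(und)):
        d = start.copy()
        for (u, v), o in zip(und, orient):
            d.add_edge(u, v) if o == 0 else d.add_edge(v, u)
        if nx.is_directed_acyclic_graph(d) and vstructures(d) == base_v:
            out.append(d)
    return out


def maximally_oriented_by_extension(g: MixedGraph) -> MixedGraph:
    """Orient every undirected edge that points the same way in all
    consistent DAG extensions — the defining property the Meek rules
    compute."""
    exts = consistent_extensions(g)
    out = g.copy()
    if not exts:
        return out
    for u, v, m in g.edges():
        if m != UNDIRECTED:
            continue
        if all(d.has_edge(u, v) for d in exts):
            out.orient(u, v)
        elif all(d.has_edge(v, u) for d in exts):
            out.orient(v, u)
    return out


def bh_bruteforce(p_values, q):
    """Largest i with p_(i) <= i*q/m; reject everything at or below."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k = rank
    reject = np.zeros(m, dtype=bool)
    if k:
        reject[order[:k]] = True
    return reject


def confounders_by_path_enumeration(dag: nx.DiGraph, target,
                                    hazard: dict) -> set:
    """Parents of target with some directed path (possibly length 0) to
    a node with nonzero hazard coefficient, by listing simple paths."""
    out = set()
    direct = {m for m, b in hazard.items() if b != 0}
    for parent in dag.predecessors(target):
        hits = parent in direct
        for d in direct:
            if not hits and d in dag:
                if any(True for _ in nx.all_simple_paths(dag, parent, d)):
                    hits = True
        if hits:
            out.add(parent)
    return out


def mediators_by_path_enumeration(dag: nx.DiGraph, A: set, B: set) -> set:
    """Middle nodes of some simple A->B path whose removal reduces the
    number of reachable (a, b) pairs."""
    def pairs(g):
        return {(a, b) for a in A for b in B
                if a in g and b in g and nx.has_path(g, a, b)}

    base = pairs(dag)
    mids = set()
    for a in A:
        for b in B:
            if a in dag and b in dag:
                for path in nx.all_simple_paths(dag, a, b):
                    mids.update(path[1:-1])
    mids -= A | B
    out = set()
    for m in mids:
        sub = dag.subgraph([n for n in dag if n != m])
        if pairs(sub) < base:
            out.add(m)
    return out
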