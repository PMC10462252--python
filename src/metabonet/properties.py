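"""Network roles and structures.

Degrees (interval-valued where directions are unresolved), broadcaster
and receiver classification, connected-component subnetworks labelled by
metabolite class, mediators between node groups, and descendant
reachability.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import pandas as pd

from .graph import MixedGraph

BROADCASTER_MIN_OUT = 3
RECEIVER_MIN_IN = 3
RECEIVER_MAX_OUT = 1


def _node_degrees(g: MixedGraph, n) -> tuple:
    # degrees count metabolite neighbors only; factor parents are
    # reported through the genetic-influence flag instead
    met = lambda nodes: [x for x in nodes if g.kind(x) == "metabolite"]
    out_pt = len(met(g.children(n)))
    in_pt = len(met(g.parents(n)))
    unori = len(met(g.undirected_neighbors(n))) \
        + len(met(g.bidirected_neighbors(n)))
    out_d = out_pt if unori == 0 else (out_pt, out_pt + unori)
    in_d = in_pt if unori == 0 else (in_pt, in_pt + unori)
    return out_d, in_d, unori


def render_degree(d) -> str:
    """Point degrees as integers, interval degrees as "a or b"."""
    if isinstance(d, tuple):
        return f"{d[0]} or {d[1]}"
    return str(int(d))


def degrees(g: MixedGraph) -> pd.DataFrame:
    """Per-node out/in degree over directed edges, undirected degree and
    total connectivity.

    Nodes with incident undirected or bidirected edges get interval
    degrees [point, point + #unoriented]; each unoriented edge counts
    once toward connectivity.
    """
    rows = {}
    for n in g.nodes:
        out_d, in_d, unori = _node_degrees(g, n)
        out_pt = out_d[0] if isinstance(out_d, tuple) else out_d
        in_pt = in_d[0] if isinstance(in_d, tuple) else in_d
        rows[n] = {
            "out_degree": out_d,
            "in_degree": in_d,
            "undirected_degree": unori,
            "total_connectivity": out_pt + in_pt + unori,
            "genetically_influenced": any(g.kind(p) == "factor"
                                          for p in g.parents(n)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "node"
    return out


def descendants(g: MixedGraph, node) -> set:
    """All nodes reachable from ``node`` via directed edges."""
    if node not in g:
        raise KeyError(f"unknown node {node!r}")
    return set(nx.descendants(g.directed_part(), node))


def classify_roles(g: MixedGraph,
                   broadcaster_min_out: int = BROADCASTER_MIN_OUT,
                   receiver_min_in: int = RECEIVER_MIN_IN,
                   receiver_max_out: int = RECEIVER_MAX_OUT) -> pd.DataFrame:
    """Label broadcasters and receivers.

    A broadcaster directly affects at least ``broadcaster_min_out``
    nodes and its influence propagates downstream (some directed path of
    length ≥ 2 leaves it).  A receiver is influenced by at least
    ``receiver_min_in`` nodes while affecting at most
    ``receiver_max_out``.  Interval degrees are judged by their
    identified (lower) endpoint.
    """
    if min(broadcaster_min_out, receiver_min_in) <= 0:
        raise ValueError("role thresholds must be positive")
    tab = degrees(g)
    directed = g.directed_part()
    roles = []
    for n in tab.index:
        out_d, in_d = tab.loc[n, "out_degree"], tab.loc[n, "in_degree"]
        out_pt = out_d[0] if isinstance(out_d, tuple) else out_d
        in_pt = in_d[0] if isinstance(in_d, tuple) else in_d
        propagates = any(directed.out_degree(c) > 0
                         for c in directed.successors(n))
        is_b = out_pt >= broadcaster_min_out and propagates
        is_r = in_pt >= receiver_min_in and out_pt <= receiver_max_out
        label = {(True, True): "broadcaster+receiver",
                 (True, False): "broadcaster",
                 (False, True): "receiver",
                 (False, False): "none"}[(is_b, is_r)]
        roles.append((is_b, is_r, label))
    tab["broadcaster"] = [r[0] for r in roles]
    tab["receiver"] = [r[1] for r in roles]
    tab["role"] = [r[2] for r in roles]
    return tab


def find_subnetworks(g: MixedGraph,
                     annotations: dict | None = None) -> dict:
    """Connected components of the undirected skeleton, labelled by the
    majority node class (ties concatenate the tied labels; repeated
    labels get a numeric suffix).  Returns node -> subnetwork label."""
    comps = sorted(nx.connected_components(g.skeleton()),
                   key=lambda c: sorted(c)[0])
    seen: dict[str, int] = {}
    result = {}
    for comp in comps:
        if annotations:
            counts: dict[str, int] = {}
            for n in comp:
                cls = annotations.get(n)
                if cls is not None:
                    counts[cls] = counts.get(cls, 0) + 1
            if counts:
                top = max(counts.values())
                winners = sorted(k for k, v in counts.items() if v == top)
                label = "+".join(winners)
            else:
                label = "unannotated"
        else:
            label = "component"
        seen[label] = seen.get(label, 0) + 1
        if seen[label] > 1:
            label = f"{label}_{seen[label]}"
        for n in comp:
            result[n] = label
    return result


def find_mediators(g: MixedGraph, group_a: Iterable,
                   group_b: Iterable) -> set:
    """Nodes outside both groups that carry directed influence from
    group_a to group_b: the node lies on a directed a→b path and its
    removal strictly reduces the number of reachable (a, b) pairs."""
    A, B = set(group_a), set(group_b)
    if A & B:
        raise ValueError(f"groups overlap: {sorted(A & B)}")
    directed = g.directed_part()

    def connected_pairs(dg) -> int:
        cnt = 0
        for a in A:
            if a not in dg:
                continue
            reach = nx.descendants(dg, a)
            cnt += len(reach & B)
        return cnt

    base = connected_pairs(directed)
    if base == 0:
        return set()
    # candidates: strictly between the groups on some directed path
    reach_from_a = set()
    for a in A:
        if a in directed:
            reach_from_a |= nx.descendants(directed, a)
    reach_to_b = set()
    rev = directed.reverse(copy=False)
    for b in B:
        if b in rev:
            reach_to_b |= nx.descendants(rev, b)
    cands = (reach_from_a & reach_to_b) - A - B
    mediators = set()
    for m in cands:
        sub = directed.subgraph(n for n in directed if n != m)
        if connected_pairs(sub) < base:
            mediators.add(m)
    return mediators


def role_table(g: MixedGraph, annotations: dict | None = None,
               **thresholds) -> pd.DataFrame:
    """Full per-node report: degrees, connectivity, role, subnetwork,
    genetic-influence flag; interval degrees serialized as "a or b"."""
    tab = classify_roles(g, **thresholds)
    sub = find_subnetworks(g, annotations)
    tab["subnetwork"] = [sub[n] for n in tab.index]
    tab["out_degree"] = tab["out_degree"].map(render_degree)
    tab["in_degree"] = tab["in_degree"].map(render_degree)
    return tab
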