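"""Constraint-based learning of metabolite conditional-independence networks.

Implements the order-independent (stable) variant of the PC algorithm on
Gaussian partial correlations: skeleton discovery with per-level frozen
adjacency sets, v-structure orientation with majority vote on conflicts,
Meek rules R1-R4, background-knowledge orientation (exogenous essential
amino acids and polygenic factors are sources), significance-level
selection by split-half structural-Hamming-distance minimization, and a
variable-reduction stability test that downgrades unstable directions to
bidirected "unidentified" edges.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .graph import (BIDIRECTED, DIRECTED, UNDIRECTED, BackgroundKnowledge,
                    MixedGraph, _pair, shd)

__all__ = [
    "partial_correlation", "ci_test", "GaussianCITest", "DSeparationOracle",
    "pc_skeleton", "orient_v_structures", "apply_meek_rules",
    "apply_background_knowledge", "select_alpha", "direction_stability",
    "learn_network", "dag_to_cpdag",
]


class OrientationConflictError(RuntimeError):
    """Background knowledge contradicts an orientation already compelled
    by the data (v-structure)."""


# ---------------------------------------------------------------------------
# conditional-independence tests
# ---------------------------------------------------------------------------

def partial_correlation(x: str, y: str, Z: Iterable[str],
                        data: pd.DataFrame) -> float:
    """Partial correlation of columns x and y given the columns in Z.

    Computed from the inverse of the correlation submatrix of
    {x, y} ∪ Z; equals the correlation of the OLS residuals of x and y
    each regressed on Z.
    """
    Z = sorted(Z)
    if x == y or x in Z or y in Z:
        raise ValueError("x, y and Z must be distinct")
    cols = [x, y] + Z
    corr = np.corrcoef(data[cols].to_numpy(), rowvar=False)
    corr = np.atleast_2d(corr)
    return _pcor_from_corr(corr)


def _pcor_from_corr(corr: np.ndarray) -> float:
    """Partial correlation of variables 0 and 1 given the rest, from
    their joint correlation matrix."""
    if corr.shape[0] == 2:
        return float(corr[0, 1])
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular correlation matrix in conditioning set") from exc
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0:
        raise np.linalg.LinAlgError(
            "non-positive precision diagonal; conditioning set is singular")
    r = -prec[0, 1] / math.sqrt(denom)
    return float(np.clip(r, -1.0, 1.0))


def fisher_z_pvalue(r: float, n: int, k: int) -> float:
    """Two-sided p-value for zero partial correlation given |Z| = k,
    using the Fisher z transform: sqrt(n-k-3)·|atanh(r)| vs N(0,1)."""
    dof = n - k - 3
    if dof <= 0:
        raise ValueError(f"need n > |Z| + 3 (n={n}, |Z|={k})")
    r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    z = 0.5 * math.log((1 + r) / (1 - r))
    stat = math.sqrt(dof) * abs(z)
    return 2.0 * stats.norm.sf(stat)


def ci_test(x: str, y: str, Z: Iterable[str], data: pd.DataFrame,
            alpha: float) -> tuple[float, bool]:
    """Fisher-z conditional-independence test.

    Returns (p_value, independent) with independence declared when
    p > alpha.
    """
    Z = sorted(Z)
    r = partial_correlation(x, y, Z, data)
    p = fisher_z_pvalue(r, len(data), len(Z))
    return p, p > alpha


class GaussianCITest:
    """Callable Fisher-z CI test with a cached correlation matrix.

    ``test(x, y, Z) -> p``; column lookups go through a precomputed
    name -> index map so repeated skeleton queries stay cheap.
    """

    def __init__(self, data: pd.DataFrame):
        self.names = list(data.columns)
        self._idx = {c: i for i, c in enumerate(self.names)}
        self.n = len(data)
        x = data.to_numpy(dtype=float)
        self.corr = np.corrcoef(x, rowvar=False)

    def __call__(self, x: str, y: str, Z: Sequence[str]) -> float:
        ix, iy = self._idx[x], self._idx[y]
        if not Z:
            r = self.corr[ix, iy]
        else:
            iz = [self._idx[c] for c in Z]
            sel = [ix, iy] + iz
            r = _pcor_from_corr(self.corr[np.ix_(sel, sel)])
        return fisher_z_pvalue(float(r), self.n, len(Z))


class DSeparationOracle:
    """Exact CI oracle from a known DAG: p = 1 when x and y are
    d-separated given Z, else 0.  Used for testing the learner against
    ground truth."""

    def __init__(self, dag: nx.DiGraph):
        self.dag = dag
        self.names = sorted(dag.nodes)

    def __call__(self, x, y, Z) -> float:
        return 1.0 if nx.is_d_separator(self.dag, {x}, {y}, set(Z)) else 0.0


# ---------------------------------------------------------------------------
# PC-stable skeleton
# ---------------------------------------------------------------------------

def _as_ci(data_or_ci, nodes=None):
    if callable(data_or_ci):
        if nodes is None:
            nodes = getattr(data_or_ci, "names")
        return data_or_ci, list(nodes)
    ci = GaussianCITest(data_or_ci)
    return ci, ci.names


def pc_skeleton(data, alpha: float, max_cond_size: int = 3,
                nodes: Sequence | None = None) -> MixedGraph:
    """PC-stable skeleton over the columns of ``data`` (a DataFrame) or
    over ``nodes`` when ``data`` is a CI-test callable.

    At each level the adjacency sets are frozen before any edge test, so
    the result does not depend on the order variables are presented in.
    Separating sets and conservative edge p-values (the largest p among
    the tests that failed to remove the edge) are recorded on the graph.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    ci, names = _as_ci(data, nodes)
    names = sorted(names)
    g = MixedGraph(names)
    for u, v in itertools.combinations(names, 2):
        g.add_edge(u, v, UNDIRECTED)

    max_p: dict[frozenset, float] = {}
    level = 0
    while level <= max_cond_size:
        frozen_adj = {n: sorted(g.adjacent(n)) for n in names}
        any_candidate = False
        for x, y in itertools.combinations(names, 2):
            if not g.has_edge(x, y):
                continue
            removed = False
            sides = ((x, y),) if level == 0 else ((x, y), (y, x))
            for a, b in sides:
                pool = [c for c in frozen_adj[a] if c != b]
                if len(pool) < level:
                    continue
                any_candidate = True
                for Z in itertools.combinations(pool, level):
                    p = ci(a, b, list(Z))
                    pr = _pair(x, y)
                    if p > alpha:
                        g.remove_edge(x, y)
                        g.separating_sets[pr] = frozenset(Z)
                        max_p.pop(pr, None)
                        removed = True
                        break
                    max_p[pr] = max(max_p.get(pr, 0.0), p)
                if removed:
                    break
        if not any_candidate:
            break
        level += 1
    g.edge_pvalues = max_p
    return g


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def orient_v_structures(g: MixedGraph,
                        separating_sets: dict | None = None,
                        bk: BackgroundKnowledge | None = None) -> MixedGraph:
    """Orient unshielded colliders x -> z <- y when z is absent from the
    separating set of (x, y).

    Conflicting proposals for the same edge are resolved by majority of
    evidence; exact ties leave the edge undirected.  Orientations that
    would point into an exogenous node are suppressed when background
    knowledge is supplied.
    """
    sepsets = separating_sets if separating_sets is not None \
        else g.separating_sets
    g = g.copy()
    votes: dict[tuple, int] = {}
    for z in g.nodes:
        nbrs = sorted(g.adjacent(z))
        for x, y in itertools.combinations(nbrs, 2):
            if g.has_edge(x, y):
                continue  # shielded
            sep = sepsets.get(_pair(x, y))
            if sep is None or z in sep:
                continue
            if bk is not None and (bk.forbids(x, z) or bk.forbids(y, z)):
                continue
            votes[(x, z)] = votes.get((x, z), 0) + 1
            votes[(y, z)] = votes.get((y, z), 0) + 1
    done = set()
    for (u, v) in sorted(votes):
        pr = _pair(u, v)
        if pr in done:
            continue
        done.add(pr)
        fwd, rev = votes.get((u, v), 0), votes.get((v, u), 0)
        if fwd == rev:
            continue
        a, b = (u, v) if fwd > rev else (v, u)
        if g.mark(a, b) == UNDIRECTED and not g.creates_cycle(a, b):
            g.orient(a, b)
    return g


def _meek_pass(g: MixedGraph, bk: BackgroundKnowledge | None) -> bool:
    changed = False
    for u, v, mark in sorted(g.edges()):
        if mark != UNDIRECTED:
            continue
        for a, b in ((u, v), (v, u)):
            if bk is not None and bk.forbids(a, b):
                continue
            if _meek_applies(g, a, b):
                if not g.creates_cycle(a, b):
                    g.orient(a, b)
                    changed = True
                break
        if changed:
            return True
    return changed


def _meek_applies(g: MixedGraph, a, b) -> bool:
    """Do Meek rules R1-R4 compel the orientation a -> b?"""
    adj_a, adj_b = g.adjacent(a), g.adjacent(b)
    # R1: c -> a, c and b nonadjacent
    for c in g.parents(a):
        if c != b and c not in adj_b:
            return True
    # R2: a -> c -> b
    for c in g.children(a):
        if c != b and g.is_directed_edge(c, b):
            return True
    # R3: a - c -> b, a - d -> b with c, d nonadjacent
    cands = [c for c in g.undirected_neighbors(a)
             if c != b and g.is_directed_edge(c, b)]
    for c, d in itertools.combinations(sorted(cands), 2):
        if not g.has_edge(c, d):
            return True
    # R4: a - c, c -> d, d -> b, with b and c nonadjacent
    for c in g.undirected_neighbors(a):
        if c == b or c in adj_b:
            continue
        for d in g.children(c):
            if d != a and d != b and g.is_directed_edge(d, b):
                return True
    return False


def apply_meek_rules(g: MixedGraph,
                     bk: BackgroundKnowledge | None = None) -> MixedGraph:
    """Apply Meek orientation rules R1-R4 to a fixed point."""
    g = g.copy()
    while _meek_pass(g, bk):
        pass
    return g


def apply_background_knowledge(g: MixedGraph,
                               bk: BackgroundKnowledge) -> MixedGraph:
    """Direct every edge between an exogenous node and a non-exogenous
    node outward from the exogenous node (edges between two exogenous
    nodes stay as they are), apply explicit required directions, then
    re-run the Meek rules.

    Raises :class:`OrientationConflictError` when a required direction
    contradicts an orientation already fixed by a v-structure.
    """
    for n in bk.exogenous_nodes:
        if n not in g:
            raise KeyError(f"background-knowledge node {n!r} not in graph")
    g = g.copy()
    required = set(bk.required_directions)
    for u, v, mark in sorted(g.edges()):
        for e, m in ((u, v), (v, u)):
            if e in bk.exogenous_nodes and m not in bk.exogenous_nodes:
                required.add((e, m))
    for a, b in sorted(required):
        if not g.has_edge(a, b):
            continue
        if g.is_directed_edge(b, a):
            raise OrientationConflictError(
                f"required direction {a!r} -> {b!r} contradicts the "
                f"existing orientation {b!r} -> {a!r}")
        if g.mark(a, b) == UNDIRECTED:
            g.orient(a, b)
    return apply_meek_rules(g, bk)


def dag_to_cpdag(dag: nx.DiGraph) -> MixedGraph:
    """Completed partially directed acyclic graph of a DAG's Markov
    equivalence class: skeleton, v-structures, Meek closure."""
    g = MixedGraph(sorted(dag.nodes))
    for u, v in dag.edges:
        g.add_edge(u, v, UNDIRECTED)
    for z in dag.nodes:
        parents = sorted(dag.predecessors(z))
        for x, y in itertools.combinations(parents, 2):
            if not (dag.has_edge(x, y) or dag.has_edge(y, x)):
                g.orient(x, z)
                g.orient(y, z)
    return apply_meek_rules(g)


# ---------------------------------------------------------------------------
# model selection and stability
# ---------------------------------------------------------------------------

DEFAULT_ALPHA_GRID = (1e-2, 1e-3, 1e-4, 1e-5)


def _learn_cpdag(data: pd.DataFrame, alpha: float, max_cond_size: int,
                 bk: BackgroundKnowledge | None) -> MixedGraph:
    g = pc_skeleton(data, alpha, max_cond_size)
    g = orient_v_structures(g, bk=bk)
    if bk is not None:
        g = apply_background_knowledge(g, bk)
    return apply_meek_rules(g, bk)


def select_alpha(data: pd.DataFrame,
                 candidate_alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
                 n_splits: int = 5,
                 seed: int = 0,
                 max_cond_size: int = 3,
                 bk: BackgroundKnowledge | None = None) -> float:
    """Choose the CI-test significance level by split-half reproducibility.

    For each candidate the samples are split into random halves
    ``n_splits`` times, a network is learned on each half, and the mean
    structural Hamming distance between the half-networks is recorded;
    the candidate with minimal mean SHD wins (ties favor the smaller,
    i.e. more conservative, level).
    """
    cands = sorted(set(candidate_alphas))
    if len(cands) < 1:
        raise ValueError("need at least one candidate alpha")
    for a in cands:
        if not 0 < a < 1:
            raise ValueError(f"candidate alpha {a} outside (0,1)")
    if len(cands) == 1:
        return cands[0]
    n = len(data)
    if n < 40:
        raise ValueError("need at least 40 samples for split-half selection")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        splits.append((perm[: n // 2], perm[n // 2:]))
    best_alpha, best_score = None, math.inf
    for a in cands:
        dists = []
        for ia, ib in splits:
            ga = _learn_cpdag(data.iloc[ia], a, max_cond_size, bk)
            gb = _learn_cpdag(data.iloc[ib], a, max_cond_size, bk)
            dists.append(shd(ga, gb))
        score = float(np.mean(dists))
        if score < best_score or (score == best_score and a < best_alpha):
            best_alpha, best_score = a, score
    return best_alpha


def direction_stability(data: pd.DataFrame, g: MixedGraph,
                        bk: BackgroundKnowledge | None,
                        alpha: float,
                        n_reductions: int = 100,
                        drop_fraction: float = 0.2,
                        tau: float = 0.9,
                        seed: int = 0,
                        max_cond_size: int = 3) -> MixedGraph:
    """Variable-reduction test of direction stability.

    The network is re-learned ``n_reductions`` times after removing a
    random ``drop_fraction`` of the variables.  A directed edge u -> v
    keeps its direction when it is oriented the same way in at least
    ``tau`` of the reductions that retained both endpoints; otherwise it
    is downgraded to a bidirected edge, flagging the direction as
    unidentified.  No metabolite is ever removed from the returned graph.
    Directions forced by background knowledge are exempt (the constraint
    survives any reduction).
    """
    if not 0 < drop_fraction < 1:
        raise ValueError(f"drop_fraction must lie in (0,1), got {drop_fraction}")
    cols = list(data.columns)
    directed = [(u, v) for u, v, m in g.edges() if m == DIRECTED]
    forced = set()
    if bk is not None:
        for u, v in directed:
            if u in bk.exogenous_nodes or (u, v) in bk.required_directions:
                forced.add((u, v))
    tested = [e for e in directed if e not in forced]
    if not tested:
        return g.copy()
    rng = np.random.default_rng(seed)
    n_drop = max(1, int(round(drop_fraction * len(cols))))
    same = {e: 0 for e in tested}
    seen = {e: 0 for e in tested}
    for _ in range(n_reductions):
        drop = set(rng.choice(len(cols), size=n_drop, replace=False))
        keep = [c for i, c in enumerate(cols) if i not in drop]
        sub_bk = None
        if bk is not None:
            sub_bk = BackgroundKnowledge(
                exogenous_nodes=frozenset(k for k in bk.exogenous_nodes
                                          if k in keep),
                required_directions=frozenset(
                    (a, b) for a, b in bk.required_directions
                    if a in keep and b in keep))
        sub = _learn_cpdag(data[keep], alpha, max_cond_size, sub_bk)
        kept = set(keep)
        for (u, v) in tested:
            if u in kept and v in kept:
                seen[(u, v)] += 1
                if sub.is_directed_edge(u, v):
                    same[(u, v)] += 1
    out = g.copy()
    for (u, v) in tested:
        if seen[(u, v)] and same[(u, v)] / seen[(u, v)] < tau:
            out.set_bidirected(u, v)
    return out


def learn_network(data: pd.DataFrame,
                  bk: BackgroundKnowledge | None = None,
                  alpha: float | str = 1e-4,
                  max_cond_size: int = 3,
                  stability: bool = False,
                  n_reductions: int = 100,
                  drop_fraction: float = 0.2,
                  tau: float = 0.9,
                  seed: int = 0,
                  candidate_alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
                  ) -> MixedGraph:
    """Full network-learning pipeline on residualized metabolite data.

    Skeleton (PC-stable) -> v-structures -> background knowledge ->
    Meek rules -> optional variable-reduction stability.  ``alpha`` may
    be the string ``"auto"`` to trigger split-half SHD selection.
    """
    if alpha == "auto":
        alpha = select_alpha(data, candidate_alphas, seed=seed,
                             max_cond_size=max_cond_size, bk=bk)
    alpha = float(alpha)
    g = pc_skeleton(data, alpha, max_cond_size)
    sepsets, pvals = g.separating_sets, g.edge_pvalues
    g = orient_v_structures(g, bk=bk)
    if bk is not None:
        g = apply_background_knowledge(g, bk)
    g = apply_meek_rules(g, bk)
    if stability:
        g = direction_stability(data, g, bk, alpha,
                                n_reductions=n_reductions,
                                drop_fraction=drop_fraction, tau=tau,
                                seed=seed, max_cond_size=max_cond_size)
    g.separating_sets = sepsets
    g.edge_pvalues = pvals
    if not g.is_acyclic():
        raise RuntimeError("directed part of the learned network is cyclic")
    return g
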