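import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from _oracles import (cpdag_by_enumeration, maximally_oriented_by_extension,
                      random_dag, vstructures)
from metabonet.graph import (DIRECTED, UNDIRECTED, BackgroundKnowledge,
                             MixedGraph, _pair, shd)
from metabonet.network import (DSeparationOracle, GaussianCITest,
                               OrientationConflictError,
                               apply_background_knowledge, apply_meek_rules,
                               ci_test, dag_to_cpdag, direction_stability,
                               fisher_z_pvalue, learn_network,
                               orient_v_structures, partial_correlation,
                               pc_skeleton, select_alpha)

from conftest import sem_data, small_config


def oracle_cpdag_learn(dag: nx.DiGraph) -> MixedGraph:
    g = pc_skeleton(DSeparationOracle(dag), alpha=0.5)
    g = orient_v_structures(g)
    return apply_meek_rules(g)


class TestPartialCorrelation:
    def test_duplicate_column_gives_unity(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"x": x, "y": x.copy()})
        assert partial_correlation("x", "y", [], df) == pytest.approx(1.0)

    def test_chain_vanishes_given_middle(self, rng):
        n = 10000
        x = rng.normal(size=n)
        z = x + rng.normal(size=n)
        y = z + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        assert abs(partial_correlation("x", "y", ["z"], df)) < 0.05

    def test_equals_residual_correlation(self, rng):
        """Partial correlation given Z must match the correlation of the
        OLS residuals of x and y on Z."""
        n = 300
        df = pd.DataFrame(rng.normal(size=(n, 5)),
                          columns=list("abcde"))
        Z = ["c", "d", "e"]
        X = np.column_stack([np.ones(n), df[Z].to_numpy()])
        rx = df["a"] - X @ np.linalg.lstsq(X, df["a"], rcond=None)[0]
        ry = df["b"] - X @ np.linalg.lstsq(X, df["b"], rcond=None)[0]
        expected = np.corrcoef(rx, ry)[0, 1]
        got = partial_correlation("a", "b", Z, df)
        assert got == pytest.approx(expected, abs=1e-10)


class TestFisherZ:
    def test_zero_correlation_gives_p_one(self):
        assert fisher_z_pvalue(0.0, 100, 0) == pytest.approx(1.0)

    def test_textbook_value(self):
        # r = 0.5, n = 103, |Z| = 0: statistic sqrt(100)*atanh(0.5)
        stat = np.sqrt(100) * np.arctanh(0.5)
        assert stat == pytest.approx(5.493, abs=5e-4)
        p = fisher_z_pvalue(0.5, 103, 0)
        assert p == pytest.approx(3.9e-8, rel=0.05)

    def test_monotone_in_correlation(self):
        ps = [fisher_z_pvalue(r, 200, 1) for r in (0.1, 0.2, 0.4, 0.8)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_pvalue(0.3, 5, 2)

    def test_ci_test_flags_independence_against_alpha(self, rng):
        x = rng.normal(size=500)
        df = pd.DataFrame({"x": x, "y": x + 0.1 * rng.normal(size=500),
                           "z": rng.normal(size=500)})
        p_dep, indep_dep = ci_test("x", "y", [], df, alpha=1e-4)
        p_ind, indep_ind = ci_test("x", "z", [], df, alpha=1e-4)
        assert not indep_dep and p_dep < 1e-4
        assert indep_ind and p_ind > 1e-4


class TestSkeletonWithOracle:
    def test_chain(self):
        dag = nx.DiGraph([("A", "B"), ("B", "C")])
        g = pc_skeleton(DSeparationOracle(dag), alpha=0.5)
        assert {(u, v) for u, v, _ in g.edges()} == {("A", "B"), ("B", "C")}
        assert g.separating_sets[_pair("A", "C")] == {"B"}

    def test_collider(self):
        dag = nx.DiGraph([("A", "C"), ("B", "C")])
        g = pc_skeleton(DSeparationOracle(dag), alpha=0.5)
        assert {(u, v) for u, v, _ in g.edges()} == {("A", "C"), ("B", "C")}
        assert g.separating_sets[_pair("A", "B")] == set()

    def test_matches_true_skeleton_on_random_dags(self, rng):
        for _ in range(20):
            dag = random_dag(8, 0.3, rng)
            g = pc_skeleton(DSeparationOracle(dag), alpha=0.5,
                            max_cond_size=7)
            assert set(map(frozenset, g.skeleton().edges)) == \
                set(map(frozenset, dag.to_undirected().edges))

    def test_alpha_validation(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            pc_skeleton(df, alpha=1.5)


class TestOrientation:
    def test_collider_oriented_chain_not(self):
        dag = nx.DiGraph([("A", "C"), ("B", "C")])
        g = orient_v_structures(pc_skeleton(DSeparationOracle(dag), 0.5))
        assert g.is_directed_edge("A", "C") and g.is_directed_edge("B", "C")
        chain = nx.DiGraph([("A", "B"), ("B", "C")])
        g2 = orient_v_structures(pc_skeleton(DSeparationOracle(chain), 0.5))
        assert all(m == UNDIRECTED for *_, m in g2.edges())

    def test_vstructures_match_truth_on_random_dags(self, rng):
        for _ in range(20):
            dag = random_dag(7, 0.3, rng)
            g = orient_v_structures(
                pc_skeleton(DSeparationOracle(dag), 0.5, max_cond_size=6))
            got = set()
            for z in g.nodes:
                for x, y in itertools.combinations(sorted(g.parents(z)), 2):
                    if not g.has_edge(x, y):
                        got.add((frozenset((x, y)), z))
            assert got == vstructures(dag)

    def test_conflict_majority_and_ties(self):
        # two triples voting opposite ways on the same edge: tie stays
        # undirected
        g = MixedGraph("abcd")
        for e in (("a", "c"), ("b", "c"), ("c", "d")):
            g.add_edge(*e, UNDIRECTED)
        seps = {_pair("a", "b"): frozenset(),   # a->c<-b votes c into collider
                _pair("a", "d"): frozenset()}   # a->c<-d votes too
        out = orient_v_structures(g, separating_sets=seps)
        # votes: (a,c):2, (b,c):1, (d,c):1 -> a->c oriented
        assert out.is_directed_edge("a", "c")


class TestMeekRules:
    def test_r1_propagates(self):
        g = MixedGraph("abc")
        g.add_edge("a", "b", DIRECTED)
        g.add_edge("b", "c", UNDIRECTED)
        out = apply_meek_rules(g)
        assert out.is_directed_edge("b", "c")

    def test_undirected_triangle_unchanged(self):
        g = MixedGraph("abc")
        for e in itertools.combinations("abc", 2):
            g.add_edge(*e, UNDIRECTED)
        assert apply_meek_rules(g) == g

    def test_equals_extension_oracle_on_random_pdags(self, rng):
        """Meek closure orients exactly the edges that share one
        direction across all consistent DAG extensions."""
        for _ in range(40):
            dag = random_dag(6, 0.35, rng)
            start = MixedGraph(sorted(dag.nodes))
            for u, v in dag.edges:
                start.add_edge(u, v, UNDIRECTED)
            for (pair, z) in vstructures(dag):
                x, y = sorted(pair)
                start.orient(x, z)
                start.orient(y, z)
            assert apply_meek_rules(start) == \
                maximally_oriented_by_extension(start)


class TestBackgroundKnowledge:
    def test_exogenous_edge_directed_outward(self):
        # a threonine-like essential amino acid adjacent to asparagine
        g = MixedGraph(["threonine", "asparagine"])
        g.add_edge("threonine", "asparagine", UNDIRECTED)
        bk = BackgroundKnowledge(exogenous_nodes=frozenset({"threonine"}))
        out = apply_background_knowledge(g, bk)
        assert out.is_directed_edge("threonine", "asparagine")

    def test_factor_edges_and_exogenous_pairs(self):
        g = MixedGraph(["F", "M", "lys", "thr"])
        g.add_edge("F", "M", UNDIRECTED)
        g.add_edge("lys", "thr", UNDIRECTED)
        bk = BackgroundKnowledge(
            exogenous_nodes=frozenset({"F", "lys", "thr"}))
        out = apply_background_knowledge(g, bk)
        assert out.is_directed_edge("F", "M")
        assert out.mark("lys", "thr") == UNDIRECTED

    def test_conflict_with_vstructure_raises(self):
        g = MixedGraph("abc")
        g.add_edge("a", "c", DIRECTED)
        g.add_edge("b", "c", DIRECTED)
        bk = BackgroundKnowledge(
            required_directions=frozenset({("c", "a")}))
        with pytest.raises(OrientationConflictError):
            apply_background_knowledge(g, bk)


class TestDagToCpdag:
    def test_matches_markov_equivalence_enumeration(self, rng):
        """dag_to_cpdag (v-structures + Meek) must agree with brute-force
        enumeration of the Markov equivalence class."""
        for _ in range(30):
            dag = random_dag(6, 0.35, rng)
            assert dag_to_cpdag(dag) == cpdag_by_enumeration(dag)


class TestSelectAlpha:
    def test_single_candidate_returned(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        assert select_alpha(df, [1e-3], seed=0) == 1e-3

    def test_default_grid_contains_operating_threshold(self):
        from metabonet.network import DEFAULT_ALPHA_GRID
        assert 1e-4 in DEFAULT_ALPHA_GRID

    def test_invalid_candidate_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            select_alpha(df, [1e-3, 2.0], seed=0)

    def test_selected_alpha_reproduces_strong_truth(self):
        cfg = small_config(5, n_met=8, n=2000, edge_density=0.25,
                           coef_range=(0.7, 0.9), min_edge_pcor=0.4)
        data, truth, *_ = sem_data(cfg)
        a = select_alpha(data, (1e-2, 1e-4), n_splits=3, seed=0)
        g = learn_network(data, alpha=a)
        assert shd(g, dag_to_cpdag(truth.metabolite_dag())) <= 2


class TestDirectionStability:
    def test_bk_forced_edges_always_stable(self):
        cfg = small_config(7, n_met=6, n=800, edge_density=0.3)
        data, truth, *_ = sem_data(cfg)
        bk = BackgroundKnowledge(exogenous_nodes=truth.exogenous_nodes)
        g = learn_network(data, bk=bk, alpha=1e-3)
        out = direction_stability(data, g, bk, alpha=1e-3, n_reductions=10,
                                  seed=0)
        for u, v, m in g.edges():
            if m == DIRECTED and u in truth.exogenous_nodes:
                assert out.is_directed_edge(u, v)

    def test_chance_orientation_downgraded_to_bidirected(self, rng):
        # a two-node dependence is Markov-reversible: force a direction
        # and the reduction test must flag it as unidentified, keeping
        # the edge rather than removing it
        n = 1500
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": x + rng.normal(size=n),
                           "u": rng.normal(size=n),
                           "v": rng.normal(size=n)})
        g = learn_network(df, alpha=1e-3)
        g.orient("x", "y")  # pretend the direction had been identified
        out = direction_stability(df, g, None, alpha=1e-3,
                                  n_reductions=20, seed=1)
        assert out.has_edge("x", "y")
        assert out.mark("x", "y") == "bidirected"

    def test_drop_fraction_validated(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        g = learn_network(df, alpha=1e-3)
        with pytest.raises(ValueError):
            direction_stability(df, g, None, 1e-3, drop_fraction=1.5)


class TestLearnNetwork:
    def test_null_data_nearly_empty(self):
        counts = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(2500, 40)),
                              columns=[f"m{i:02d}" for i in range(40)])
            counts.append(learn_network(df, alpha=1e-4).n_edges())
        assert sum(counts) <= 2

    def test_planted_chain_recovered(self):
        rng = np.random.default_rng(11)
        n = 2500
        cols = {}
        prev = rng.normal(size=n)
        cols["m0"] = prev
        for i in range(1, 5):
            prev = 0.8 * prev + rng.normal(size=n)
            cols[f"m{i}"] = prev
        df = pd.DataFrame(cols)
        g = learn_network(df, alpha=1e-4)
        expected = {frozenset((f"m{i}", f"m{i+1}")) for i in range(4)}
        assert set(map(frozenset, g.skeleton().edges)) == expected

    def test_column_permutation_invariance(self):
        cfg = small_config(3, n_met=8, n=1200, edge_density=0.25)
        data, *_ = sem_data(cfg)
        g1 = learn_network(data, alpha=1e-3)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(data.columns))
        g2 = learn_network(data[perm], alpha=1e-3)
        assert g1 == g2

    def test_edge_pvalues_below_alpha(self):
        cfg = small_config(9, n_met=8, n=1500, edge_density=0.25)
        data, *_ = sem_data(cfg)
        alpha = 1e-3
        g = learn_network(data, alpha=alpha)
        assert g.edge_pvalues  # recorded
        for pr, p in g.edge_pvalues.items():
            assert p <= alpha

    def test_exogenous_nodes_stay_sources(self):
        cfg = small_config(13, n_met=10, n=1500, edge_density=0.25)
        data, truth, *_ = sem_data(cfg)
        bk = BackgroundKnowledge(exogenous_nodes=truth.exogenous_nodes)
        g = learn_network(data, bk=bk, alpha=1e-3)
        for e in truth.exogenous_nodes:
            assert not g.parents(e)
            for m in g.undirected_neighbors(e):
                assert m in truth.exogenous_nodes
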