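import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_bruteforce
from metabonet.associate import (AssociationRecord, SurvivalData,
                                 adjusted_association, assemble_results,
                                 bh_fdr, fit_cox, identify_confounders,
                                 univariable_screen)
from metabonet.graph import DIRECTED, UNDIRECTED, MixedGraph


def make_survival(rng, n=800, beta=None, data=None, censor_q=0.25,
                  time_varying=None):
    cov = pd.DataFrame({
        "age": rng.normal(55, 10, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "bmi": rng.normal(27, 4, n),
    }, index=[f"s{i}" for i in range(n)])
    eta = 0.02 * (cov["age"] - 55)
    if beta and data is not None:
        for m, b in beta.items():
            eta = eta + b * data[m]
    t = rng.exponential(np.exp(-eta))
    if time_varying is not None:
        m, b = time_varying
        # effect that switches on late in follow-up violates PH
        t = np.where(data[m] > 0, t ** (1 / (1 + abs(b))), t)
    c = np.quantile(t, censor_q)
    return SurvivalData(
        time=pd.Series(np.minimum(t, c) + 1e-9, index=cov.index),
        event=pd.Series((t <= c).astype(int), index=cov.index),
        covariates=cov)


def std_cols(rng, n, names):
    return pd.DataFrame(
        {m: rng.normal(size=n) for m in names},
        index=[f"s{i}" for i in range(n)])


class TestFitCox:
    def test_time_rescaling_leaves_estimates_unchanged(self, rng):
        data = std_cols(rng, 800, ["m"])
        surv = make_survival(rng, beta={"m": 0.4}, data=data)
        res1 = fit_cox(surv, ["m", "age"], data, check_ph=False)
        doubled = SurvivalData(time=2 * surv.time, event=surv.event,
                               covariates=surv.covariates)
        res2 = fit_cox(doubled, ["m", "age"], data, check_ph=False)
        assert np.allclose(res1.effects, res2.effects, atol=1e-8)

    def test_recovers_planted_effect(self, rng):
        data = std_cols(rng, 2500, ["m"])
        surv = make_survival(rng, n=2500, beta={"m": 0.3}, data=data,
                             censor_q=0.12)
        res = fit_cox(surv, ["m", "age", "sex", "bmi"], data,
                      check_ph=False)
        assert res.effects["m"] == pytest.approx(0.3, abs=3 * res.se["m"])

    def test_few_events_rejected(self, rng):
        data = std_cols(rng, 50, ["m"])
        surv = make_survival(rng, n=50, censor_q=0.1, data=data)
        with pytest.raises(ValueError, match="events"):
            fit_cox(surv, ["m"], data)

    def test_zero_variance_term_rejected(self, rng):
        data = std_cols(rng, 300, ["m"])
        data["flat"] = 1.0
        surv = make_survival(rng, n=300, data=data)
        with pytest.raises(ValueError, match="flat"):
            fit_cox(surv, ["m", "flat"], data)

    def test_ph_violation_flagged_only_for_nonproportional_term(self, rng):
        data = std_cols(rng, 2000, ["ok", "bad"])
        surv = make_survival(rng, n=2000, beta={"ok": 0.3, "bad": 0.8},
                             data=data, censor_q=0.4,
                             time_varying=("bad", 0.8))
        res = fit_cox(surv, ["ok", "bad"], data, check_ph=True)
        assert bool(res.ph_violation["bad"])


class TestUnivariableScreen:
    def test_row_count_and_planted_flag(self, rng):
        data = std_cols(rng, 1500, [f"m{i}" for i in range(6)])
        surv = make_survival(rng, n=1500, beta={"m0": 0.5}, data=data,
                             censor_q=0.15)
        tab = univariable_screen(surv, data)
        assert len(tab) == 6
        assert bool(tab.loc["m0", "flagged"])


def targinine_graph():
    g = MixedGraph(["targinine", "ornithine", "dimethylglycine",
                    "isoleucine", "other"])
    g.add_edge("ornithine", "targinine", DIRECTED)
    g.add_edge("dimethylglycine", "targinine", DIRECTED)
    g.add_edge("targinine", "other", UNDIRECTED)
    return g


def screen_frame(flags: dict) -> pd.DataFrame:
    return pd.DataFrame({"effect": 0.1, "se": 0.05, "p": 0.01,
                         "flagged": pd.Series(flags)})


class TestIdentifyConfounders:
    def test_worked_example_both_parents(self):
        screen = screen_frame({"ornithine": True, "dimethylglycine": True,
                               "targinine": True, "isoleucine": True,
                               "other": False})
        got = identify_confounders("targinine", targinine_graph(), screen)
        assert got == {"ornithine", "dimethylglycine"}

    def test_unflagged_parent_excluded(self):
        screen = screen_frame({"ornithine": True,
                               "dimethylglycine": False,
                               "targinine": True, "isoleucine": True,
                               "other": False})
        got = identify_confounders("targinine", targinine_graph(), screen)
        assert got == {"ornithine"}

    def test_source_metabolite_unconfounded(self):
        screen = screen_frame({n: True for n in targinine_graph().nodes})
        assert identify_confounders("isoleucine", targinine_graph(),
                                    screen) == frozenset()

    def test_conservative_mode_adds_unoriented_neighbors(self):
        screen = screen_frame({n: True for n in targinine_graph().nodes})
        got = identify_confounders("other", targinine_graph(), screen,
                                   conservative=True)
        assert got == {"targinine"}
        assert identify_confounders("other", targinine_graph(),
                                    screen) == frozenset()

    def test_ancestor_mode_reaches_beyond_parents(self):
        g = MixedGraph(["a", "b", "c"])
        g.add_edge("a", "b", DIRECTED)
        g.add_edge("b", "c", DIRECTED)
        screen = screen_frame({"a": True, "b": True, "c": True})
        assert identify_confounders("c", g, screen) == {"b"}
        assert identify_confounders("c", g, screen,
                                    ancestors=True) == {"a", "b"}

    def test_unknown_target_raises(self):
        with pytest.raises(KeyError):
            identify_confounders("nope", targinine_graph(),
                                 screen_frame({}))


class TestAdjustedAssociation:
    def confounded_null(self, seed, n=2000):
        rng = np.random.default_rng(seed)
        C = rng.normal(size=n)
        M = 0.7 * C + rng.normal(size=n)
        data = pd.DataFrame({"C": C, "M": M},
                            index=[f"s{i}" for i in range(n)])
        data = (data - data.mean()) / data.std(ddof=1)
        surv = make_survival(rng, n=n, beta={"C": 0.4}, data=data,
                             censor_q=0.15)
        g = MixedGraph(["C", "M"])
        g.add_edge("C", "M", DIRECTED)
        screen = univariable_screen(surv, data)
        return data, surv, g, screen

    def test_adjustment_absorbs_confounded_signal(self):
        data, surv, g, screen = self.confounded_null(3)
        rec = adjusted_association("M", surv, data, g, screen)
        assert rec.confounders_adjusted == {"C"}
        unadj = fit_cox(surv, ["M", "age", "sex", "bmi"], data,
                        check_ph=False)
        assert abs(rec.effect_size) < abs(unadj.effects["M"])

    def test_hr_effect_consistency_enforced(self):
        with pytest.raises(ValueError):
            AssociationRecord("m", hazard_ratio=2.0, effect_size=0.1,
                              se=0.05, p_value=0.5,
                              confounders_adjusted=frozenset(),
                              covariates_adjusted=(), out_degree=0,
                              in_degree=0)
        rec = AssociationRecord("m", hazard_ratio=math.exp(-0.17),
                                effect_size=-0.17, se=0.06, p_value=0.009,
                                confounders_adjusted=frozenset(),
                                covariates_adjusted=("age",),
                                out_degree=4, in_degree=1)
        assert rec.hazard_ratio == pytest.approx(0.8437, abs=5e-5)

    def test_collinear_confounder_rejected(self, rng):
        n = 500
        C = rng.normal(size=n)
        data = pd.DataFrame({"C": C, "M": C + 1e-6 * rng.normal(size=n)},
                            index=[f"s{i}" for i in range(n)])
        surv = make_survival(rng, n=n, data=data)
        g = MixedGraph(["C", "M"])
        g.add_edge("C", "M", DIRECTED)
        screen = screen_frame({"C": True, "M": True})
        with pytest.raises(ValueError, match="collinear"):
            adjusted_association("M", surv, data, g, screen)


class TestBenjaminiHochberg:
    def test_single_small_p_rejected(self):
        reject, cutoff = bh_fdr([0.04], q=0.1)
        assert reject.all() and cutoff == 0.04

    def test_step_up_by_hand(self):
        reject, cutoff = bh_fdr([0.01, 0.02, 0.9], q=0.1)
        assert list(reject) == [True, True, False]
        assert cutoff == 0.02

    def test_empty_and_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([], 0.1)
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], 0.1)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40),
           st.sampled_from([0.05, 0.1, 0.2]))
    def test_matches_bruteforce_step_up(self, ps, q):
        reject, _ = bh_fdr(ps, q)
        assert (reject == bh_bruteforce(ps, q)).all()

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_monotone_in_q(self, ps):
        r1, _ = bh_fdr(ps, 0.05)
        r2, _ = bh_fdr(ps, 0.2)
        assert (~r1 | r2).all()  # rejections at smaller q are a subset


class TestAssembleResults:
    def record(self, m, eff, p, out_d=0, in_d=0):
        return AssociationRecord(m, hazard_ratio=math.exp(eff),
                                 effect_size=eff, se=0.06, p_value=p,
                                 confounders_adjusted=frozenset({"x"}),
                                 covariates_adjusted=("age", "sex", "bmi"),
                                 out_degree=out_d, in_degree=in_d)

    def test_table_shape_and_rendering(self):
        recs = [self.record("glycine-like", -0.17, 0.009, out_d=4, in_d=1),
                self.record("gca-like", 0.21, 0.001, out_d=(0, 2),
                            in_d=(0, 2)),
                self.record("null-like", 0.01, 0.9)]
        tab = assemble_results(recs, platform={"glycine-like": "AAA",
                                               "gca-like": "BONS",
                                               "null-like": "BONS"})
        row = tab[tab.metabolite == "glycine-like"].iloc[0]
        assert row.hazard_ratio == pytest.approx(0.8437, abs=5e-5)
        assert row.out_degree == "4"
        gca = tab[tab.metabolite == "gca-like"].iloc[0]
        assert gca.out_degree == "0 or 2"
        assert bool(gca.fdr_significant)
        assert not bool(tab[tab.metabolite == "null-like"]
                        .iloc[0].fdr_significant)
        # sorted by platform then p
        assert list(tab.platform) == ["AAA", "BONS", "BONS"]

    def test_empty_records_give_header_only(self, tmp_path):
        tab = assemble_results([])
        assert len(tab) == 0
        path = tmp_path / "res.tsv"
        tab.to_csv(path, sep="\t", index=False)
        assert path.read_text().strip().startswith("metabolite\t")
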