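"""Metabolite → heart-failure association with network-guided confounder
adjustment.

The hazard model is a Cox proportional-hazards regression
``ln H(t; X, Z) = ln h0(t) + θX + βZ`` with covariates X (age, sex, BMI)
and metabolites Z.  A metabolite C is treated as a confounder for target
M when the learned network contains the directed edge C -> M (network
evidence at the graph's significance level) and C itself is associated
with the outcome in a univariable screen (p < 0.05).  The adjusted model
for M then includes M, its confounders, and the covariates; significance
is declared by Benjamini-Hochberg FDR at q = 0.1 on the realized
p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from statsmodels.stats.multitest import multipletests

from .graph import MixedGraph
from .preprocess import MetaboliteMatrix

DEFAULT_COVARIATES = ("age", "sex", "bmi")
SCREEN_ALPHA = 0.05
FDR_Q = 0.1


@dataclass(frozen=True)
class SurvivalData:
    """Per-sample follow-up time (years), event indicator and covariates."""

    time: pd.Series
    event: pd.Series
    covariates: pd.DataFrame

    def __post_init__(self):
        if (self.time <= 0).any():
            bad = self.time.index[self.time <= 0][0]
            raise ValueError(f"nonpositive follow-up time for sample {bad!r}")
        if not self.event.isin((0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        if not (self.time.index.equals(self.event.index)
                and self.time.index.equals(self.covariates.index)):
            raise ValueError("time, event and covariates must share the "
                             "same sample index")

    @property
    def sample_ids(self) -> list:
        return list(self.time.index)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def frame(self) -> pd.DataFrame:
        out = self.covariates.copy()
        out["time"] = self.time
        out["event"] = self.event
        return out


@dataclass(frozen=True)
class CoxResult:
    """Per-term Cox estimates plus proportional-hazards diagnostics."""

    effects: pd.Series
    se: pd.Series
    p: pd.Series
    ph_pvalues: pd.Series
    ph_violation: pd.Series  # flag only; the fit is still returned
    n: int
    n_events: int


@dataclass(frozen=True)
class AssociationRecord:
    """One metabolite's outcome association in the adjusted model."""

    metabolite_id: str
    hazard_ratio: float
    effect_size: float
    se: float
    p_value: float
    confounders_adjusted: frozenset
    covariates_adjusted: tuple
    out_degree: object  # int or (low, high) interval
    in_degree: object
    fdr_significant: bool = False

    def __post_init__(self):
        if not math.isclose(self.hazard_ratio, math.exp(self.effect_size),
                            rel_tol=1e-10):
            raise ValueError("hazard ratio must equal exp(effect size)")
        if self.se <= 0:
            raise ValueError("standard error must be positive")


def _assemble_frame(survival: SurvivalData, terms: Sequence[str],
                    data: pd.DataFrame | None) -> pd.DataFrame:
    cols = {}
    for t in terms:
        if data is not None and t in data.columns:
            cols[t] = data[t]
        elif t in survival.covariates.columns:
            cols[t] = survival.covariates[t]
        else:
            raise KeyError(f"term {t!r} found in neither data nor covariates")
    df = pd.DataFrame(cols, index=survival.time.index)
    if df.isna().to_numpy().any():
        raise ValueError("missing values in the Cox design")
    df["time"] = survival.time
    df["event"] = survival.event
    return df


def fit_cox(survival: SurvivalData, terms: Sequence[str],
            data: pd.DataFrame | None = None,
            check_ph: bool = True) -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling) for the named
    terms, with a Schoenfeld-residual proportionality test per term.

    A PH-test p-value below 0.05 sets the violation flag for that term;
    estimates are returned regardless.
    """
    terms = list(terms)
    if survival.n_events < 10:
        raise ValueError(f"need at least 10 events, have {survival.n_events}")
    df = _assemble_frame(survival, terms, data)
    X = df[terms].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError(f"zero-variance term {terms[int(np.argmin(sd))]!r}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(terms):
        raise ValueError("rank-deficient Cox design")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    summ = cph.summary
    if check_ph:
        ph = proportional_hazard_test(cph, df, time_transform="rank")
        ph_p = ph.summary["p"]
        ph_p.index = ph_p.index.get_level_values(0)
        ph_p = ph_p.reindex(terms)
    else:
        ph_p = pd.Series(np.nan, index=terms)
    return CoxResult(
        effects=summ["coef"].reindex(terms),
        se=summ["se(coef)"].reindex(terms),
        p=summ["p"].reindex(terms),
        ph_pvalues=ph_p,
        ph_violation=ph_p < 0.05,
        n=len(df),
        n_events=survival.n_events,
    )


def univariable_screen(survival: SurvivalData,
                       metabolites: MetaboliteMatrix | pd.DataFrame,
                       covariates: Sequence[str] = DEFAULT_COVARIATES,
                       screen_alpha: float = SCREEN_ALPHA,
                       check_ph: bool = False) -> pd.DataFrame:
    """One covariate-adjusted Cox fit per metabolite.

    Returns a table indexed by metabolite with columns effect, se, p and
    a ``flagged`` indicator (p < ``screen_alpha``), the outcome side of
    the confounding-metabolite definition.
    """
    data = metabolites.data if isinstance(metabolites, MetaboliteMatrix) \
        else metabolites
    rows = {}
    for m in data.columns:
        res = fit_cox(survival, [m, *covariates], data, check_ph=check_ph)
        rows[m] = (res.effects[m], res.se[m], res.p[m])
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["effect", "se", "p"])
    out.index.name = "metabolite"
    out["flagged"] = out["p"] < screen_alpha
    return out


def identify_confounders(target: str, g: MixedGraph,
                         screen: pd.DataFrame,
                         conservative: bool = False,
                         ancestors: bool = False) -> frozenset:
    """Confounding metabolites for ``target``: directed metabolite
    parents in the network (edge retained at the network's significance
    level) that are themselves flagged in the univariable outcome screen.

    With ``conservative=True``, undirected and bidirected neighbors are
    also admitted (directions unresolved, so treated as potential
    parents); with ``ancestors=True``, all directed ancestors qualify,
    not just parents.
    """
    if target not in g:
        raise KeyError(f"unknown target metabolite {target!r}")
    flagged = set(screen.index[screen["flagged"]])
    if ancestors:
        import networkx as nx
        cands = set(nx.ancestors(g.directed_part(), target))
    else:
        cands = set(g.parents(target))
    cands = {p for p in cands if g.kind(p) == "metabolite"}
    if conservative:
        cands |= {p for p in (g.undirected_neighbors(target)
                              | g.bidirected_neighbors(target))
                  if g.kind(p) == "metabolite"}
    return frozenset(cands & flagged)


def _degree_pair(g: MixedGraph, node: str) -> tuple:
    """(out, in) degrees over directed metabolite edges; intervals when
    the node has incident undirected/bidirected edges."""
    from .properties import _node_degrees
    out_d, in_d, _ = _node_degrees(g, node)
    return out_d, in_d


def adjusted_association(target: str, survival: SurvivalData,
                         metabolites: MetaboliteMatrix | pd.DataFrame,
                         g: MixedGraph, screen: pd.DataFrame,
                         covariates: Sequence[str] = DEFAULT_COVARIATES,
                         conservative: bool = False,
                         ancestors: bool = False) -> AssociationRecord:
    """Confounder-adjusted Cox association for one target metabolite."""
    data = metabolites.data if isinstance(metabolites, MetaboliteMatrix) \
        else metabolites
    conf = sorted(identify_confounders(target, g, screen,
                                       conservative=conservative,
                                       ancestors=ancestors))
    for c in conf:
        r = float(np.corrcoef(data[target], data[c])[0, 1])
        if abs(r) > 0.99:
            raise ValueError(
                f"confounder {c!r} is collinear with target {target!r} "
                f"(|r| = {abs(r):.4f})")
    res = fit_cox(survival, [target, *conf, *covariates], data,
                  check_ph=False)
    out_deg, in_deg = _degree_pair(g, target)
    eff = float(res.effects[target])
    return AssociationRecord(
        metabolite_id=target,
        hazard_ratio=math.exp(eff),
        effect_size=eff,
        se=float(res.se[target]),
        p_value=float(res.p[target]),
        confounders_adjusted=frozenset(conf),
        covariates_adjusted=tuple(covariates),
        out_degree=out_deg,
        in_degree=in_deg,
    )


def bh_fdr(p_values: Sequence[float], q: float = FDR_Q):
    """Benjamini-Hochberg step-up at level ``q``.

    Returns (rejection flags, realized p cutoff) where the cutoff is the
    largest rejected p-value (NaN when nothing is rejected).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError(f"q must lie in (0,1), got {q}")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    cutoff = float(p[reject].max()) if reject.any() else float("nan")
    return reject, cutoff


def _render_degree(d) -> str:
    if isinstance(d, tuple):
        return f"{d[0]} or {d[1]}"
    return str(int(d))


def assemble_results(records: Iterable[AssociationRecord],
                     platform: dict | None = None,
                     q: float = FDR_Q) -> pd.DataFrame:
    """Results table: one row per metabolite with hazard ratio, per-SD
    effect size, SE, p, FDR flag at level ``q``, adjustment sets and
    network degrees (intervals rendered as "a or b").  Sorted by
    platform then p."""
    records = list(records)
    if not records:
        return pd.DataFrame(columns=[
            "metabolite", "platform", "hazard_ratio", "effect_size", "se",
            "p_value", "fdr_significant", "confounders", "covariates",
            "out_degree", "in_degree"])
    flags, _ = bh_fdr([r.p_value for r in records], q)
    rows = []
    for r, sig in zip(records, flags):
        rows.append({
            "metabolite": r.metabolite_id,
            "platform": (platform or {}).get(r.metabolite_id, ""),
            "hazard_ratio": r.hazard_ratio,
            "effect_size": r.effect_size,
            "se": r.se,
            "p_value": r.p_value,
            "fdr_significant": bool(sig),
            "confounders": ";".join(sorted(r.confounders_adjusted)),
            "covariates": ",".join(r.covariates_adjusted),
            "out_degree": _render_degree(r.out_degree),
            "in_degree": _render_degree(r.in_degree),
        })
    out = pd.DataFrame(rows)
    return out.sort_values(["platform", "p_value"],
                           kind="stable").reset_index(drop=True)
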