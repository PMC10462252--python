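"""Polygenic factors as Mendelian-randomization instruments.

Factors are principal components of the standardized genotype dosage
matrix.  A factor qualifies as an instrument for a metabolite when it is
(i) relevant — marginally associated with the metabolite — and (ii)
plausibly exclusive — in the factor-augmented network it is adjacent to
that metabolite and to no other, a graphical proxy for the
no-pleiotropy/exclusion assumption.  Valid factors enter the network as
exogenous nodes, anchoring edge directions the way genetic variation
anchors causal direction in Mendelian randomization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .graph import BackgroundKnowledge, MixedGraph
from .network import learn_network

logger = logging.getLogger(__name__)

RELEVANCE_ALPHA = 1e-4

VALID = "valid"
FAILS_RELEVANCE = "fails_relevance"
FAILS_EXCLUSION = "fails_exclusion"


@dataclass(frozen=True)
class PolygenicFactorSet:
    """PCA-derived factor scores with per-(factor, metabolite) instrument
    validity status once screened."""

    scores: pd.DataFrame              # samples × factors
    loadings: pd.DataFrame            # SNPs × factors
    explained_variance: pd.Series     # per factor, non-increasing per block
    validity: dict = field(default_factory=dict)
    # (factor, metabolite) -> valid | fails_relevance | fails_exclusion

    @property
    def factor_ids(self) -> list:
        return list(self.scores.columns)

    def valid_factors(self) -> list:
        """Factors that are a valid instrument for at least one
        metabolite; factors valid for none are dropped from
        augmentation."""
        ok = {f for (f, _m), status in self.validity.items()
              if status == VALID}
        return [f for f in self.factor_ids if f in ok]

    def valid_pairs(self) -> list[tuple]:
        return sorted((f, m) for (f, m), s in self.validity.items()
                      if s == VALID)

    def validity_table(self) -> pd.DataFrame:
        rows = [(f, m, s) for (f, m), s in sorted(self.validity.items())]
        return pd.DataFrame(rows, columns=["factor", "metabolite", "status"])


def compute_polygenic_factors(genotypes: pd.DataFrame,
                              n_factors: int | None = None,
                              variance_threshold: float | None = None,
                              blocks: Sequence[Sequence[str]] | None = None,
                              ) -> PolygenicFactorSet:
    """Principal-component polygenic factors from a dosage matrix.

    SNPs are standardized (monomorphic SNPs dropped with a warning);
    components are extracted per SNP block — by default the whole matrix
    is one block.  Either a fixed count per block (``n_factors``) or all
    components with explained-variance ratio at or above
    ``variance_threshold`` are retained.
    """
    if genotypes.shape[1] < 2:
        raise ValueError("need at least two SNPs")
    if (n_factors is None) == (variance_threshold is None):
        raise ValueError("give exactly one of n_factors or "
                         "variance_threshold")
    sd = genotypes.std(axis=0, ddof=1)
    mono = list(sd.index[sd == 0])
    if mono:
        logger.warning("dropping %d monomorphic SNPs", len(mono))
    geno = genotypes.drop(columns=mono)
    if blocks is None:
        blocks = [list(geno.columns)]
    if n_factors is not None and \
            n_factors > min(len(geno), geno.shape[1]):
        raise ValueError("n_factors exceeds min(n_samples, n_snps)")
    all_scores, all_loadings, ev = [], [], []
    fid = 0
    for block in blocks:
        cols = [c for c in block if c in geno.columns]
        X = geno[cols].to_numpy(dtype=float)
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        k = n_factors if n_factors is not None else min(X.shape)
        pca = PCA(n_components=min(k, min(X.shape)), svd_solver="full")
        scores = pca.fit_transform(X)
        ratios = pca.explained_variance_ratio_
        if variance_threshold is not None:
            keep = ratios >= variance_threshold
            scores, ratios = scores[:, keep], ratios[keep]
            comps = pca.components_[keep]
        else:
            comps = pca.components_
        names = [f"PGF{fid + i + 1:03d}" for i in range(scores.shape[1])]
        fid += scores.shape[1]
        all_scores.append(pd.DataFrame(scores, index=geno.index,
                                       columns=names))
        ld = pd.DataFrame(0.0, index=geno.columns, columns=names)
        ld.loc[cols, names] = comps.T
        all_loadings.append(ld)
        ev.extend(zip(names, ratios))
    scores = pd.concat(all_scores, axis=1)
    loadings = pd.concat(all_loadings, axis=1)
    evs = pd.Series(dict(ev)).reindex(scores.columns)
    return PolygenicFactorSet(scores=scores, loadings=loadings,
                              explained_variance=evs)


def _relevance_p(f: np.ndarray, m: np.ndarray) -> float:
    r, p = stats.pearsonr(f, m)
    return float(p)


def screen_instruments(factors: PolygenicFactorSet,
                       metabolites: pd.DataFrame,
                       network_with_factors: MixedGraph,
                       relevance_alpha: float = RELEVANCE_ALPHA,
                       ) -> PolygenicFactorSet:
    """Screen every factor against every metabolite for instrument
    validity.

    A factor f is valid for metabolite M iff its marginal association
    with M has p < ``relevance_alpha`` (relevance) and, in the
    factor-augmented network, f is adjacent to M and to no other
    metabolite (exclusion proxy)."""
    if list(factors.scores.index) != list(metabolites.index):
        raise ValueError("factor scores and metabolite data must share "
                         "the same samples")
    validity = {}
    met_cols = list(metabolites.columns)
    for f in factors.factor_ids:
        fvec = factors.scores[f].to_numpy()
        adj = set()
        if f in network_with_factors:
            adj = {m for m in network_with_factors.adjacent(f)
                   if m in metabolites.columns}
        for m in met_cols:
            p = _relevance_p(fvec, metabolites[m].to_numpy())
            if p >= relevance_alpha:
                if m in adj:
                    validity[(f, m)] = FAILS_RELEVANCE
                continue
            if adj == {m}:
                validity[(f, m)] = VALID
            else:
                validity[(f, m)] = FAILS_EXCLUSION
    return replace(factors, validity=validity)


def augment_network(metabolites: pd.DataFrame,
                    factor_scores: pd.DataFrame,
                    bk: BackgroundKnowledge | None = None,
                    alpha: float = 1e-4,
                    **learn_options) -> MixedGraph:
    """Joint network over metabolites and (valid) polygenic factors.

    Factors are marked exogenous in the background knowledge, so every
    factor-metabolite edge is directed factor -> metabolite and factor
    nodes are sources; with no factors this reduces to plain network
    learning on the metabolites."""
    if factor_scores.shape[1] == 0:
        return learn_network(metabolites, bk=bk, alpha=alpha,
                             **learn_options)
    if list(factor_scores.index) != list(metabolites.index):
        raise ValueError("factor scores and metabolite data must share "
                         "the same samples")
    joint = pd.concat([metabolites, factor_scores], axis=1)
    exo = frozenset((bk.exogenous_nodes if bk else frozenset())
                    | set(factor_scores.columns))
    bk2 = BackgroundKnowledge(
        exogenous_nodes=exo,
        forbidden_edges=bk.forbidden_edges if bk else frozenset(),
        required_directions=bk.required_directions if bk else frozenset())
    g = learn_network(joint, bk=bk2, alpha=alpha, **learn_options)
    for f in factor_scores.columns:
        g.set_kind(f, "factor")
    return g


def genetically_influenced(g: MixedGraph) -> set:
    """Metabolites with a polygenic-factor parent in the augmented
    network ("directly influenced by polygenic factors")."""
    out = set()
    for n in g.nodes:
        if g.kind(n) != "metabolite":
            continue
        if any(g.kind(p) == "factor" for p in g.parents(n)):
            out.add(n)
    return out
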