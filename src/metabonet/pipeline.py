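"""End-to-end orchestration: simulate/load -> preprocess -> network ->
instruments -> properties -> associate, with deterministic per-stage
seeding and a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associate import (DEFAULT_COVARIATES, FDR_Q, SCREEN_ALPHA, SurvivalData,
                        adjusted_association, assemble_results,
                        univariable_screen)
from .graph import BackgroundKnowledge, MixedGraph, _pair
from .instruments import (RELEVANCE_ALPHA, augment_network,
                          compute_polygenic_factors, genetically_influenced,
                          screen_instruments)
from .io import (read_survival_table, read_table, write_graph_tsv,
                 write_graphml, write_sif, write_table)
from .network import learn_network
from .preprocess import (MetaboliteMatrix, log_transform, residualize,
                         standardize, winsorize)
from .properties import role_table
from .simulate import SimulationConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "network", "instruments", "associate")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    outdir: str = "metabonet_run"
    seed: int = 0
    simulate: dict | None = field(default_factory=dict)  # None => load inputs
    inputs: dict = field(default_factory=dict)
    # paths: metabolites, genotypes, covariates, survival, annotations
    network: dict = field(default_factory=dict)
    # alpha ('auto' or float), max_cond_size, stability, n_reductions,
    # drop_fraction, tau
    instruments: dict = field(default_factory=dict)
    # enabled, n_factors, relevance_alpha
    roles: dict = field(default_factory=dict)
    associate: dict = field(default_factory=dict)
    # covariates, screen_alpha, fdr_q, confounder_mode, per_platform_fdr

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir, "seed": self.seed,
            "simulate": self.simulate, "inputs": self.inputs,
            "network": self.network, "instruments": self.instruments,
            "roles": self.roles, "associate": self.associate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: d[k] for k in d})

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    graph: MixedGraph
    roles: pd.DataFrame
    screen: pd.DataFrame
    results: pd.DataFrame
    manifest: dict
    validity: pd.DataFrame | None = None
    cohort: Any = None


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31)
            for name, c in zip(_STAGES, children)}


def merge_graphs(graphs) -> MixedGraph:
    merged = MixedGraph()
    for g in graphs:
        for n in g.nodes:
            merged.add_node(n, g.kind(n))
        for u, v, mark in g.edges():
            merged.add_edge(u, v, mark)
            p = g.edge_pvalues.get(_pair(u, v))
            if p is not None:
                merged.edge_pvalues[_pair(u, v)] = p
    return merged


def _load_inputs(cfg: RunConfig):
    paths = cfg.inputs
    met = read_table(paths["metabolites"])
    cov = read_table(paths["covariates"], required=("age", "sex", "bmi"),
                     numeric=("age", "sex", "bmi"))
    surv = read_survival_table(paths["survival"])
    genotypes = read_table(paths["genotypes"]) \
        if paths.get("genotypes") else None
    platform, exo = {}, set()
    if paths.get("annotations"):
        ann = pd.read_csv(paths["annotations"], sep="\t")
        platform = dict(zip(ann["metabolite"], ann["platform"]))
        exo = set(ann.loc[ann["exogenous"].astype(bool), "metabolite"])
    matrix = MetaboliteMatrix(data=met, platform=platform,
                              exogenous=frozenset(exo))
    survival = SurvivalData(time=surv["time"], event=surv["event"],
                            covariates=cov)
    return matrix, genotypes, cov, survival


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis; every artifact lands under
    ``cfg.outdir`` and the manifest records config hash, seed, package
    versions, thresholds and row/edge counts."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)

    # -- data ----------------------------------------------------------
    cohort = None
    try:
        if cfg.simulate is not None:
            simcfg = SimulationConfig(**{**cfg.simulate,
                                         "seed": seeds["simulate"]})
            cohort = generate_cohort(simcfg)
            write_cohort(cohort, out / "cohort")
            raw, genotypes = cohort.metabolites, cohort.genotypes
            covariates, survival = cohort.covariates, cohort.survival
        else:
            raw, genotypes, covariates, survival = _load_inputs(cfg)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate/load", exc) from exc

    # -- preprocess ----------------------------------------------------
    try:
        logged = winsorize(log_transform(raw))
        resid = residualize(logged, covariates)
        std = standardize(logged)
    except Exception as exc:
        raise StageError("preprocess", exc) from exc

    net_opts = dict(cfg.network)
    alpha = net_opts.pop("alpha", 1e-4)
    learn_options = {
        "max_cond_size": net_opts.pop("max_cond_size", 3),
        "stability": net_opts.pop("stability", False),
        "n_reductions": net_opts.pop("n_reductions", 100),
        "drop_fraction": net_opts.pop("drop_fraction", 0.2),
        "tau": net_opts.pop("tau", 0.9),
        "seed": seeds["network"],
    }
    inst_opts = dict(cfg.instruments)
    use_factors = inst_opts.pop("enabled", True) and genotypes is not None
    n_factors = inst_opts.pop("n_factors", 8)
    relevance_alpha = inst_opts.pop("relevance_alpha", RELEVANCE_ALPHA)

    platforms = sorted({raw.platform.get(m, "all")
                        for m in raw.metabolite_ids})
    factors = None
    validity_rows = []
    try:
        if use_factors:
            factors = compute_polygenic_factors(genotypes,
                                                n_factors=n_factors)
        platform_graphs = []
        for label in platforms:
            cols = [m for m in resid.data.columns
                    if raw.platform.get(m, "all") == label]
            data = resid.data[cols]
            bk = BackgroundKnowledge(
                exogenous_nodes=frozenset(raw.exogenous) & set(cols))
            if factors is not None:
                g_screen = augment_network(data, factors.scores, bk=bk,
                                           alpha=alpha if alpha != "auto"
                                           else 1e-4,
                                           max_cond_size=learn_options[
                                               "max_cond_size"])
                screened = screen_instruments(factors, data, g_screen,
                                              relevance_alpha)
                validity_rows.append(screened.validity_table())
                valid = [f for f, m in screened.valid_pairs()]
                g = augment_network(data, factors.scores[sorted(set(valid))],
                                    bk=bk, alpha=alpha, **learn_options)
            else:
                g = learn_network(data, bk=bk, alpha=alpha, **learn_options)
            platform_graphs.append(g)
        graph = merge_graphs(platform_graphs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("network", exc) from exc

    # -- properties ----------------------------------------------------
    try:
        roles = role_table(graph, annotations=raw.platform or None,
                           **cfg.roles)
        roles = roles.loc[[n for n in roles.index
                           if graph.kind(n) == "metabolite"]]
    except Exception as exc:
        raise StageError("properties", exc) from exc

    # -- associate -----------------------------------------------------
    asc = dict(cfg.associate)
    covariate_terms = tuple(asc.pop("covariates", DEFAULT_COVARIATES))
    screen_alpha = asc.pop("screen_alpha", SCREEN_ALPHA)
    fdr_q = asc.pop("fdr_q", FDR_Q)
    # with Markov-reversible edges, treating unresolved neighbors as
    # potential parents is the safe default for confounding control
    confounder_mode = asc.pop("confounder_mode", "conservative")
    per_platform_fdr = asc.pop("per_platform_fdr", True)
    try:
        screen = univariable_screen(survival, std,
                                    covariates=covariate_terms,
                                    screen_alpha=screen_alpha)
        records = {}
        for m in std.metabolite_ids:
            records[m] = adjusted_association(
                m, survival, std, graph, screen,
                covariates=covariate_terms,
                conservative=confounder_mode == "conservative",
                ancestors=confounder_mode == "ancestors")
        if per_platform_fdr and raw.platform:
            parts = []
            for label in platforms:
                recs = [records[m] for m in std.metabolite_ids
                        if raw.platform.get(m, "all") == label]
                if recs:
                    parts.append(assemble_results(recs, raw.platform,
                                                  q=fdr_q))
            results = pd.concat(parts, ignore_index=True)
        else:
            results = assemble_results(records.values(), raw.platform,
                                       q=fdr_q)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("associate", exc) from exc

    # -- outputs -------------------------------------------------------
    write_graph_tsv(graph, out / "network_edges.tsv")
    write_graphml(graph, out / "network.graphml")
    write_sif(graph, out / "network.sif")
    write_table(roles, out / "roles.tsv", index_label="node")
    write_table(screen, out / "univariable_screen.tsv",
                index_label="metabolite")
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    validity = None
    if validity_rows:
        validity = pd.concat(validity_rows, ignore_index=True)
        validity.to_csv(out / "instrument_validity.tsv", sep="\t",
                        index=False)
        factors.scores.to_csv(out / "factor_scores.tsv", sep="\t",
                              index_label="sample_id")
        factors.loadings.to_csv(out / "factor_loadings.tsv", sep="\t",
                                index_label="snp")

    import lifelines
    import networkx
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "versions": {
            "metabonet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
            "lifelines": lifelines.__version__,
        },
        "thresholds": {
            "network_alpha": alpha,
            "relevance_alpha": relevance_alpha if use_factors else None,
            "screen_alpha": screen_alpha,
            "fdr_q": fdr_q,
            "roles": cfg.roles,
        },
        "counts": {
            "n_samples": len(raw.data),
            "n_metabolites": len(raw.metabolite_ids),
            "n_events": survival.n_events,
            "n_edges": graph.n_edges(),
            "n_genetically_influenced":
                len(genetically_influenced(graph)),
            "n_fdr_significant": int(results["fdr_significant"].sum()),
        },
    }
    logger.info("thresholds used: %s", manifest["thresholds"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return PipelineResult(graph=graph, roles=roles, screen=screen,
                          results=results, manifest=manifest,
                          validity=validity, cohort=cohort)
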