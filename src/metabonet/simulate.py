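"""Synthetic cohorts with known causal structure.

The generator emulates the statistical shape of a prospective
metabolomics cohort: ~200 relative metabolite levels in three platform
blocks (amino acids and amines, AAA; bile acids / organic acids /
nucleotides / sugars, BONS; lipids), ~2,500 participants, genotype
dosages carrying planted low-rank polygenic structure, covariates (age,
sex, BMI, batch), and right-censored time-to-heart-failure outcomes at a
~10% event rate.  Metabolites follow a linear-Gaussian structural
equation model on the log scale over a known DAG; a designated set of
"essential amino acid" metabolites is exogenous (no metabolite parents).
The ground-truth DAG ships with the cohort so structure learners,
instrument screens and confounder selection can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .associate import SurvivalData
from .preprocess import MetaboliteMatrix

DEFAULT_BLOCKS = (("AAA", 42), ("BONS", 54), ("lipid", 104))

# covariate effects on the hazard (per year of age, male sex, BMI unit),
# typical magnitudes for incident heart failure in a middle-aged cohort
DEFAULT_COVARIATE_HAZARD = {"age": 0.05, "sex": 0.4, "bmi": 0.03}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 2526
    platform_blocks: tuple = DEFAULT_BLOCKS
    n_exogenous: int = 9          # essential amino acids, all in the AAA block
    n_snps: int = 400
    n_factors_causal: int = 8
    factor_targets_per_factor: int = 1
    edge_density: float = 0.015
    cross_block_factor: float = 0.1   # blocks are weakly inter-connected
    coef_range: tuple = (0.3, 0.8)
    factor_effect: float = 0.3
    noise_sd: float = 1.0
    n_hazard_metabolites: int = 16
    log_hr_range: tuple = (0.2, 0.4)
    baseline_shape: float = 1.5       # Weibull κ
    baseline_scale: float = 1e-3
    target_event_rate: float = 0.103  # ≈ 260 events in 2,526 participants
    min_edge_pcor: float | None = None
    # when set, edges whose implied partial correlation drops below this
    # under some admissible conditioning set are pruned from the truth,
    # guaranteeing a strong-edge cohort
    seed: int = 0

    def __post_init__(self):
        if self.n_exogenous >= self.n_metabolites:
            raise ConfigurationError(
                "n_exogenous must be smaller than n_metabolites")
        if not 0 < self.target_event_rate < 1:
            raise ConfigurationError("target_event_rate must lie in (0,1)")
        if not 0 <= self.edge_density < 1:
            raise ConfigurationError("edge_density must lie in [0,1)")
        for name in ("n_samples", "n_snps"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.coef_range[0] < 0.05:
            raise ConfigurationError(
                "edge coefficients must be bounded away from zero "
                "(|b| >= 0.05) so true edges are well defined")
        if self.n_hazard_metabolites > self.n_metabolites:
            raise ConfigurationError("more hazard metabolites than metabolites")
        if self.n_snps < self.n_factors_causal:
            raise ConfigurationError("need at least one SNP per factor")

    @property
    def n_metabolites(self) -> int:
        return sum(size for _, size in self.platform_blocks)

    def metabolite_names(self) -> list[str]:
        names = []
        for label, size in self.platform_blocks:
            names.extend(f"{label}_{i:03d}" for i in range(1, size + 1))
        return names

    def factor_names(self) -> list[str]:
        return [f"F{i:02d}" for i in range(1, self.n_factors_causal + 1)]

    def platform_map(self) -> dict:
        return {name: label
                for label, size in self.platform_blocks
                for name in (f"{label}_{i:03d}" for i in range(1, size + 1))}


@dataclass(frozen=True)
class GroundTruthDAG:
    """The data-generating graph: metabolite -> metabolite structural
    coefficients, polygenic factor -> metabolite effects, hazard
    coefficients β (metabolites) and θ (covariates)."""

    metabolites: tuple
    factors: tuple
    directed_edges: tuple          # (parent, child, coefficient)
    exogenous_nodes: frozenset     # metabolites with no metabolite parents
    factor_targets: dict           # factor -> {metabolite}
    hazard_coefficients: dict      # metabolite -> β (per SD, log scale)
    covariate_hazard: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_HAZARD))
    covariate_effects: dict = field(default_factory=dict)
    # metabolite -> {covariate term -> coefficient}

    def __post_init__(self):
        dag = self.metabolite_dag()
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("ground-truth metabolite graph is cyclic")
        for p, c, b in self.directed_edges:
            if not np.isfinite(b):
                raise ValueError(f"non-finite coefficient on {p}->{c}")
            if c in self.exogenous_nodes and p in self.metabolites:
                raise ValueError(
                    f"exogenous metabolite {c!r} has metabolite parent {p!r}")
            if p in self.factors and c in self.factors:
                raise ValueError("factor-to-factor edges are not allowed")

    def metabolite_dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.metabolites)
        for p, c, b in self.directed_edges:
            if p in g and c in g:
                g.add_edge(p, c, coefficient=b)
        return g

    def full_dag(self) -> nx.DiGraph:
        g = self.metabolite_dag()
        g.add_nodes_from(self.factors)
        for p, c, b in self.directed_edges:
            if p in self.factors:
                g.add_edge(p, c, coefficient=b)
        return g

    def parent_coefficients(self) -> dict:
        out: dict = {m: [] for m in self.metabolites}
        for p, c, b in self.directed_edges:
            out[c].append((p, b))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "metabolites": list(self.metabolites),
            "factors": list(self.factors),
            "directed_edges": [[p, c, b] for p, c, b in self.directed_edges],
            "exogenous_nodes": sorted(self.exogenous_nodes),
            "factor_targets": {f: sorted(t)
                               for f, t in self.factor_targets.items()},
            "hazard_coefficients": self.hazard_coefficients,
            "covariate_hazard": self.covariate_hazard,
            "covariate_effects": self.covariate_effects,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthDAG":
        d = json.loads(Path(path).read_text())
        return cls(
            metabolites=tuple(d["metabolites"]),
            factors=tuple(d["factors"]),
            directed_edges=tuple((p, c, float(b))
                                 for p, c, b in d["directed_edges"]),
            exogenous_nodes=frozenset(d["exogenous_nodes"]),
            factor_targets={f: set(t) for f, t in d["factor_targets"].items()},
            hazard_coefficients=d["hazard_coefficients"],
            covariate_hazard=d["covariate_hazard"],
            covariate_effects=d["covariate_effects"],
        )


@dataclass(frozen=True)
class SyntheticCohort:
    metabolites: MetaboliteMatrix      # raw (exp-scale) relative abundances
    genotypes: pd.DataFrame            # samples × SNPs, dosages in [0,2]
    covariates: pd.DataFrame           # age, sex, bmi, batch
    survival: SurvivalData
    truth: GroundTruthDAG
    factor_scores: pd.DataFrame        # planted latent polygenic scores

    def __post_init__(self):
        ids = list(self.metabolites.data.index)
        for tbl in (self.genotypes, self.covariates, self.factor_scores):
            if list(tbl.index) != ids:
                raise ValueError("cohort tables must share sample ids "
                                 "in the same order")
        if list(self.survival.time.index) != ids:
            raise ValueError("survival table misaligned with cohort")
        geno = self.genotypes.to_numpy()
        if geno.min() < 0 or geno.max() > 2:
            raise ValueError("genotype dosages must lie in [0, 2]")


# ---------------------------------------------------------------------------
# graph generation
# ---------------------------------------------------------------------------

def _draw_coef(rng: np.random.Generator, low: float, high: float) -> float:
    return float(rng.choice((-1, 1)) * rng.uniform(low, high))


def generate_dag(config: SimulationConfig,
                 rng: np.random.Generator | None = None) -> GroundTruthDAG:
    """Random ground-truth DAG over the configured metabolites.

    Edges respect the metabolite ordering (earlier -> later), exogenous
    metabolites (the first ``n_exogenous``) receive no metabolite
    parents, blocks are only weakly inter-connected, every polygenic
    factor points at one or more metabolites, and all coefficients are
    bounded away from zero.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    names = config.metabolite_names()
    plat = config.platform_map()
    exo = frozenset(names[: config.n_exogenous])
    low, high = config.coef_range
    edges = []
    for j, child in enumerate(names):
        if child in exo:
            continue
        for parent in names[:j]:
            dens = config.edge_density
            if plat[parent] != plat[child]:
                dens *= config.cross_block_factor
            if rng.random() < dens:
                edges.append((parent, child, _draw_coef(rng, low, high)))
    factors = config.factor_names()
    factor_targets: dict = {}
    k = max(1, config.factor_targets_per_factor)
    for f in factors:
        targets = rng.choice(len(names), size=min(k, len(names)),
                             replace=False)
        factor_targets[f] = {names[t] for t in targets}
        for t in sorted(factor_targets[f]):
            edges.append((f, t,
                          float(rng.choice((-1, 1))) * config.factor_effect))
    hz_idx = rng.choice(len(names), size=config.n_hazard_metabolites,
                        replace=False)
    lo, hi = config.log_hr_range
    hazard = {names[i]: _draw_coef(rng, lo, hi) for i in sorted(hz_idx)}
    cov_effects = {}
    for m in names:
        cov_effects[m] = {
            "age": float(rng.uniform(-0.02, 0.02)),
            "sex": float(rng.uniform(-0.3, 0.3)),
            "bmi": float(rng.uniform(-0.05, 0.05)),
            "batch_2": float(rng.uniform(-0.3, 0.3)),
            "batch_3": float(rng.uniform(-0.3, 0.3)),
        }
    truth = GroundTruthDAG(
        metabolites=tuple(names),
        factors=tuple(factors),
        directed_edges=tuple(edges),
        exogenous_nodes=exo,
        factor_targets=factor_targets,
        hazard_coefficients=hazard,
        covariate_effects=cov_effects,
    )
    if config.min_edge_pcor is not None:
        truth = prune_weak_edges(truth, config.noise_sd,
                                 config.min_edge_pcor)
    return truth


def implied_covariance(truth: GroundTruthDAG,
                       noise_sd: float = 1.0) -> tuple[np.ndarray, dict]:
    """Model-implied metabolite covariance (after covariate adjustment):
    Σ = (I−B)⁻¹ (ΓΓᵀ + σ²I) (I−B)⁻ᵀ with B the metabolite coefficient
    matrix and Γ the factor loadings.  Returns (Σ, name → index)."""
    mets = list(truth.metabolites)
    idx = {m: i for i, m in enumerate(mets)}
    p = len(mets)
    B = np.zeros((p, p))
    G = np.zeros((p, len(truth.factors)))
    fidx = {f: i for i, f in enumerate(truth.factors)}
    for pa, ch, b in truth.directed_edges:
        if pa in fidx:
            G[idx[ch], fidx[pa]] = b
        else:
            B[idx[ch], idx[pa]] = b
    Minv = np.linalg.inv(np.eye(p) - B)
    S = Minv @ (G @ G.T + noise_sd**2 * np.eye(p)) @ Minv.T
    return S, idx


def _implied_pcor(S: np.ndarray, i: int, j: int, Z: Sequence[int]) -> float:
    sel = [i, j] + list(Z)
    P = np.linalg.inv(S[np.ix_(sel, sel)])
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))


def prune_weak_edges(truth: GroundTruthDAG, noise_sd: float,
                     min_pcor: float, max_cond: int = 3) -> GroundTruthDAG:
    """Remove metabolite edges whose implied partial correlation falls
    below ``min_pcor`` under some conditioning set drawn from the
    endpoints' adjacency (up to size ``max_cond``).

    Iterates (weakest edge first) until every remaining edge is strong
    under every admissible conditioning set, so constraint-based
    recovery of the pruned graph is statistically well posed.
    """
    import dataclasses
    import itertools as it
    while True:
        S, idx = implied_covariance(truth, noise_sd)
        met_edges = [(p_, c, b) for p_, c, b in truth.directed_edges
                     if p_ not in truth.factors]
        adj: dict = {}
        for p_, c, _ in met_edges:
            adj.setdefault(p_, set()).add(c)
            adj.setdefault(c, set()).add(p_)
        worst = None
        for p_, c, b in met_edges:
            pool = sorted((adj.get(p_, set()) | adj.get(c, set())) - {p_, c})
            strength = abs(_implied_pcor(S, idx[p_], idx[c], []))
            for k in range(1, max_cond + 1):
                for Z in it.combinations(pool, k):
                    strength = min(strength, abs(_implied_pcor(
                        S, idx[p_], idx[c], [idx[z] for z in Z])))
            if strength < min_pcor and (worst is None
                                        or strength < worst[0]):
                worst = (strength, (p_, c, b))
        if worst is None:
            return truth
        truth = dataclasses.replace(
            truth,
            directed_edges=tuple(e for e in truth.directed_edges
                                 if e != worst[1]))


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------

def simulate_covariates(config: SimulationConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    ids = [f"S{i:05d}" for i in range(1, n + 1)]
    return pd.DataFrame({
        "age": np.round(rng.normal(55, 10, size=n), 1),
        "sex": rng.binomial(1, 0.48, size=n),
        "bmi": np.round(rng.normal(27.5, 4.5, size=n), 1),
        "batch": rng.integers(1, 4, size=n),
    }, index=pd.Index(ids, name="sample_id"))


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator,
                       ids: Sequence[str] | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype dosages with planted low-rank polygenic structure.

    SNPs are binomial(2, MAF) with MAF ~ U(0.05, 0.5).  SNPs are split
    into contiguous blocks, one per causal factor; within block f each
    SNP's success probability is shifted by a latent standard-normal
    score z_f (symmetrically truncated so the marginal MAF is
    preserved), which lets PCA recover z_f from the dosage matrix.

    Returns (dosages, latent factor scores).
    """
    n, p = config.n_samples, config.n_snps
    if ids is None:
        ids = [f"S{i:05d}" for i in range(1, n + 1)]
    snps = [f"snp{j:04d}" for j in range(1, p + 1)]
    factors = config.factor_names()
    maf = rng.uniform(0.05, 0.5, size=p)
    latent = rng.standard_normal((n, len(factors)))
    per_block = p // max(1, len(factors))
    probs = np.tile(maf, (n, 1))
    for fi in range(len(factors)):
        j0, j1 = fi * per_block, (fi + 1) * per_block
        for j in range(j0, j1):
            w = rng.choice((-1, 1)) * 0.4 * np.sqrt(maf[j] * (1 - maf[j]))
            zcap = min(2.0, (maf[j] - 0.01) / abs(w),
                       (0.99 - maf[j]) / abs(w))
            shift = w * np.clip(latent[:, fi], -zcap, zcap)
            probs[:, j] = maf[j] + shift
    dosages = rng.binomial(2, probs)
    geno = pd.DataFrame(dosages, index=pd.Index(ids, name="sample_id"),
                        columns=snps)
    geno.attrs["maf"] = dict(zip(snps, maf))
    scores = pd.DataFrame(latent, index=geno.index, columns=factors)
    return geno, scores


def simulate_metabolites(truth: GroundTruthDAG,
                         factor_scores: pd.DataFrame,
                         covariates: pd.DataFrame,
                         config: SimulationConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Log-scale metabolite levels from the linear-Gaussian structural
    model, evaluated in topological order:

        M_j = Σ_k b_jk M_k + Σ_f γ_jf F_f + c_jᵀ W + ε_j,
        ε_j ~ N(0, noise_sd²).
    """
    if len(factor_scores) != len(covariates):
        raise ValueError("factor scores and covariates differ in length")
    n = len(covariates)
    W = pd.DataFrame({
        "age": covariates["age"] - covariates["age"].mean(),
        "sex": covariates["sex"].astype(float),
        "bmi": covariates["bmi"] - covariates["bmi"].mean(),
        "batch_2": (covariates["batch"] == 2).astype(float),
        "batch_3": (covariates["batch"] == 3).astype(float),
    }, index=covariates.index)
    order = list(nx.topological_sort(truth.metabolite_dag()))
    parents = truth.parent_coefficients()
    values: dict[str, np.ndarray] = {}
    for m in order:
        col = rng.normal(0.0, config.noise_sd, size=n)
        for p_, b in parents[m]:
            if p_ in truth.factors:
                col = col + b * factor_scores[p_].to_numpy()
            else:
                col = col + b * values[p_]
        ce = truth.covariate_effects.get(m, {})
        for term, c in ce.items():
            col = col + c * W[term].to_numpy()
        values[m] = col
    data = pd.DataFrame({m: values[m] for m in truth.metabolites},
                        index=covariates.index)
    return data


def simulate_survival(metabolites: pd.DataFrame,
                      covariates: pd.DataFrame,
                      truth: GroundTruthDAG,
                      config: SimulationConfig,
                      rng: np.random.Generator) -> SurvivalData:
    """Right-censored event times from a Weibull-baseline proportional
    hazards model by inverse-transform sampling.

    The cumulative hazard is H(t) = scale · t^κ · exp(θX + βZ) with Z
    the column-standardized (per-SD) metabolite levels; censoring is a
    single administrative cutoff placed at the event-time quantile that
    realizes the target event rate.
    """
    kappa, scale = config.baseline_shape, config.baseline_scale
    eta = np.zeros(len(covariates))
    for m, beta in truth.hazard_coefficients.items():
        col = metabolites[m].to_numpy()
        if not np.all(np.isfinite(col)):
            bad = metabolites.index[~np.isfinite(col)][0]
            raise RuntimeError(
                f"non-finite linear predictor for sample {bad!r} "
                f"(metabolite {m!r})")
        z = (col - col.mean()) / col.std(ddof=1)
        eta = eta + beta * z
    theta = truth.covariate_hazard
    eta = eta + theta.get("age", 0.0) * (covariates["age"] - 55).to_numpy()
    eta = eta + theta.get("sex", 0.0) * covariates["sex"].to_numpy()
    eta = eta + theta.get("bmi", 0.0) * (covariates["bmi"] - 27.5).to_numpy()
    if not np.all(np.isfinite(eta)):
        bad = covariates.index[~np.isfinite(eta)][0]
        raise RuntimeError(f"non-finite linear predictor for sample {bad!r}")
    u = rng.uniform(size=len(eta))
    t_event = (-np.log(u) / (scale * np.exp(eta))) ** (1.0 / kappa)
    cutoff = float(np.quantile(t_event, config.target_event_rate))
    time = np.minimum(t_event, cutoff)
    event = (t_event <= cutoff).astype(int)
    return SurvivalData(
        time=pd.Series(time, index=covariates.index, name="time"),
        event=pd.Series(event, index=covariates.index, name="event"),
        covariates=covariates.copy(),
    )


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """One complete synthetic cohort; all randomness flows from the
    config seed through a single generator."""
    rng = np.random.default_rng(config.seed)
    truth = generate_dag(config, rng)
    covariates = simulate_covariates(config, rng)
    genotypes, factor_scores = simulate_genotypes(
        config, rng, ids=list(covariates.index))
    sem = simulate_metabolites(truth, factor_scores, covariates, config, rng)
    survival = simulate_survival(sem, covariates, truth, config, rng)
    raw = np.exp(sem)  # relative abundances; the analysis log-transforms back
    metabolites = MetaboliteMatrix(
        data=raw, platform=config.platform_map(),
        exogenous=truth.exogenous_nodes, transforms=())
    return SyntheticCohort(metabolites=metabolites, genotypes=genotypes,
                           covariates=covariates, survival=survival,
                           truth=truth, factor_scores=factor_scores)


# ---------------------------------------------------------------------------
# truth oracles
# ---------------------------------------------------------------------------

def hazard_affecting(truth: GroundTruthDAG) -> set:
    """Metabolites with a nonzero total effect on the hazard: a nonzero
    direct β or a directed metabolite path to one."""
    direct = {m for m, b in truth.hazard_coefficients.items() if b != 0}
    dag = truth.metabolite_dag()
    return {m for m in truth.metabolites
            if m in direct or (nx.descendants(dag, m) & direct)}


def true_confounders(truth: GroundTruthDAG, target: str) -> set:
    """Ground-truth confounding metabolites for ``target``: metabolite
    parents in the true DAG that also affect the hazard (directly or
    through a directed path)."""
    if target not in truth.metabolites:
        raise KeyError(f"unknown target metabolite {target!r}")
    dag = truth.metabolite_dag()
    affecting = hazard_affecting(truth)
    return set(dag.predecessors(target)) & affecting


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Write the cohort as four TSV tables plus the truth as JSON;
    returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metabolites": outdir / "metabolites.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "covariates": outdir / "covariates.tsv",
        "survival": outdir / "survival.tsv",
        "truth": outdir / "truth.json",
    }
    cohort.metabolites.data.to_csv(paths["metabolites"], sep="\t",
                                   index_label="sample_id")
    cohort.genotypes.to_csv(paths["genotypes"], sep="\t",
                            index_label="sample_id")
    cohort.covariates.to_csv(paths["covariates"], sep="\t",
                             index_label="sample_id")
    surv = pd.DataFrame({"time": cohort.survival.time,
                         "event": cohort.survival.event})
    surv.to_csv(paths["survival"], sep="\t", index_label="sample_id")
    cohort.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
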