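import dataclasses

import numpy as np
import pandas as pd
import pytest

from metabonet.preprocess import MetaboliteMatrix, residualize
from metabonet.simulate import (SimulationConfig, generate_dag,
                                simulate_covariates, simulate_metabolites)


def small_config(seed: int, n_met: int = 10, n: int = 1000,
                 **overrides) -> SimulationConfig:
    defaults = dict(
        n_samples=n,
        platform_blocks=(("AAA", n_met),),
        n_exogenous=2,
        n_snps=20,
        n_factors_causal=1,
        edge_density=0.15,
        coef_range=(0.5, 0.9),
        n_hazard_metabolites=2,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def sem_data(config: SimulationConfig, truth=None, rng=None,
             with_factors: bool = False):
    """Residualized linear-SEM metabolite data plus the truth used."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if truth is None:
        truth = generate_dag(config, rng)
        if not with_factors:
            truth = dataclasses.replace(
                truth,
                directed_edges=tuple(e for e in truth.directed_edges
                                     if e[0] not in truth.factors),
                factor_targets={f: set() for f in truth.factors})
    cov = simulate_covariates(config, rng)
    scores = pd.DataFrame(
        rng.standard_normal((config.n_samples, len(truth.factors))),
        index=cov.index, columns=truth.factors)
    data = simulate_metabolites(truth, scores, cov, config, rng)
    resid = residualize(MetaboliteMatrix(data=data), cov)
    return resid.data, truth, cov, scores


def instrument_cohort(seed: int, pleiotropic: bool = False,
                      null_factor: bool = False, n: int = 2500,
                      gamma: float = 0.3):
    """Four metabolites (M1 -> M2 chain, M3, M4 independent) plus one
    genotype-backed polygenic factor hitting M1 (and M3 when
    pleiotropic); returns (screened factor set, factor set, data)."""
    from metabonet.instruments import (augment_network,
                                       compute_polygenic_factors,
                                       screen_instruments)
    from metabonet.simulate import simulate_genotypes

    rng = np.random.default_rng(seed)
    cfg = small_config(seed, n_met=4, n=n, n_snps=40, n_factors_causal=1)
    geno, latent = simulate_genotypes(cfg, rng)
    z = latent.iloc[:, 0].to_numpy()
    g = 0.0 if null_factor else gamma
    m1 = g * z + rng.normal(size=n)
    m2 = 0.6 * m1 + rng.normal(size=n)
    m3 = (g * z if pleiotropic else 0) + rng.normal(size=n)
    m4 = rng.normal(size=n)
    mets = pd.DataFrame({"M1": m1, "M2": m2, "M3": m3, "M4": m4},
                        index=geno.index)
    fs = compute_polygenic_factors(geno, n_factors=1)
    g_aug = augment_network(mets, fs.scores, alpha=1e-4)
    return screen_instruments(fs, mets, g_aug), fs, mets


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
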