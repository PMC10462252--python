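# metabonet

Causal conditional-independence networks of circulating metabolites,
polygenic-factor instruments, and network-guided survival association.

## The problem

In prospective metabolomics cohorts, metabolite levels are densely
correlated, so a metabolite associated with a clinical outcome such as
incident heart failure may carry no effect of its own — its signal can
be entirely inherited from other metabolites that drive both it and the
outcome. `metabonet` addresses this by (1) learning the conditional
dependence structure of the metabolites, (2) strengthening edge
directions with biological knowledge and genetics, and (3) using the
resulting network to pick, per metabolite, the *confounding
metabolites* that must enter its outcome model.

It is written for statistical geneticists and systems-biology analysts
who want a tested, scriptable version of this workflow, plus a
synthetic-cohort generator with known ground truth for validating every
step.

## The model

**Network.** An edge between metabolites x and y means their partial
correlation given every conditioning subset of the other metabolites is
nonzero. The learner is order-independent PC (PC-stable) with the
Fisher-z test — z = ½ ln((1+r)/(1−r)), statistic √(n−|Z|−3)·|z| — at
α = 1e-4 (selectable by split-half structural-Hamming-distance
minimization). Directions come from v-structures, Meek rules,
exogeneity of essential amino acids (nothing metabolic points into
them), and polygenic factors: principal components of genotype dosages
that pass a Mendelian-randomization screen (relevance p < 1e-4 and a
graphical exclusion proxy) enter the graph as instruments. Directions
that fail a variable-reduction stability test are reported as
bidirected ("unidentified"), never dropped.

**Association.** For each metabolite X with confounders Z (network
parents — or unresolved neighbors in conservative mode — that are
themselves outcome-associated at p < 0.05), the hazard model is

    ln H(t; X, Z) = ln h0(t) + θ·covariates + β_X·X + β_Z·Z

fitted by Cox partial likelihood (Efron ties, Schoenfeld PH check).
Metabolites are z-scored, so exp(β_X) is the hazard ratio per SD.
Significance is Benjamini–Hochberg FDR at q = 0.1 per platform.

**Roles.** From the final graph the package reports degrees (interval
"a or b" when directions are unresolved), broadcasters (high out-degree
with downstream propagation), receivers (high in, low out), connected
subnetworks labelled by metabolite class, and mediators between groups.

## Worked example

Run the whole pipeline on a simulated cohort (1,500 samples, 40
metabolites in two platform blocks, 4 polygenic factors, 4 planted
hazard metabolites):

```python
from metabonet import RunConfig, run_pipeline

cfg = RunConfig(
    outdir="example_run", seed=7,
    simulate={"platform_blocks": [["AAA", 20], ["BONS", 20]],
              "n_samples": 1500, "n_exogenous": 4, "n_snps": 80,
              "n_factors_causal": 4, "edge_density": 0.08,
              "n_hazard_metabolites": 4, "min_edge_pcor": 0.3},
    network={"stability": False})
res = run_pipeline(cfg)
print(res.manifest["counts"])
print(res.results[res.results.fdr_significant])
```

prints

```
{'n_samples': 1500, 'n_metabolites': 40, 'n_events': 155, 'n_edges': 26,
 'n_genetically_influenced': 3, 'n_fdr_significant': 3}
metabolite platform  hazard_ratio  effect_size    se  p_value confounders out_degree in_degree
   AAA_002      AAA         0.628       -0.465 0.080    0.000                      1         0
   AAA_012      AAA         1.238        0.214 0.083    0.010                      0         2
  BONS_005     BONS         0.715       -0.336 0.099    0.001    BONS_006     0 or 1    0 or 1
```

Reading the rows: `AAA_002` lowers the hazard (HR 0.63 per SD) and has
no confounders — it is a source in the learned network. `BONS_005`
remains significant *after* adjusting for its confounding metabolite
`BONS_006`; its "0 or 1" degrees flag an edge whose direction the data
could not identify. Three of the four planted hazard metabolites are
recovered at this sample size; the fourth (`AAA_009`, with the weakest
planted effect) does not clear the per-platform FDR bar. The run
directory contains the cohort tables, the network as
TSV/GraphML/SIF, the role table, the univariable screen, the results
table, and a manifest (config hash, seed, versions, counts) from which
the run can be reproduced byte-for-byte.

The same stages are available from the shell:

```bash
metabonet simulate --config sim.yaml --out cohort/ --seed 7
metabonet network --data resid.tsv --alpha 1e-4 --out net/
metabonet all --config run.yaml
```

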