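# Methods

## Overview

`metabonet` implements a two-stage systems analysis of circulating
metabolites in a prospective cohort. Stage one learns a
conditional-independence network over metabolite levels — a partially
directed graph in which an edge is a partial correlation not explained
by any subset of the other metabolites — and upgrades it toward a causal
network using two sources of directional information: biological
background knowledge (essential amino acids are exogenous: nothing
metabolic points into them) and polygenic factors used as
Mendelian-randomization instruments. Stage two uses the network to pick
the confounding metabolites for each target and estimates each
metabolite's association with a time-to-event outcome (incident heart
failure) in a confounder-adjusted Cox proportional-hazards model.

Because the motivating cohort data are access-restricted, the package
ships a synthetic-cohort generator with a known ground-truth causal
graph; every claim the pipeline makes is tested against that truth.

## Preprocessing

Relative abundances are log-transformed, then winsorized at
mean ± 3 SD per column (statistics computed once, on the log scale,
before clipping — the transform is a single pass, not iterated). Two
branches follow:

* network branch — each column is replaced by its OLS residuals on an
  intercept, batch indicators, age, sex and BMI; the network is learned
  on the residuals;
* survival branch — columns are z-scored, so Cox coefficients are
  per-SD log hazard ratios. "Normalized" is not defined more precisely
  by the upstream description of the analysis; z-scoring the
  log-winsorized values is this package's reading, and it makes effect
  sizes unit-free and comparable across metabolites.

Missing data are handled by complete-case deletion with a logged count;
no imputation is attempted.

## Network learning

The learner is the order-independent ("stable") PC algorithm with the
Gaussian conditional-independence test: partial correlation r of x and y
given Z (from the inverse of the correlation submatrix), Fisher
transform z = ½·ln((1+r)/(1−r)), statistic √(n−|Z|−3)·|z| against the
standard normal. Defaults: significance level α = 1e-4 and maximum
conditioning-set size 3, both configurable. α may also be chosen
automatically by split-half reproducibility: for each candidate in
{1e-2, 1e-3, 1e-4, 1e-5} the samples are halved `n_splits` times, a
network is learned on each half, and the candidate minimizing the mean
structural Hamming distance (SHD) between half-networks wins; ties go to
the more conservative (smaller) candidate. SHD counts 1 per node pair
whose edge state differs — missing/extra adjacency or any mark
disagreement (direction flip, directed vs undirected vs bidirected).

Orientation proceeds in a fixed order: unshielded colliders x→z←y
(z absent from the recorded separating set of x, y) with
majority-of-evidence conflict resolution and ties left undirected; then
background knowledge — every edge between an exogenous node and a
non-exogenous node is directed outward from the exogenous node, edges
between two exogenous nodes stay undirected; then Meek rules R1–R4 to a
fixed point. A required direction contradicting an existing collider
raises an error rather than silently rewriting the graph. Each surviving
edge carries a conservative p-value: the largest p among the CI tests
that failed to remove it (all ≤ α by construction).

Direction stability is assessed by variable reduction: the network is
re-learned `n_reductions` (default 100) times after dropping a random
20% of variables; a directed edge keeps its direction only if it is
oriented the same way in at least τ = 0.9 of the reductions retaining
both endpoints. Unstable directions become *bidirected* edges — the
direction is reported as unidentified, but the metabolites are never
dropped. Directions forced by background knowledge are exempt, since the
constraint survives any reduction. The reduction parameters are this
package's defaults; the upstream description defers them to cited
references.

All tie-breaking (node iteration, subset enumeration) is lexicographic,
which together with per-level frozen adjacency sets makes the learned
graph invariant to the order of input columns.

## Polygenic factors as instruments

Factors are principal components of the standardized genotype dosage
matrix (monomorphic SNPs dropped; whole matrix as one block by default,
per-block extraction available). A factor f is accepted as an instrument
for metabolite M iff

1. relevance — marginal association p(f, M) < 1e-4 (matching the
   network edge threshold), and
2. exclusion proxy — in the factor-augmented network, f is adjacent to
   M and to no other metabolite.

The second condition is a graphical operationalization of the
no-pleiotropy/exchangeability assumptions; a stricter econometric test
is out of scope. Valid factors enter the joint PC run as exogenous
nodes; metabolites with a factor parent are flagged "genetically
influenced". With no valid factors the augmented network reduces exactly
to the metabolite-only network.

## Network properties

Out/in degrees are counted over directed metabolite edges; a node with k
incident undirected or bidirected edges gets interval degrees
[point, point+k], rendered "a or b". Broadcasters are nodes with
out-degree ≥ 3 whose influence propagates at least two steps downstream;
receivers have in-degree ≥ 3 and out-degree ≤ 1 (thresholds
configurable; the source narrative gives none). Subnetworks are
connected components of the skeleton labelled by majority metabolite
class. Mediators between groups A and B are nodes outside both groups
lying on a directed A→B path whose individual removal strictly reduces
the number of reachable (a, b) pairs.

## Survival association

Cox proportional-hazards models, ln H(t; X, Z) = ln h0(t) + θX + βZ, are
fitted by maximum partial likelihood with Efron tie handling (the tie
method is unstated upstream; Efron is the standard choice for moderate
ties). A Schoenfeld-residual proportionality test per term sets a
violation flag at p < 0.05; the fit is returned regardless.

Confounding metabolites for a target M are metabolites that affect both
M and the outcome: network evidence is a directed parent edge C→M (in
conservative mode — the pipeline default — undirected and bidirected
neighbors also qualify, since an unresolved direction may hide a
parent), and outcome evidence is p < 0.05 for C in a covariate-adjusted
univariable Cox screen. Parents-only selection is available and is the
`identify_confounders` function default; the pipeline default is
conservative because with Markov-reversible edges a parents-only rule
systematically misses confounders whose edge direction is unidentifiable
from observational data alone, and the cost of over-adjustment (a lost
degree of freedom per neighbor) is small relative to the inflated
false-positive rate of under-adjustment.

The adjusted model for target M contains M, its confounders, and the
covariates (age, sex, BMI by default; the covariate list is
configurable per run, e.g. dropping BMI for lipid analyses). Final
significance uses Benjamini–Hochberg FDR at q = 0.1 on the realized
p-values — computed within each platform by default, since platforms
are analyzed separately — and the realized p cutoff is reported. A fixed
p threshold tied to another cohort's p distribution is deliberately not
hard-coded.

## Synthetic cohorts

The generator emulates the statistical shape of the motivating study:
n = 2,526 samples; 200 metabolites in platform blocks of 42 (amino
acids/amines), 54 (bile acids, organic acids, nucleotides, sugars) and
104 (lipids); 9 exogenous "essential amino acid" metabolites; 400 SNPs
in 8 blocks backing 8 polygenic factors; covariates age ~ N(55, 10²),
sex ~ Bernoulli(0.48), BMI ~ N(27.5, 4.5²), 3 batches; and an
administrative-censoring event rate of 10.3% (~260 events).

Metabolites follow a linear-Gaussian structural equation model on the
log scale over a random DAG whose edges respect a fixed topological
order: M_j = Σ b_jk·M_k + Σ γ_jf·F_f + c_jᵀ·covariates + ε_j with unit
noise SD. Structural coefficients are uniform in ±(0.3, 0.8) —
magnitudes bounded away from zero so "true edge" is well defined —
with within-block edge probability 0.015 and cross-block edges
down-weighted ×0.1 (block coupling is an assumption, not an observed
quantity). Genotypes are Binomial(2, MAF) with MAF ~ U(0.05, 0.5); each
SNP block's success probability is shifted by a latent standard-normal
factor score, symmetrically truncated so marginal MAFs are preserved,
which is what lets PCA recover the planted factors. Hazards follow a
Weibull baseline (κ = 1.5; chosen for closed-form inverse-transform
sampling, the baseline being unstated upstream) with per-SD log hazard
ratios uniform in ±(0.2, 0.4) on 16 metabolites by default — the range
where effects are detectable at ~260 events, consistent with the upper
half of reported effect magnitudes — plus covariate effects
(0.05/year age, 0.4 male sex, 0.03/BMI unit). Censoring is a single
administrative cutoff placed at the event-time quantile realizing the
target event rate.

An optional `min_edge_pcor` floor produces *strong-edge cohorts*: edges
whose implied partial correlation under some admissible conditioning
set (computed from the model-implied covariance) falls below the floor
are pruned from the truth, weakest first. Without it, random signed
coefficients occasionally produce near-cancellations under which no
constraint-based method can recover the edge; with it, structure
recovery is statistically well posed, which is the intended regime for
recovery benchmarks.

What the generator does **not** emulate: linkage disequilibrium,
population stratification, platform-specific measurement error,
nonlinear kinetics, informative censoring, competing risks. Passing
tests therefore demonstrate correctness of the algorithms under the
model's assumptions, not robustness to these real-data complications.

## Numerical and degenerate-input choices

Partial correlations are clipped to [−1, 1]; |r| is capped just below 1
before the Fisher transform, so duplicated columns give p = 0 rather
than NaN. Singular conditioning sets raise. Zero-variance columns:
winsorization skips them with a warning, standardization raises.
Collinear confounders (|r| > 0.99 with the target) raise before the Cox
fit. Cox fits require ≥ 10 events and a full-rank design. Orientation
steps never create directed cycles (a cycle guard skips the orientation,
which can only trigger under finite-sample CI inconsistencies).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the algorithms at the
cohort scale they target (n = 2,500, p = 40 for structure recovery;
n = 2,000–2,500 for Cox properties) but with replicate counts sized for
a single CPU: 100–200 replicates for calibration-style checks, 10–20
seeds for cohort-level checks, and exhaustive DAG enumeration up to 4
nodes (plus seeded random samples at 5–10 nodes) for the oracle
equivalence of the structure learner.

## Known limitations

* The exclusion proxy for instrument validity is graphical; a factor
  whose pleiotropic targets sit in different platform blocks can evade
  it when platforms are analyzed separately.
* Platform-separated analysis cannot adjust cross-platform confounding
  (a limitation inherited from the design it reimplements).
* Confounder adjustment conditions on measured metabolites only; latent
  confounding is out of scope (no FCI-style discovery).
* Interval degrees propagate unresolved directions to the report but
  role classification uses the identified (lower) endpoint.
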