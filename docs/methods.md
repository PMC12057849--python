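# Methods

This note documents the models, numerical choices and known limitations of
`ecoassembly`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and normalisation

The universal substrate is a samples × taxa abundance matrix with one
group label per sample, a rooted phylogeny covering the taxa, and a
samples × 9 soil-factor table (TN, TP, TK, salt, SOM, SUE, SALP, SSC, pH).
Counts are total-sum scaled to relative abundances; no rarefaction is
applied by default (a seeded `rarefy` exists but is off), because every
downstream statistic here is either scale-free or abundance-weighted on
relative abundances. Sample and taxon order is canonicalised
lexicographically on read so outputs are order-stable. Taxa missing from
the tree are a hard error in the null-model stages (βMNTD is undefined for
them) but only trigger exclusion elsewhere.

## Abundant / rare partition

Within each group, *abundant* ⇔ min over the group's samples of relative
abundance > 0.1%; *rare* ⇔ max < 0.01%; otherwise *intermediate*. Both
inequalities are strict. Labels are per group, so a taxon can be abundant
near the disturbance source and intermediate elsewhere; the combined
abundant (rare) table retains a sample's observed value only when the
taxon carries that label in the sample's own group and assigns exactly 0
otherwise. Taxa wholly absent from a group have group-maximum 0 and are
formally rare there, but columns that end up all-zero are dropped from the
combined tables — they carry no signal and would distort richness. A
practical consequence worth knowing: at sequencing depth below
1/0.0001 = 10⁴ reads no *observed* taxon can sit under the rare ceiling,
so the combined rare table is empty. Thresholds are configurable. The
min/max reading of the rule (rather than a mean-based one) follows the
conventional abundant/rare framework; both thresholds are exposed for
anyone preferring another convention.

## Diversity

Shannon is reported in nats and Simpson as 1 − Σp² (the defaults of the
standard vegan-style toolchain); both conventions are recorded in the
result metadata. NMDS minimises Kruskal stress-1 over 20 random restarts
of scikit-learn's nonmetric MDS (disparities by isotonic regression with
tie pooling); coordinates are centred and the seed fixes the restarts.
PERMANOVA uses the Gower-centred pseudo-F with
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), delegated to scikit-bio; the
reported R² is recovered from the pseudo-F identity. Group comparisons of
α-indices use one-way ANOVA plus unprotected pairwise LSD t-tests on the
pooled error term, with an optional log1p transform for skewed indices
(off by default).

## Assembly null models

**βMNTD** (abundance-weighted): for samples j and m,
0.5·[Σ_{i∈j} f_ij·min_{k∈m} d(i,k) + Σ_{k∈m} f_km·min_{i∈j} d(k,i)], with
f renormalised over present taxa and d the patristic distance. An
unweighted variant averages over presences. Correctness is pinned by an
exhaustive double-loop oracle on small random instances (agreement to
1e-10).

**βNTI**: standardised effect size of βMNTD against a null that shuffles
taxon labels across the tree's tips — taxa swap positions on the
phylogeny, abundances untouched. The randomisation pool is every taxon
present anywhere in the table (the regional pool), not per-group, because
the study design computes one cross-distance analysis with per-group
views of the same pairs. Null permutations are shared across pairs within
one call (the field convention, and what makes all-pairs computation
tractable). Identical communities leave every null βMNTD at zero; the
degenerate sd = 0 case returns NaN with a warning, and NaN propagates to
the process label.

**RC_bray**: null communities preserve each sample's observed richness and
read total; presences are drawn without replacement with probability
proportional to regional occurrence frequency, one read seeds each drawn
taxon, and the remaining reads are allocated multinomially by regional
relative abundance among the drawn taxa. RC = 2·((#{null < obs} +
½·#ties)/n_null − ½) ∈ [−1, 1], ties half-weighted. Raw integer counts are
required — the null reassembles reads.

**Classification** follows the usual two-stage rule (βNTI first, then
RC_bray) with thresholds ±2 and ±0.95; n_null defaults to 999 (tests use
199 for speed). All null draws are seeded and bit-reproducible.

## Co-occurrence networks

Per group, the 250 taxa with highest mean relative abundance (ties broken
lexicographically) are correlated pairwise with Spearman's ρ; p-values use
the t-approximation with average-rank ties. An edge requires |ρ| > 0.8 and
p < 0.01 (raw p by default; Benjamini–Hochberg available by flag).
Zero-variance taxa are excluded and isolated nodes dropped, both logged —
which is why realised node counts fall below the nominal 250. Path length
and diameter are computed over reachable pairs only (the common Gephi
convention); clustering is the mean local coefficient with degree-<2 nodes
contributing 0; modularity comes from greedy modularity maximisation
(Louvain by flag), and the partition used is always recorded because Zi–Pi
depends on it. Zi is the within-module degree z-score (Zi = 0 in modules
with zero spread), Pi = 1 − Σ_m (k_im/k_i)² (Pi = 0 for isolated nodes),
with roles cut at Zi = 2.5 and Pi = 0.62.

Natural connectivity is ln((1/N′)·Σ e^{λ_i}) over adjacency eigenvalues of
the remaining graph, computed with a log-sum-exp for stability. Under edge
removal on a fixed node set it is provably non-increasing, and that is
asserted as an invariant. Under *node* removal the per-node normalisation
can tick upward on strongly modular graphs when loosely attached remnants
disappear and dense cores remain; curves are monotone on the
Erdős–Rényi-type synthetic networks the robustness checks use, but
monotonicity under node removal is an empirical tendency, not a theorem.

## Environmental drivers

LMG importance is computed exactly: R² for all 2⁹ predictor subsets, each
factor's sequential contribution averaged over orderings with
|S|!(p−|S|−1)!/p! weights. Shares are non-negative and sum to the
full-model R² (hard invariant, checked to 1e-9); aliased columns are
dropped with a warning and get share 0. With orthogonal predictors each
share equals the factor's marginal R² — also asserted.

The ordination test performs RDA of Hellinger-transformed, column-centred
abundances on standardised factors (transform switchable to none/log1p).
Per-factor R² is the squared multiple correlation of the factor with the
two leading constrained-axis site scores. The permutation p *refits the
whole ordination* with that factor's rows permuted inside the constraint
matrix; permuting against fixed site scores would be anti-conservative,
because the tested factor helps shape the axes it is then correlated with.

The βNTI ~ |Δfactor| regression uses OLS for slope and R² but a
Mantel-type permutation for p: sample identities are permuted and the
pairwise differences recomputed, preserving the dependence between pairs
that share a sample.

## Synthetic-data generator

The generator emulates the study design: 5 distance groups with 9/6/6/6/6
replicates, 2000-taxon regional pool (lognormal σ = 1.5 rank-abundance),
30 000 reads per sample, a pure-birth phylogeny scaled to unit depth
(the simulator's final cherry gets the exponential waiting time to the
next unrealised speciation appended so no two tips coincide), and a
one-dimensional latent disturbance axis: group optima spread over
[−2, 2], and the nine soil factors are affine loadings on that axis plus
replicate-level noise. One latent axis rather than nine independent
filters reflects how such designs treat distance as the master gradient.

Mechanisms:

* **Selection** — niche optima evolve by Brownian motion on the tree
  (rate 1 per unit depth), so filtering produces phylogenetic signal;
  each group weights the pool by a Gaussian kernel
  exp(−(niche − optimum)²/2σ²). The *selection regime* preset uses
  σ = 0.3 with no mass-effect blending: between-group pairs then recover
  heterogeneous selection. Blending the regional pool back in
  (dispersal_rate > 0) dilutes the signal quickly, because shared taxa
  have nearest-neighbour distance zero in both directions.
* **Dispersal** — at dispersal_rate = 1 all samples draw from the shared
  pool; lower rates add taxon-wise lognormal drift to each group's pool
  (σ_drift = 1.5·(1 − dispersal_rate)) with no phylogenetic structure —
  the fingerprint of dispersal limitation (RC → +1, |βNTI| ≤ 2).
* **Neutral regime** — the flat-filter mode draws samples i.i.d. from the
  probabilistic-occupancy process that the Raup–Crick null itself
  postulates: presence weights, pool abundances and expected richness are
  taken as the fixed point of the occurrence-estimation map (three
  burn-in rounds of drawing a seed table and re-estimating occurrence
  frequencies from it). This matters: communities drawn multinomially at
  depth share nearly all taxa, sit far below the null's presence
  turnover, and would push RC to −1 by construction; the fixed-point
  draw makes "samples i.i.d. from the null model" literally true, which
  is the defining calibration property of the metric (RC mean ≈ 0,
  |βNTI| ≤ 2 for ≥ 90% of pairs — both checked).

What the generator does **not** emulate: sequencing error and chimeras,
compositional biases of PCR, overdispersion beyond multinomial sampling
(a Dirichlet-multinomial switch would be the natural extension),
taxon-specific dispersal kernels, and multi-dimensional niches. Passing
calibration and recovery tests therefore shows the inference machinery is
correct and well calibrated under its own assumptions, not that real
mining-gradient data would yield these percentages.

## Problem sizes used in the checks

Calibration and recovery run at a reduced scale chosen to exercise every
code path with stable statistics: 200-taxon pools, two groups of three
samples at 3 000 reads, 199 null replicates, ≥ 100 pairs pooled over seven
seeds; PERMANOVA calibration uses 500 group-free Dirichlet datasets of 10
samples at 199 permutations (binomial 95% band around 0.05); the
study-design run in the acceptance script uses 300 taxa, 33 samples,
5 000 reads and 199 null replicates. The full-scale defaults (2 000 taxa,
30 000 reads, 999 nulls) are the package defaults for real use.

## Known limitations

* The Spearman p-value t-approximation is anti-conservative for n < ~10
  samples; an exact-permutation option exists for small designs.
* RC_bray inherits the finite-sample flattening of occurrence-frequency
  estimates: with six samples per group the null cannot distinguish
  "present in all six" from "present with probability 5/6", which biases
  RC negative for tightly replicated designs (visible as the
  homogenizing-dispersal reading of within-group replicate pairs).
* The greedy modularity partition is deterministic but not optimal;
  Zi–Pi roles can change under a different partition, which is why the
  partition is always emitted alongside the roles.
* PERMANOVA p-values are limited by the number of distinct label
  partitions (e.g. min p = 0.1 for 3 + 3 designs).
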