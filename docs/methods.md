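# Methods

This note documents the models, estimators, numerical choices, and known
limitations of panconet, stage by stage in pipeline order.

## Preprocessing

Genes with missing-or-zero entries in more than 75% of samples are removed
(the comparison is strict: a gene at exactly 75% is kept). Values are
log2(x + offset) transformed (offset 1 by default; the transform is skipped
for fixtures that are already on the log2 scale, which is what the synthetic
generator emits). Each gene is then replaced by the residuals of an OLS fit
on intercept + covariates — age (years, numeric), sex and race (indicator
contrasts). Constant or rank-deficient design columns are dropped with a
logged warning. Missing expression entries are handled per gene by
complete-case fitting; their residuals stay missing and are excluded
pairwise from correlations downstream. Residuals are orthogonal to the
design to machine precision and the adjustment is idempotent.

## Correlation thresholding

The permutation null permutes each gene row independently across samples,
preserving gene marginals while destroying gene–gene dependence. With
n_perm = 10 permutations and a candidate grid |r| ∈ {0.01, …, 0.99} (step
configurable), FDR(c) = mean permuted pair count at c / observed count,
with 0/0 → 0 and k/0 → ∞. The chosen cutoff is the smallest c with
FDR ≤ 0.05; if none qualifies the stage raises, and the caller may proceed
with an empty network. Pairs with fewer than 10 shared observed samples are
excluded. Ranking ties in |r| break by lexicographic gene pair, so builds
are deterministic.

## Planar filtered network

Greedy insertion in decreasing |r| order, keeping an edge iff the graph
stays planar, stopping at 3(n − 2) edges. Planarity is checked with the
left-right test (networkx). Two exact shortcuts make this fast at fixture
scale: an edge joining two connected components always preserves planarity
(planar components connected by a bridge remain planar), and a component
already holding its planar maximum of 3(n_c − 2) edges can reject
intra-component candidates without testing; otherwise only the containing
component's subgraph is tested. The result is identical to whole-graph
testing (verified against a brute-force oracle in the tests). |r| is the
edge weight; the signed correlation is kept as an edge attribute.

## Multiscale clustering

Top-down recursion from the root (all network nodes). Disconnected parents
first split into their connected components (components below the minimum
module size are dropped from the hierarchy). Connected parents split at the
best modularity partition: exhaustive 2-way search for parents with ≤ 14
nodes (vectorized over bitmasks, exact), seeded Louvain for larger parents.
A split is accepted iff Q > 0 and at least two blocks have ≥ min_size (10)
genes; smaller blocks are then merged into the sibling with the highest
total connecting edge weight, smallest block first. Recursion continues per
accepted child. `max_size` (500) marks enrichment eligibility only.

A structural property worth knowing: the PMFG of a *single* homogeneous
correlation block is close to a random maximal planar graph, whose best
partitions have Q ≈ 0.3–0.4 with natural communities of ~6–8 nodes. With
min_size 10 such artifactual splits fail the two-large-children rule, so
planted blocks of ~20 genes are returned intact, while genuinely separated
blocks (weak cross-block connectivity) split cleanly. Planted modules much
larger than ~2× min_size can be oversplit into genuine sub-communities of
the planar topology — the hierarchy is then still nested and valid, but the
leaf scale is finer than the plant.

## Hub detection

The null "randomly permuted planar network" is implemented as node-label
permutation of the observed degree sequence: relabeling nodes before
rebuilding the PMFG from the same ranked pair list yields an isomorphic
graph whenever weights are distinct (greedy insertion depends only on the
weight order), so the null degree of a node is the degree of a uniformly
drawn node. p = (1 + #{null ≥ observed}) / (1 + n_perm) with n_perm = 100;
hubs have p < 0.05. In a regular graph no node can be flagged; in a star
the center is.

## Enrichment

One-sided hypergeometric upper-tail p-values; BH correction within one
(module × collection) family, matching per-batch adjustment semantics.
Significance needs overlap ≥ 4 ("greater than three") and aFETP < 0.05.
The default universe is the cohort's filtered expression gene set;
cytoband enrichment treats each band's gene content as one set.

## Prognosis

The eigengene is PC1 of the module's gene-standardized submatrix via SVD;
zero-variance genes are dropped with a warning; the score is mean-centered
and sign-anchored so that corr(score, mean module expression) ≥ 0 (ties in
sign resolved toward +). Median stratification sends scores strictly above
the median to "high", the median itself to "low"; constant scores are a
degenerate-stratification error. The default Cox model regresses survival
on the binary high/low indicator with Efron tie handling (lifelines); a
continuous mode on the standardized eigengene is available and is the right
scale for per-SD hazard-ratio recovery — the median-split contrast estimates
a group effect (roughly exp(1.6β) at baseline, attenuated over follow-up),
not the per-SD HR. Complete separation is caught, the coefficient capped at
|β| = 10 and flagged. Kaplan–Meier curves use the product-limit estimator
per group. Endpoint choice (overall survival vs progression-free interval)
is per-cohort configuration.

## Differential expression and methylation

Per-feature OLS on group + covariates gives effect (log2FC or Δβ) and
residual variance s²_g with d degrees of freedom. The empirical-Bayes prior
(d₀, s₀²) is estimated by moment matching of log variances: with
e_g = log s²_g − ψ(d/2) + log(d/2), the excess of var(e) over ψ′(d/2)
identifies d₀ through a Newton inversion of the trigamma function, and
mean(e) identifies s₀². Shrinkage is s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d);
the moderated t has d₀ + d degrees of freedom (normal when d₀ = ∞). When
the sample variances are literally identical there is no dispersion signal
and the estimator returns the common value unchanged, so shrinkage is a
fixed point and the moderated t equals the ordinary t. Thresholds: DEG
2^|log2FC| > 2 and adjusted P < 0.05; DMC |Δβ| > 0.2 and adjusted P < 0.05
with SNP probes (MAF > 0.05) masked before testing. The Δβ is the model
coefficient (covariate-adjusted mean difference). Promoter windows are
TSS-relative and strand-aware: [t − 2000, t + 200] on +, mirrored on −;
coordinates 1-based inclusive everywhere (BED converted at the reader).
Module regulation labels combine the four Fisher flags (up/down DEG, up/down
DMC) under the standard significance rule.

## Chromatin accessibility

Band signal is the mean over overlapping fixed-width peak regions × samples
(any-overlap: a region spanning a boundary counts in every overlapped
band); fold change divides by the genome background, the mean over all peak
values from all samples — so the region-count-weighted mean of band FCs is
exactly 1 when all bands are covered. The enriched-vs-depleted comparison
is a two-sided Wilcoxon rank-sum: exact enumeration when both groups have
≤ 10 bands, normal approximation with continuity correction otherwise.

## Preservation and aggregation

The Fisher universe for a cohort pair is the intersection of the two
cohorts' network universes, so unmeasured genes cannot reward overlap; BH
correction is per cohort-pair family. Conserved: any pair with J > 0.4 and
aFETP < 0.05. Specific: in *every* other cohort the best-matching
counterpart (highest J) has J < 0.05 or aFETP > 0.05; anything else is
intermediate. Greedy clustering iterates frontier expansion over conserved
pairs until closure; the result equals the connected components of the
conserved-pair graph, hence is invariant to the visit order (tested against
a union-find oracle). Cohort clustering builds a cohort × module-cluster
profile of maximal pair Jaccards, takes cosine distance, and applies
average-linkage hierarchical clustering (cut height configurable).
Aggregation counts supporting cohorts as node/edge weights and removes
nodes below weight 4 — with a 3-cohort study the demo config lowers this to
3, since no gene can appear in 4 of 3 cohorts; the package default stays 4.

## Synthetic data generator

The generator emulates covariate-adjusted TCGA-like expression with a
spiked-covariance latent-factor model: a module gene is
√ρ·f + √(1−ρ)·ε (unit-variance factor f per module and cohort), so the
expected within-module Pearson r equals the target ρ; two-level modules add
a child factor (parent share of ρ configurable, default half). Shared
modules reuse identical gene sets across cohorts; private module genes are
plain noise elsewhere. Covariates (age, sex, race) contribute linear
effects with gene-specific random loadings, giving the adjustment stage
real work. Gaussian noise is assumed throughout — the residual noise family
of real pre-corrected matrices is not characterized, and heavy tails,
batch structure, tumor purity, copy-number and read-level effects are
deliberately not simulated, so passing tests demonstrate correctness of the
estimators under the stated model, not robustness to those artifacts.

Survival times are exponential with log-hazard Σ β_m z_m over the planted
modules' standardized latent factors (the module's true activity), with
independent exponential censoring whose rate is tuned to the configured
censoring fraction (0.3 by default, baseline hazard 10⁻³/day). Parameter
recovery is cleanest with one prognostic module per study: a second
independent hazard driver attenuates the univariate marginal HR
(non-collapsibility of hazard ratios), which the estimator cannot and
should not undo.

Methylation-coupled modules get one promoter probe per gene with
β = logistic(s·k·z + noise), s ∈ {−1, +1} the coupling sign and k = 3 the
slope, giving gene-wise corr(β, expression) strongly negative for s = −1;
tumor/normal contrast is planted by shifting coupled-module expression by
s·2 log2 units in tumors (so s = −1 yields the canonical dDEG-uDMC class).
About 2% of probes on unplanted genes carry a common SNP (MAF 0.1) to
exercise the mask. One probe per gene is deliberate — enough to exercise
promoter mapping and DMC logic without array-density bookkeeping.

The synthetic genome has 4 chromosomes × 6 cytobands of 10 Mb.
Cytoband-assigned module genes sit contiguously (25 kb spacing) in their
band; other genes are uniform. Fixed-width 500 bp peaks tile the genome
every 50 kb over 20 samples, baseline log2 signal N(2, 0.4) with +1.8 in
the "open" bands hosting modules (open/background ratio ≈ 1.7).

Default study: 3 cohorts × 1,200 genes × 200 tumor + 60 normal samples,
12 flat modules of 20–24 genes (4 shared by all, 2 shared by two, 6
private), target within-module r = 0.7, prognostic HR 2.0 and 0.5, two
methylation-coupled modules, four cytoband-assigned (= open-band) modules.
Module sizes near 2× the minimum module size keep the leaf scale of the
hierarchy aligned with the plant (see the clustering note above); the
planted r is the realistic upper range for tight coexpression modules and
keeps the permutation cutoff (~0.27 at n = 200) well below the block
correlation. All generators are deterministic under the configured seed
(independent child streams per cohort and data type).

## Problem sizes and determinism

The shipped study sizes (1,200 genes, 200 samples, 3 cohorts; 500 samples
for survival recovery; 10 × 22 modules for null calibration — independent
survival replicates, because 200 tests against one shared survival draw
overdisperse the flag count) were chosen so the statistical targets are
well-powered at desk scale. Reruns with the same seed are byte-identical
across all output tables; every stochastic step (permutations, Louvain,
hub nulls, generators) draws from seeds derived from the single configured
seed.

## Known limitations

- The multiscale partition search is exact only for parents with ≤ 14
  nodes; larger parents rely on Louvain and may miss the optimal partition.
- The hub null is degree-sequence permutation, not re-grown planar nulls;
  with many tied |r| values the two can differ slightly.
- The Cox stage is univariate (module indicator or eigengene only); no
  clinical covariates or competing risks.
- The moderated-t prior estimation is the closed-form moment-matching
  approximation; no robustification against variance outliers.
- Aggregated-network edge weights are reported but not filtered by default
  (only nodes are), mirroring the stated node-weight rule.
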