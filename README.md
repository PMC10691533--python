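# panconet

Multi-cohort gene coexpression network analysis for tumor transcriptomes:
planar filtered networks, multiscale module hierarchies, module-eigengene
survival testing, epigenetic regulation of modules, and cross-cohort module
preservation — with a fully synthetic multi-omic study generator so every
stage is testable end to end without external downloads.

The package is aimed at computational biologists who want a transparent,
desk-scale reimplementation of the pan-cancer coexpression workflow:
expression matrices go in, and out come per-cohort networks, nested gene
modules, prognostic modules, module-level DEG/DMC regulation categories,
chromatin-accessibility contrasts, conserved/specific module calls, module
clusters, and a conservation-weighted aggregated network.

## The method

**Network construction.** For a covariate-adjusted log2 expression matrix
(genes × samples), all pairwise Pearson correlations are computed. Each gene
row is independently permuted across samples (n = 10 by default) and, for
every candidate cutoff *c*, the empirical FDR is estimated as

&nbsp;&nbsp;&nbsp;&nbsp;FDR(*c*) = E[#{|r<sub>perm</sub>| ≥ *c*}] / #{|r<sub>obs</sub>| ≥ *c*};

the smallest cutoff with FDR ≤ 0.05 is kept. Surviving pairs, sorted by |r|
descending, are inserted greedily into a growing graph whenever the
insertion preserves planarity — the planar maximally filtered graph (PMFG),
which holds at most 3(n − 2) edges.

**Multiscale modules.** The planar network is recursively partitioned by
maximizing Newman's weighted modularity

&nbsp;&nbsp;&nbsp;&nbsp;Q = (1/2m) Σ<sub>ij</sub> [A<sub>ij</sub> − k<sub>i</sub>k<sub>j</sub>/2m] δ(c<sub>i</sub>, c<sub>j</sub>),

accepting a split iff Q > 0 and at least two children reach the minimum
module size (10 genes; modules of 10–500 genes are enrichment-eligible).
Hub genes have connectivity exceeding label-permuted planar nulls
(p < 0.05).

**Module annotation and prognosis.** Modules are tested against gene-set
collections (GMT) and cytoband windows with one-sided Fisher exact tests,
BH-corrected; a hit needs overlap > 3 and aFETP < 0.05. Each module's
eigengene (PC1 of its standardized submatrix) stratifies patients at the
median into high/low groups, and a Cox proportional-hazards model (Efron
ties) flags prognostic modules at P < 0.05, HR > 1 meaning poorer survival
in the high-expression group.

**Epigenetic regulation.** Tumor-vs-normal contrasts use an empirical-Bayes
moderated t statistic (per-feature OLS with age/sex/race covariates;
variances shrunk toward a moment-matched prior). DEGs need fold change > 2
and adjusted P < 0.05; promoter CpGs (2 kb upstream to 200 bp downstream of
the TSS, strand-aware) are DMCs at |Δβ| > 0.2 and adjusted P < 0.05 after
masking probes on common SNPs (MAF > 0.05). Modules are labeled by joint
DEG/DMC enrichment (e.g. dDEG-uDMC). Cytoband-level ATAC signal is averaged
per band, fold-changed against the genome background, and module-enriched
bands are compared with depleted ones by a Wilcoxon rank-sum test.

**Preservation.** Cross-cohort module pairs are scored with the Jaccard
index J = |A∩B|/|A∪B| plus a Fisher test on the shared gene universe:
conserved iff J > 0.4 and aFETP < 0.05; specific iff every best counterpart
has J < 0.05 or aFETP > 0.05. Conserved modules form module clusters by
greedy closure over conserved pairs, cohorts are clustered on conservation
profiles, and target modules merge into an aggregated network whose node and
edge weights count supporting cohorts (nodes below weight 4 are filtered).

## Worked example

Generate the default synthetic study — 3 cohorts × 1,200 genes × 200 tumor
samples with 12 planted modules (4 shared by all cohorts, 2 shared by two,
6 private), prognostic modules with HR 2.0 and 0.5, two
methylation-coupled modules, and four cytoband-colocalized modules — then
run the whole pipeline:

```bash
panconet simulate --out demo --seed 1
panconet all --config demo/pipeline.yaml --out demo/results --seed 1
```

`demo/results/manifest.json` records per-stage counts; for cohort C1 at
seed 1:

```
network stage: {"cutoff": 0.27, "edges": 507, "hubs": 11, "modules": 13, "significant_pairs": 1721}
preservation:  {"clusters": 3, "conserved_modules": 23, "conserved_pairs": 30, "pairs": 312, "specific_modules": 6}
```

The permutation FDR kept pairs with |r| ≥ 0.27 (1,721 of ~719k), the PMFG
retained 507 of them, and multiscale clustering found 13 modules. Across
cohorts, 23 detected modules are classified conserved and 6 specific,
grouping into 3 module clusters — matching the planted sharing structure.
`demo/results/C1.prognosis.tsv` lists the flagged modules:

```
module_id    beta     hr      p  prognostic direction         mode
       M1  0.6639 1.9423 0.0002        True      poor median-split
       M3 -0.9561 0.3844 0.0000        True      good median-split
       ...
```

M1 recovers the planted risk module (median-split HR ≈ 1.94 against the
planted per-SD HR 2.0) and M3 the protective one; `truth.json` in the
fixture directory carries the full ground truth for comparison.

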