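# Methods

## The analysis model

The pipeline treats each region of interest (ROI) as the sampling unit: a
gene × ROI matrix of raw integer counts, annotated with subject, diagnostic
group (HC, PD, MSAP), substantia-nigra quadrant (DM, DL, VM, VL), slide and
nuclei count. The statistical model underlying every stage is a
negative-binomial count model with variance μ + αμ², the standard RNA-seq
convention; α is a per-gene dispersion.

### QC and normalization

ROIs with nuclei count ≤ 90 are dropped (strict inequality: a count of
exactly 90 fails). Genes are never filtered.

Between-lane normalization defaults to upper-quartile scaling: each column
is scaled so that the 75th percentile of its nonzero counts equals the
geometric mean of the per-column upper quartiles. This is idempotent and
leaves a doubled library exactly aligned with its original. Full-quantile
normalization (each column's sorted values replaced by rank-wise means,
tied entries sharing the mean of their positions) and median scaling are
available; upper-quartile is the default because it is robust for targeted
panels and needs no distributional agreement across lanes. Note that with
ties (inevitable in integer counts), full-quantile columns are identical
only up to tie-averaging.

### Removal of unwanted variation (RUV)

We use the control-gene factor-analysis variant: given control genes
assumed free of biological signal, the ROI × k loadings are the leading
right-singular directions (scaled by their singular values) of the
row-centered log(norm + 1) control-gene submatrix, mean-centered per
factor. Controls default to *empirical* controls — the genes with the
largest first-pass differential-expression p-values (minimum over all
group-vs-reference contrasts when there are three groups) among genes with
above-median mean expression. The estimated loadings enter the downstream
GLM as covariates rather than producing "corrected counts"; this keeps the
counts integer and the noise model honest. Default k = 1, matching one
dominant batch axis (slide); it is configurable.

### Differential expression

A deliberately transparent re-implementation of the standard NB Wald
pipeline, with no claim of concordance with any particular package's
internals (no Cox–Reid adjustment, no fold-change shrinkage, no outlier
replacement, no independent filtering). Stages:

- **Size factors**: median-of-ratios over genes expressed in every ROI,
  rescaled to geometric mean 1; upper-quartile fallback (with a warning)
  when no gene is expressed everywhere.
- **Dispersions**: method-of-moments α̂ = max(0, (var − μ)/μ²) on
  size-factor-scaled counts within each design cell, pooled with
  df weights, then shrunk toward a fitted trend α(μ) = a₁ + a₀/μ with gene
  weight ∝ residual df against a fixed prior df of 6. Genes with zero
  variance in every cell are degenerate and get α = 0.
- **GLM**: log link, offset log(size factor), design
  [intercept, group indicator, RUV covariates], fitted by IRLS vectorized
  across genes (batched weighted normal equations with a 1e-10 ridge;
  convergence when max |Δβ| < 1e-8, cap 60 iterations; non-convergent genes
  are flagged and assigned p = 1). Wald p-values are two-sided normal; BH
  adjustment runs across tested (nonzero, converged) genes. With ~24 ROIs
  the normal reference makes the test mildly liberal (null type-I ≈ 0.06 at
  nominal 0.05); BH at 0.05 still holds the empirical FDR under 0.10 in the
  planted benchmark below.
- **Quadrant stratification**: the same contrast run inside each quadrant's
  ROIs with per-stratum BH, matching a design in which each quadrant is
  reported as a separate analysis. Strata with < 2 ROIs per group are
  skipped with a warning.

ROIs, not subjects, are the modeling unit (the study design this emulates
has only 2 subjects per group, so subject-level modeling is not estimable);
consequently subject- or slide-level confounding that RUV fails to absorb
inflates discoveries. This is visible in the synthetic benchmark whenever
`unwanted_sigma > 0` and is a faithful property of the design, not a bug.

### Enrichment

Over-representation per term by the hypergeometric upper tail
P(X ≥ k | N, K, n), with gene sets intersected with the universe first; the
universe defaults to all post-QC genes in the count matrix, standard ORA
practice. The combined score is c = −ln(p) · z. Published combined-score
implementations derive z from rank deviations over precomputed random-set
tables that cannot be reproduced exactly; we define z as the standardized
hypergeometric deviation (k − nK/N)/sd(X), which is deterministic,
parameter-free and monotone in the overlap. Combined scores from different
z definitions are therefore not comparable across tools. Redundant terms
are clustered by average linkage on 1 − Jaccard of their overlap gene sets,
cut at distance 1 − similarity threshold (default 0.5); each cluster is
represented by its lowest-padj term. Gene-overlap Jaccard replaces
ontology-graph semantic similarity deliberately: it needs no ontology
dependency and is defined for arbitrary collections.

### Network propagation and hub genes

Significant DEGs are mapped by symbol onto the PPI network and seeded with
|log2FC|, normalized to a probability vector (the sign is kept for display;
a probability seed cannot carry negative mass). Alternatives are exposed:
positive-part seeding, and a signed split that runs up- and down-seeded
walks separately and averages their stationary vectors. The walk

p⁽ᵗ⁺¹⁾ = (1 − r) W′ p⁽ᵗ⁾ + r p⁰

uses the column-normalized adjacency W′ (zero-degree nodes get a self-loop
column, preserving stochasticity without teleporting their mass) and stops
when the L1 change falls below 1e-8; total mass is asserted conserved at
every iteration, and the returned vector satisfies the fixed-point equation
within 10× the tolerance. The restart rate defaults to r = 0.7, the common
convention in the propagation literature; results are qualitatively stable
in r because it only rebalances seed-locality against diffusion.

Betweenness centrality is computed by Brandes' algorithm with the
unordered-pair convention, on the induced largest connected component of
the full network (a bridge's importance depends on non-DEG paths, so the
DEG subgraph would understate it; subgraph mode remains possible by passing
a subnetwork). Key genes are significant DEG nodes at or above the 0.90
quantile (computed over DEG nodes) of both stationary probability and
betweenness; the quantiles are configurable and 0 recovers "all DEGs".
Ties in the ranked output are broken by betweenness, then symbol, making
output files byte-reproducible.

## The synthetic-data generator

`generate_dataset` draws counts gene-wise from
NB(mean = s_j · q_g · 2^(x_ij β_g + w_j α_g)) with

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | panel size |
| `groups`, `n_subjects_per_group` | (HC, PD, MSAP), 2 | study arms |
| `rois_per_subject` | 12 | one slide per subject, quadrants cycled (3 per quadrant) |
| `frac_de`, `effect_log2fc` | 0.1, 2.0 | planted DE fraction and magnitude (± at random, alternating target group) |
| `nb_dispersion` | 0.2 | central dispersion; per-gene log-normal jitter (σ = 0.3); 0 ⇒ Poisson |
| `libsize_sigma` | 0.3 | log-normal ROI library-size spread |
| `n_unwanted_factors`, `unwanted_sigma` | 1, 0.5 | slide-correlated factor: per-subject N(0,1) base ± N(0,0.3) ROI noise, gene loadings N(0, σ) |
| `n_control_genes` | 500 | truth-labelled subset of non-DE genes |

Baselines q_g are log-normal (median 50, σ = 1.4), spanning roughly three
orders of magnitude; nuclei counts are uniform on [50, 300], so the default
QC threshold removes ~16% of ROIs. The PPI stand-in is a preferential-
attachment graph (connected, simple, heavy-tailed degrees) labelled with
the simulated gene symbols; gene-set collections are random draws from the
universe with an optional fully-planted term.

What the generator does **not** emulate: probe/UMI-level noise, segment QC
beyond the nuclei filter, cell-type composition, spatially smooth expression
fields, gene–gene correlation beyond the shared unwanted factor, and any
correspondence between the synthetic PPI topology and real interactome
modules. Passing tests therefore demonstrate statistical correctness and
calibration of the machinery under the declared generative model, not
biological validity on real GeoMx data.

## Verification problem sizes

The acceptance script and test suite use: 50 random connected graphs
(n ≤ 50) for the RWR-vs-linear-solve oracle; 200 random graphs (n ≤ 7) for
the betweenness enumeration oracle; 10 simulated datasets of 2000 genes ×
(12 vs 12 ROIs) each for null calibration and for FDR/power with 10%
planted DE; 10 datasets of 1000 genes for RUV factor recovery; 100 random
hypergeometric configurations and 20 planted-term collections for
enrichment; and a 300-gene two-contrast pipeline executed twice for
byte-level determinism. These sizes were chosen as the smallest designs at
which each property is a stable population-level statement rather than a
single-draw anecdote.

## Known limitations

- Normal (not t) reference for the Wald statistic: mildly liberal at ROI
  counts in the low tens; mitigated by BH and visible only as the ~0.06
  null type-I rate noted above.
- Empirical controls inherit any biology that is uniformly non-DE but
  group-correlated; with only two subjects per group, RUV cannot fully
  separate subject from group.
- Symbol-based matching between DE tables and the PPI network: unmatched
  symbols are reported and excluded, not resolved through aliases.
- Enrichment combined scores are internally consistent but not numerically
  comparable with tools using rank-based z-scores.
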