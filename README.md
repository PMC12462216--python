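# nigraspace

Analysis pipeline for ROI-based spatial transcriptomics of the substantia
nigra, built for small post-mortem case–control designs (healthy control,
Parkinson disease, and the Parkinsonian subtype of multiple system atrophy)
profiled with GeoMx-style digital spatial profiling: a handful of subjects,
~12 regions of interest (ROIs) per slide spanning the dorsomedial,
dorsolateral, ventromedial and ventrolateral quadrants of the nucleus.

Starting from a gene × ROI raw count matrix the pipeline runs:

1. **QC** — keep ROIs with nuclei count strictly exceeding 90; genes are never filtered.
2. **Normalization** — between-lane upper-quartile scaling (full-quantile and
   median modes available), then **RUV**: unwanted-variation factors estimated
   by SVD of the row-centered log expression of empirical control genes and
   passed downstream as design covariates.
3. **Differential expression** — per-gene negative-binomial GLM
   (log link, median-of-ratios size-factor offsets, moment-based dispersions
   shrunk toward a mean–dispersion trend), Wald test `z = β̂/se(β̂)`, BH
   adjustment, DEGs at adjusted p < 0.05. Quadrant-stratified contrasts use
   per-stratum BH.
4. **Enrichment** — hypergeometric over-representation against GMT gene-set
   collections, with the combined score `c = −ln(p)·z` where
   `z = (k − E[X])/sd(X)` under the hypergeometric null, and average-linkage
   clustering of redundant terms on Jaccard similarity of their overlap genes.
5. **Network propagation (hub discovery)** — significant DEGs are mapped onto
   a protein–protein interaction network with |log2FC| as seed mass and the
   random walk with restart

   p⁽ᵗ⁺¹⁾ = (1 − r) W′ p⁽ᵗ⁾ + r p⁰

   is iterated to its fixed point, where W′ is the column-normalized
   adjacency matrix and r the restart rate (default 0.7). Betweenness
   centrality BC(v) = Σ_{s≠v≠t} σ_st(v)/σ_st (Brandes accumulation) measures
   topological importance; **key genes** are the DEGs in the upper quantiles
   of both the stationary probability and betweenness.

A first-class synthetic-data module generates the whole study design with
known ground truth (planted log2 fold-changes, slide-correlated unwanted
variation, control genes, scale-free PPI stand-in, plantable gene sets), so
every stage is testable end-to-end without downloads.

## Worked example

```python
import pandas as pd
from nigraspace.simulate import SimulationConfig, generate_dataset, generate_ppi
from nigraspace.normalize import (filter_rois, between_lane_normalize,
                                  select_empirical_controls, estimate_ruv_factors)
from nigraspace.de import (DesignSpec, size_factors, estimate_dispersions,
                           nb_wald_test, significant_genes)
from nigraspace.netprop import PropagationConfig, propagate_degs, select_key_genes

cfg = SimulationConfig(n_genes=500, frac_de=0.15, n_control_genes=120, seed=42)
counts, meta, truth = generate_dataset(cfg)
counts, meta = filter_rois(counts, meta, min_nuclei=90)

norm = between_lane_normalize(counts, "upper")
controls = select_empirical_controls(counts, meta, 120)
ruv = estimate_ruv_factors(norm, controls, k=1)

sf = size_factors(counts)
disp = estimate_dispersions(counts, sf, pd.Series(meta["group"].to_numpy(),
                                                  index=meta["roi_id"]))
de = nb_wald_test(counts, meta, sf, disp,
                  DesignSpec(("MSAP", "HC"), covariates=ruv.loadings))
up, down = significant_genes(de)
print("DEGs:", len(up), "up,", len(down), "down")

net = generate_ppi(500, 2, seed=42, genes=counts.genes)
ranked = select_key_genes(propagate_degs(de, net, PropagationConfig()), 0.8, 0.8)
print(ranked[ranked["key"]][["gene", "log2FC", "probability", "betweenness"]]
      .round(4).to_string(index=False))
```

prints

```
DEGs: 23 up, 15 down
 gene  log2FC  probability  betweenness
G0066 -2.6030       0.0321    3503.6818
G0142  2.1486       0.0236    1170.6449
```

62 of 72 ROIs pass the nuclei filter; 38 genes reach adjusted p < 0.05 in
the MSA-P vs HC contrast (all 37 planted MSA-P effects are among them), and
two of those DEGs sit in the top quintile of both network-propagation
probability and betweenness centrality — the pipeline's "key gene" calls,
here hub nodes that carry planted |log2FC| ≈ 2 effects.

The same stages are available from the shell:

```sh
nigraspace simulate --n-genes 500 --frac-de 0.15 --seed 42 --out data/
nigraspace normalize --counts data/counts.tsv --meta data/meta.csv --n-controls 120 --out norm/
nigraspace de --counts norm/counts_filtered.tsv --meta norm/meta_filtered.csv \
              --contrast MSAP,HC --ruv norm/ --out de.tsv
nigraspace netprop --de de.tsv --network data/ppi.tsv --out netprop.tsv
nigraspace run --config run.yaml     # full multi-contrast pipeline + manifest
```

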