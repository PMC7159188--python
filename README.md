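# thymonet

Age-related weighted gene co-expression network analysis (WGCNA) and
TF–miRNA–mRNA integration for grouped transcriptome studies, with a
synthetic-data generator that plants the full statistical structure the
analysis assumes.

The motivating problem: infant thymic tissue transcriptomes sampled across
five sequential age groups (A: 0–30 days … E: 19–31 months), where the
questions are (i) which co-expression modules track age, (ii) which genes
are topologically central (hubs, high intramodular connectivity `kWithin`)
versus trait-driving (HGS genes, high gene significance `GS`), and (iii)
how abundant miRNAs and transcription factors co-vary with those genes.
The package is aimed at computational biologists who want this pipeline as
importable, tested functions rather than a collection of scripts.

## The model in brief

- Similarity: Pearson `r_ij` between log2 gene profiles.
- Adjacency: `a_ij = |r_ij|^β` with β the smallest soft power whose
  connectivity distribution fits a scale-free model at `R² ≥ 0.87` with
  negative slope (grid 1–35).
- Topological overlap:
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`.
- Modules: average-linkage clustering of `1 − TOM` with a dynamic branch
  decomposition; module eigengene `ME` = first principal component of the
  module; membership `kME(g,M) = cor(x_g, ME_M)`.
- Module–trait: `cor(ME, trait indicator)` with Student-t p (gate at
  p < 0.05) plus module significance `MS` = mean member `GS`.
- Selection: hubs = top-5% `kWithin` per significant module; HGS = top-|GS|
  members (GS p < 0.05), capped at 50; DE = Wilcoxon A vs E, 5-group ANOVA
  (BH), signed fold change `FC = ±2^|Δlog2|`.
- miRNAs: per-group abundance cutoff at the knee of the sorted
  linear-intensity curve; DE by raw ANOVA p < 0.01.
- Integration: typed co-expression edges — gene–gene `|r| ≥ 0.70`,
  gene–miRNA `r ≤ −0.50` (negative only), gene–TF `|r| ≥ 0.50` — over hubs,
  HGS genes, abundant miRNAs and expressed interacting TFs.

See `docs/methods.md` for the full account, including the synthetic-data
generator's design and its limits.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data, writing tables to `results/`:

```bash
python analysis/01_simulate_data.py
python analysis/03_build_network.py
python analysis/04_module_trait.py
python analysis/05_select_genes.py
python analysis/06_mirna_abundance.py
python analysis/07_integrative_network.py
```

On the default seed the drivers print, among other things:

```
chosen soft power beta = 5 (scale-free R^2 = 0.889)
15 modules detected (sizes 31-123); 347 genes grey
adjusted Rand index vs planted modules: 0.939
...
  midnightblue ~ E: r = +0.41 (p = 0.0028)
           tan ~ A: r = -0.35 (p = 0.0138)
...
28 hubs across 7 significant modules
50 HGS genes (44 hyper / 35 hypo records)
127 of 495 significant-module genes DE between groups A and E (Wilcoxon p < 0.05)
...
abundant miRNAs per group: {'A': 19, 'B': 19, 'C': 19, 'D': 19, 'E': 19}; union 19 of 428
...
network: 95 nodes ({'hgs': 46, 'hub': 24, 'hub+hgs': 4, 'mirna': 19, 'tf': 2}), 237 edges
all 18 gene-miRNA edges negative (r range -0.66 to -0.50)
```

Reading this: the dynamic cut recovered the 15 planted modules almost
exactly (ARI 0.94); the planted trait-linked modules surface with their
planted correlations (e.g. +0.41 to group E, −0.35 to group A) alongside a
handful of raw-p false positives, which is the expected cost of the
uncorrected p < 0.05 gate; the abundance knee isolates exactly the planted
19-miRNA tier in every group; and the integrative network contains only
negative gene–miRNA edges, as the sign constraint demands.

The same stages are available as a CLI (`thymonet simulate`, `preprocess`,
`network`, `trait`, `select`, `mirna`, `integrate`, `enrich`) and, most
usefully, as library calls:

```python
from thymonet import RunConfig, run_pipeline, simulate_dataset

mrna, mirna, tf, meta, truth = simulate_dataset(seed=0)
res = run_pipeline(mrna, meta, RunConfig(), mirna_expr=mirna, tf_expr=tf)
res.significant_pairs    # [(module, trait, r, p), ...]
res.hubs, res.hgs        # selection tables
res.abundant_union       # abundant miRNA ids
```

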