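# Methods

`thymonet` reimplements, as a tested pipeline over synthetic data, an
age-grouped thymic transcriptome analysis: weighted gene co-expression
network analysis (WGCNA-style), module–trait association, hub and
high-gene-significance (HGS) gene selection, abundant-miRNA selection, and a
sign-constrained TF–miRNA–mRNA integrative co-expression network.

## The analysis model

**Co-expression network.** Gene–gene similarity is the Pearson correlation
`r_ij` of log2 expression profiles (pairwise-complete over missing values,
at least 3 shared samples per pair). The adjacency is the soft-thresholded
correlation, `a_ij = |r_ij|^β` (unsigned, the default) or
`a_ij = ((1+r_ij)/2)^β` (signed). β is chosen as the smallest integer in the
configured grid (default 1–35) whose connectivity distribution fits a
scale-free model at `R² ≥ 0.87` with negative slope; the fit bins the
connectivities `k_i = Σ_{j≠i} a_ij` into 10 equal-width bins and regresses
`log10(relative frequency)` on `log10(mean k)` over non-empty bins. If no β
reaches the cutoff, the β maximizing R² is used with a warning.

**Topological overlap.** `TOM_ij = (L_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij)`
with `L_ij = Σ_{u≠i,j} a_iu a_uj`, `TOM_ii = 1`. Modules are detected on the
dissimilarity `1 − TOM` by average-linkage hierarchical clustering followed
by a dynamic branch decomposition (below). Modules are labelled by size rank
with the conventional colour sequence (largest = turquoise); unassigned
genes are grey.

**Dynamic branch decomposition.** Soft-thresholding compresses TOM
dissimilarities towards 1, so absolute dendrogram heights are nearly
meaningless at high β; what distinguishes a module branch from a
between-module or noise junction is the *scale* of the merge similarity
`u = 1 − height`. Among all branches of at least `min_module_size` leaves,
the values of `log10(u)` form two groups — coherent within-module merges and
junction merges, typically separated by one or more decades. A two-class
minimum-within-variance (Otsu) split locates the boundary, and the coherence
threshold is placed inside the boundary gap; `deep_split` (0–4, default 2)
sets where in the gap it sits (higher = closer to the coherent group =
finer splitting). The dendrogram is then decomposed top-down: a branch whose
merge similarity falls below the threshold is split into its children, a
branch above it becomes a module whole (average linkage is monotone, so all
its internal merges are at least as coherent), and branches smaller than
`min_module_size` (default 30) dissolve into the unassigned pool. Unassigned
genes are then given a second chance: each is assigned to the module whose
eigengene it correlates with best, provided `|kME| ≥ 0.4`; the rest stay
grey. The Otsu-in-log-similarity rule and the kME floor are this package's
own formulation of the usual "dynamic hybrid" idea; on data with no real
group structure the two-class split is arbitrary and spurious modules can
appear, as with any dynamic cut.

**Eigengenes and membership.** The module eigengene (ME) is the first
principal component across samples of the module's row-standardized
expression (SVD), standardized to zero mean and unit variance and
sign-aligned so it correlates positively with the module's mean profile;
variance explained is `s₁²/Σs²`. Module membership `kME(g, M)` is the
Pearson correlation of gene g with ME_M.

**Module–trait association.** Traits are binary one-vs-rest indicators for
each age group A–E plus gender (M = 1). Two module-level summaries are
computed: the ME–trait Pearson correlation with its Student-t p-value
(`t = r√((n−2)/(1−r²))`, n−2 df), and the module significance MS = signed
mean of member-gene gene-significance values (GS = gene–trait Pearson r).
Both are reported; the significance gate selecting modules uses the ME–trait
p at `p < 0.05`, strict inequality. No multiple-testing correction is
applied across the module×trait grid — raw p-values are a deliberate,
documented limitation of the procedure being reimplemented; expect ~5% of
null module-trait pairs to be selected.

**Hubs, HGS genes, differential expression.** Within each significant
module, hubs are the `⌈0.05·n⌉` genes with the highest intramodular
connectivity `kWithin` (ties by `kTotal`, then gene id). The 5% default
stands in for a visual selection (≈6% in the original setting) and is
configurable. HGS candidates are members of significant (module, trait)
pairs with GS p < 0.05, ranked by |GS| and capped at 50 distinct genes
pooled across pairs; a gene may carry both a neonate-group and an
oldest-group record. The DE layer on significant-module genes runs the
two-sided Wilcoxon rank-sum test between groups A and E (exact enumeration
for tie-free samples with n+m ≤ 12, tie-corrected normal approximation
otherwise), one-way ANOVA across the five groups with Benjamini–Hochberg
adjustment, and a signed fold change from log2 group means:
`Δ = mean_A − mean_E`, `FC = 2^Δ` if `Δ ≥ 0` else `−2^(−Δ)`, so `|FC| ≥ 1`.
Whether a fold change of this kind is computed on log2 or linear means is
ambiguous in practice; the log2-mean convention is the default here.

**miRNA abundance.** Abundance is judged on linear intensities (`2^x` of
the log2 matrix) because that is the scale on which expression-distribution
dot plots are drawn and on which published cutoffs (e.g. 453/433/610/514/685
for groups A–E) are expressed. Per group, the per-miRNA mean linear
intensities are sorted descending and the knee — the point of maximum
perpendicular distance to the chord joining the curve's endpoints — marks
the boundary of the abundant tier. The cutoff is placed halfway between the
knee point and its predecessor on the curve rather than on the knee value
itself: the knee lands on the first background feature, and a midpoint
keeps that feature below an inclusive `mean ≥ cutoff` rule instead of
exactly on it. Manual per-group cutoffs are first-class configuration for
reproducing visually chosen values. Group-mean abundance (not per-sample
voting) was chosen for determinism. DE miRNAs use raw one-way ANOVA
p < 0.01, unadjusted.

**Integrative network.** Over hubs, HGS genes, abundant miRNAs and TF
candidates (TFs with a curated interaction edge to ≥1 hub/HGS gene that are
also present in the TF expression matrix), Pearson correlations are computed
on shared samples — gene–miRNA pairs on the intersection of the mRNA and
miRNA sample sets, the only defensible pairing when the two assays cover
different subsets. Edges are admitted by type: gene–gene `|r| ≥ 0.70` (both
signs kept, sign recorded), gene–miRNA `r ≤ −0.50` only (a positive
correlation never becomes an edge), gene–TF `|r| ≥ 0.50`; all thresholds
inclusive. Curated miRNA–TF pairs annotate edges as "validated" but never
create edges. The reporting view rounds r half-away-from-zero to one
decimal; raw values stay on the network object. Over-representation
analysis is a one-sided hypergeometric upper-tail test against user-supplied
GMT collections with BH adjustment — the standard offline equivalent of
web-tool enrichment.

## The synthetic-data generator

The generator (`thymonet.simulate`) plants the statistical structure that
the analysis assumes, with ground-truth labels, so every stage is testable
without downloads.

- **Design.** 50 samples in five balanced age groups (A–E × 10), genders
  alternating; 1,500 genes with 15 modules of 30–120 genes (the 85–403
  range of the motivating study scaled down ~3× for desk-scale runs) and
  25% pure-noise background; 428 miRNAs on a 29-sample subset (6/6/6/6/5
  per group); 63 TFs on the full sample set.
- **Modules.** Each module m has a latent eigengene e_m; member gene
  `g = w·e_m + √(1−w²)·ε` with `w ~ U(0.5, 0.95)` (so w is the
  gene–eigengene correlation at the default `noise_sd = 1`). Three modules
  are trait-linked by default, mirroring the study's pattern: one
  positively and one negatively linked to the oldest group (ρ = +0.41 and
  −0.34) and one linked to both the neonate (−0.31) and oldest (+0.30)
  groups; multi-trait constructions solve a small linear system against the
  empirical indicator correlation matrix and error out when infeasible.
- **Exact in-sample embedding.** Every planted construct residualizes its
  noise component against the target vector and re-standardizes, so the
  empirical correlation of a planted pair equals its target ρ at generation
  (to float rounding). Planted effect sizes are thereby study conditions,
  not draws around them; background features remain iid Gaussian, so null
  calibration (uniform p-values, ≈α false-selection rates) is still
  exercised with real sampling noise.
- **miRNAs.** Background log2 locations are uniform over [3, 6.5]
  (reciprocal-distributed, long-tailed linear intensities); the 19-miRNA
  abundant tier is log-evenly spread over ~4 log2 units starting
  `knee_gap = 5.3` above the background floor, which makes the sorted
  linear curve drop steeply through the whole tier and puts its knee at the
  tier's lower edge (abundant/background mean intensity ratio ≈ 50×).
  Twelve abundant miRNAs carry planted gene partners at r = −0.6 on the
  shared samples. With this construction the knee cutoffs recover the
  planted tier exactly in ~80% of seeds; in the rest a single borderline
  background miRNA joins one group's set.
- **TFs.** Twenty TFs carry planted partners at r = ±0.6; the rest are
  noise. Interaction fixtures emit the planted TF–gene edges plus
  configurable random decoys (never duplicating planted pairs) and
  "validated" miRNA–TF annotations over the abundant tier.

What the generator does *not* emulate: probe-level flag structure beyond a
uniform random NA rate, batch or array effects, heavy-tailed or correlated
noise, gene-length or GC biases, realistic gene symbols, and overlapping or
hierarchically nested modules. Passing tests therefore demonstrate
correctness of the algorithms under the planted model, not performance on
real microarray data, where module boundaries are fuzzier and the
scale-free fit is noisier.

## Numerical and design choices

- Unsigned network type by default (configurable), matching the common
  historical default.
- Correlations use population (n) normalization; eigengene and kME
  computations clip to [−1, 1] against rounding.
- Quantile normalization is the concrete normalization variant behind the
  generic "normalize between arrays" step (configurable off); ties receive
  the mean of the reference values their ranks span.
- Probe collapse keeps the probe with maximal mean expression; ties break
  by lexicographic probe id.
- Flag filtering masks cells with ≥2 quality flags (a count threshold;
  boolean flag dialects should be summed first).
- The group-NA rule is strict as specified: mRNA features drop on a single
  NA in any group; miRNA features drop only when a group is *more than*
  half NA (exactly half survives).
- Degenerate inputs fail loudly: zero-variance genes, constant abundance
  vectors, empty sample intersections, infeasible planted correlations.
- Scaled-down problem sizes in tests and the acceptance script (400–1,500
  genes, 20–100 replicates) were chosen to keep full runs in the minutes
  range on one CPU while leaving all rates far from their thresholds.

## Known limitations

- Module labels (colours) depend on size rank, so a one-gene change can
  swap two labels between runs; comparisons should use gene sets, not
  colour names.
- The Otsu-based coherence split assumes the dendrogram contains both
  coherent and junction merges; on structureless data it still splits
  somewhere and can emit noise modules.
- No module merging by eigengene similarity and no block-wise decomposition
  for very large gene sets.
- Raw (unadjusted) p-value gates in module selection and miRNA DE inflate
  false positives by design fidelity; treat those lists as candidate sets.
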