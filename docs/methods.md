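# Methods

This note documents the statistical procedures implemented in
`cochleasc`, the synthetic data they are validated against, and the
design choices made where the procedure left room.

## Pipeline procedures

### Quality control

A cell is excluded when **any** bound is violated: detected genes
< 200 or > 3,000; total UMI < 1,500 or > 15,000; mitochondrial or
stress-gene UMI share > 5%. The low/high gene–UMI sentence can also be
read conjunctively (both members of a pair must fail); that reading is
available via `QCThresholds.conjunctive_pairs` but the disjunctive
reading — the common practice the wording abbreviates — is the
default. Mito/stress shares are measured as UMI fractions, not
detected-gene fractions, the standard convention. Genes detected in
fewer than 10 cells are removed first. Stress genes are never
enumerated by a standard; the package ships an immediate-early-gene
list (`data/stress_genes.txt`) for real data, and by convention also
recognizes `mt-*`/`stress-*` name prefixes, which the generator uses.

### Normalization, regression, scaling

Expression is `log(1 + s·count/cellTotal)` with scale factor
s = 10,000. Per gene, a least-squares fit on total UMI, mito share and
stress share is removed; residuals are centered, scaled to unit
variance and clipped to ±10 (clip mirrors common scaling practice;
degenerate genes become all-zero rows; collinear covariate columns are
dropped with a warning).

### Clustering and resolution selection

Top 20 principal components (full SVD, component sign fixed so the
largest-magnitude loading is positive) feed a shared-nearest-neighbor
graph (k = 20 neighbors, Jaccard edge weights, pruning below 1/15).
Modularity community detection (RB-configuration, Leiden) runs at
resolutions 0.2–2.4 in steps of 0.2. Each partition's quality is the
out-of-bag misclassification rate of a 100-tree random forest
predicting labels from the embedding. "Low OOB error and high cluster
number" is not by itself an algorithm; it is formalized here as the
smallest rule consistent with the phrase: among partitions with OOB
error within 0.05 of the minimum, take the maximum cluster count,
breaking ties toward the lower resolution. A single-cluster partition
is defined to have OOB error 0 (with a warning).

### Differential expression and screens

Two-group DE is the two-sided Wilcoxon rank-sum test on log-normalized
values, gated before testing by min.pct = 0.25 and |avg logFC| ≥ 0.25.
avg logFC is the difference of group means on the natural-log
normalized scale (log2 available by flag). Adjustment is Bonferroni
over the genes actually tested — the convention of the marker tables —
while FDR control (Benjamini–Hochberg) is used along pseudotime and
raw p < 0.05 in the pathway U/D counts, each exactly where that
criterion is conventional. The exclusivity screen takes genes detected
in ≥ f_on = 0.3 of the target cluster and ≤ f_off = 0.1 of every other
cluster; the screen in the source analysis is verbal, so these
defaults are declared, not derived. Cross-dataset concordance marks a
DE gene eligible when its reference fold (pseudocount 1 on both means)
is ≥ 2 in either direction and concordant when directions agree.

### Trajectory and phase modules

Ordering builds a minimum spanning tree over cluster centroids in the
embedding and projects every cell onto its nearest tree edge;
pseudotime is arc length from the root cluster, normalized to [0, 1].
This is a deliberate, simpler substitute for tree-embedding methods:
the tested contract is ordering fidelity and at most one bifurcation,
which the MST + projection construction preserves and makes easy to
verify. Ordering uses a coarse backbone clustering at a fixed
resolution (default 1.0) rather than the finest typology — an MST over
many fine centroids zigzags through noise and degrades rank fidelity.
Trees with more than one degree-3 node are tolerated with a warning;
branches split at the bifurcation nearest the root. The root is given
explicitly or chosen as the cluster with the highest mean expression
of a progenitor marker set.

DE along pseudotime compares a cubic B-spline fit (3 internal knots at
pseudotime quantiles, gaussian working model on log-normalized values)
against an intercept-only model with an F-test, then BH at FDR 0.1.
The gaussian spline F-test substitutes for a count-model likelihood
ratio; downstream use is rank- and recovery-based, which the
substitution preserves.

Significant genes' fitted trends on a 50-point grid are z-scored and
partitioned by seeded k-means. With k = "auto", k ∈ {2..8} maximizes
the **macro-averaged** silhouette (mean over clusters of each
cluster's mean silhouette). The macro average is used deliberately: at
FDR 0.1 roughly a tenth of the significant genes are false positives
whose trends are incoherent wiggles, and under the per-gene average a
small junk cluster of them can buy an extra k by a hair's breadth;
averaging per cluster removes that reward while agreeing with the
per-gene average on clean inputs. Module ids are renamed phase_1..k in
order of their mean trend's peak position, so labels follow time.

### Regulons

Pseudocells are arithmetic means of 5–20 cells drawn uniformly without
replacement within one cell type (50 pseudocells per type by default;
types smaller than the pool minimum are skipped with a warning).
Regulon inference — a stand-in for motif-pruned co-expression methods,
which need external motif databases — thresholds Spearman correlation
with each TF across pseudocells at 0.3, optionally capped by
descending correlation; regulons can instead be supplied as a GMT.
RAS ranks genes per pseudocell by descending expression (ties broken
by gene name) and takes the area under the recovery curve of the
regulon's targets within the top ⌈0.05·G⌉ ranks, normalized by the
maximal achievable area (0.05 is the customary recovery-curve cutoff).
RSS = 1 − sqrt(JSD(p_R, p_C)) with base-2 logs (0·log 0 ≡ 0), where
p_R is the RAS vector normalized to sum 1 and p_C the normalized
indicator of the target type; base 2 bounds JSD and hence RSS in
[0, 1]. Ranking is by descending RSS, ties by regulon name.

### Regulation matrix and disease maps

Per pathway, per cell type, Wilcoxon DE between the later and earlier
time points (no pct or fold gate) counts U (up, raw p < 0.05) and D
(down). p(U) = U/(U+D) and p(D) = D/(U+D); pathways with U + D = 0 are
undefined (NA) and drop out — p(U) is not defined at 0/0, and dropping
preserves the normalization identities. Per type, the p(U) and p(D)
vectors are each normalized to sum 1 over the non-NA pathways and
subtracted. Consequences tested as invariants: entries lie in [−1, 1],
per-type entries sum to 0, and swapping the two time points negates
the matrix exactly. Disease maps are cluster-averaged z-scores
(z-score per gene across all cells, then mean within cluster) for each
disease-gene class, with absent genes listed separately.

## The synthetic generator

Counts are negative binomial: gene g in cell c has mean
m_g · f(g, c) · l_c with inverse-dispersion r = 2, where m_g is a
Gamma(0.5)-distributed base mean (scale such that E[m] = 2, giving
~4,500 UMI per 2,000-gene cell), l_c is lognormal(0, 0.25), and f
carries the planted structure:

- **Cell types** — 25 marker genes per type upregulated 6-fold in
  their type (base means drawn in [0.5, 1.5]× the mean scale so the
  fold is detectable), plus 5 *exclusive* genes per type expressed at
  normal levels in their type and at 0.003× elsewhere. The two classes
  mirror real marker tables: most markers are graded, a handful are
  effectively on/off, and only the latter are what an
  exclusive-expression screen targets.
- **QC violators** — designated cells rewritten to violate exactly one
  rule: low-complexity (~150 detected genes, ~300 UMI),
  high-complexity (counts scaled past 15,000 UMI), high-mito /
  high-stress (special-gene counts re-drawn to an ~8% share). Normal
  cells draw mito/stress shares from Beta(40, 1960) (≈2%, tight) with
  mildly dispersed counts (10·r), so that no normal cell crosses the
  5% bound by sampling noise and planted violators define the excluded
  set exactly — an invariant the QC tests assert.
- **Trajectory** — pseudotime uniform on [0, 1]; four 50-gene modules
  whose means follow marker_fold^s(t) for template s: early-decreasing
  (1−t)², a transient peak at t = 0.35, a mid bump at t = 0.68, and a
  late sigmoid at t = 0.88. The shapes are spaced to be roughly
  equidistant in z-scored trend space, as four genuinely distinct
  temporal programs are; two near-collinear pairs would make any
  shape-based module count ambiguous between 2 and 4.
- **Regulons** — a latent-factor model: within a TF's active type, the
  TF and its targets share a lognormal(0, 1) activity factor
  (multiplier 1 + coupling·(fold−1)·z) and their conditional draw is
  near-Poisson (10·r). The factor carries the biological
  co-variability; folding it into a single bursty NB draw caps
  achievable TF–target correlation near 0.5 because conditional NB
  variance grows with the squared mean.
- **Time points** — two independent draws from one shared structure;
  the second multiplies each pathway's designated up/down genes by
  e^{±ln 2}. Up/down fractions are per pathway (the default preset
  alternates up- and down-shifted pathways), because the regulation
  matrix contrasts pathways within a type and is identically ~0 when
  every pathway shifts the same way.

Preset scales: p1 = 15 types × 100 cells, p7 = 12 × 100, trajectory =
600 cells, regulons = 5 types × 150 cells with one active regulon per
type, timepoints = 3 types × 150 cells per time point, all at 2,000
genes. These sizes keep every recovery experiment (10 seeds each)
within a few minutes on one CPU while leaving comfortable margins on
the recovery criteria.

### What the generator does and does not emulate

It reproduces the statistical structure the pipeline's inferences rely
on: overdispersed UMI counts, library-size variation, discrete
expression programs, graded and exclusive markers, smooth temporal
modules, factor-driven co-expression, and directional pathway shifts.
It does **not** emulate ambient RNA, doublets, batch effects (optional
covariate shifts only), tonotopic gradients within a type, realistic
gene–gene correlation beyond the planted factors, or real cochlear
gene names beyond a few mnemonics. Passing recovery tests therefore
demonstrates that the procedures recover the structure they assume
when it is present at realistic noise levels — not that real cochlear
data satisfy those assumptions.

## Numerical choices and degenerate inputs

- Wilcoxon p-values are asymptotic with tie correction; groups smaller
  than 3 cells are errors.
- Component signs in PCA fixed by largest-|loading|; k-means seeded
  with n_init = 10; community detection seeded; all stage seeds derive
  from the config seed, and identical config + seed reproduces every
  table byte-for-byte.
- Zero-variance genes: all-zero rows (z-scores, scaling) with a
  warning rather than NaNs.
- RAS ties: ranking ties broken by gene name so results are
  order-independent.
- Equal-size cluster ties in size-relabeling fall back to community
  id; permutation invariance is exact when cluster sizes differ.

## Known limitations

- The OOB tolerance band (0.05) and the exclusivity thresholds are
  declared defaults; the source procedures state no numeric rule.
- Pseudotime fidelity is bounded by the centroid-tree resolution;
  observed Spearman agreement with planted time is 0.92–0.98 per run
  on the trajectory preset, not arbitrarily close to 1.
- Only one bifurcation is modeled; deeper branching collapses onto the
  nearest-root split with a warning.
- Regulon "significance" is a correlation threshold, not a motif-based
  enrichment test; supplied-regulon mode bypasses inference entirely.
- The two-timepoint statistic treats cells as exchangeable within
  type × time point; replicate structure is not modeled.
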