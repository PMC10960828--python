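# Methods

This note documents the models behind each stage, the defaults that
matter, what the synthetic generators do and do not emulate, and the
design decisions taken where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic data generators

### Lineage simulator (`simulate_lineage_cells`)

Cells are assigned uniform integer depths `d ∈ {0..tree_depth}` of a
differentiation hierarchy. The number of active genes per cell is
`round(genes_active_root · (1 − activity_decay)^d)`, jittered by binomial
thinning from a slightly inflated pool (s.d. ≈ 5 % of the target) so
depths are not perfectly separable. Active genes are a uniform random
subset per cell; counts are negative-binomial (gamma–Poisson) with mean
`nb_mean` (default 2.0) and dispersion `nb_dispersion` (default 2.0),
zero elsewhere. A planted module (default 50 genes, the first gene
indices) has its NB mean multiplied by
`1 + (1 − d/tree_depth) · module_effect` (default effect 2.0), emulating
a stemness programme that peaks at the root. Defaults: 500 cells, 1000
genes, 600 active at the root, decay 0.2 per depth step, depth 4 — sized
so that the expressed-gene count spans roughly 600 → 250 across the
hierarchy, comfortably above the noise floor while leaving overlap
between adjacent depths.

`simulate_stroma_cells` draws a companion population from the same
baseline with the module silenced (counts on module genes thinned by
90 %) and no depth structure. This emulates the fact that a malignant
programme is largely absent from stroma and immune cells; it is what
makes the avg_logFC > 0.5 marker rule meaningful at this scale, since an
unboosted copy of the same baseline differs by only ~0.3 natural-log
units after library normalization.

`simulate_cnv_profiles` overlays copy-number segments on a random
malignant subset: losses thin counts binomially (p = multiplier), gains
add Poisson counts with mean `(multiplier − 1) ×` the observed count, so
the conditional mean is multiplied exactly while counts stay integral.

### Visium simulator (`simulate_visium_sample`)

Spots sit on a 10x-style offset hex lattice (array_row and array_col of
equal parity; planar pitch 1). A tumor disc of configurable radius holds
malignant expression: CNV segment means multiplied by the segment
multiplier, and a CSC signature whose loading rises linearly toward the
disc centre. The macrophage signature follows the CSC loading into a
one-spot fringe beyond the rim with multiplicative noise — at
`colocation_strength = 0` it is spatially unstructured instead. The ten
immune marker genes (PTPRC, CD2, CD3D, CD3E, CD3G, CD79A, MS4A1, CD79B,
CD68, CD14) dominate a distal corner region that downstream reference
selection should find. Ground truth (region, loadings, malignant flag) is
written into `obs`.

**What the generators do not emulate:** doublets, ambient RNA, batch
effects, cell-type deconvolution mixtures within spots, image features,
and realistic gene-length/GC biases. Passing recovery tests therefore
shows the algorithms are correctly implemented and behave as designed
under their own assumptions — not that they are robust to every artefact
of real tissue data.

## Stemness scoring

Log-normalization scales each cell to the median library size and applies
log1p. The gene-count correlate signature (top 200 genes by Pearson
correlation with the expressed-gene count) is averaged per cell, then
smoothed by iterating `s ← α·M·s + (1 − α)·raw` (α = 0.9, tolerance 1e-4,
max 200 iterations) where `M` is the row-normalized kNN adjacency
(k = 30, on 30 PCs) with self-loops, so smoothing is aperiodic and each
update is a convex combination — smoothed scores provably stay inside the
raw range. Rank normalization (average ranks, scaled by `1/(n−1)`) forces
the [0, 1] span whenever smoothed scores are distinct. Classification
uses strict quantile thresholds: cells exactly at a threshold stay
intermediate, which is deterministic and conservative under ties.

A caveat tested explicitly: rescaling every library rescales the median
target too, so the end-to-end score is only *approximately* invariant to
global library scaling (rank agreement ρ > 0.95 in the suite); exact
invariance holds for the rank-normalization step itself.

## Metacells

Feature genes are selected by variance/mean > 0.08 on counts down-sampled
(binomial thinning) to the 5th-percentile library size, after removing
"MT-"-prefixed genes. The balanced kNN graph keeps edge (i, j) only if j
is in i's top K = 100 and i is in j's top 3K. Each of the resampling
iterations (75 % of cells) clusters the induced subgraph by connected
components of its mutual-top-K subgraph; co-membership frequencies are
accumulated, average-linkage clustered (cut at frequency 0.5), and
clusters under the 50-cell floor are merged into their most co-clustered
neighbour.

On data with discrete subpopulations this recovers the populations
exactly (ARI 1.0 on two planted blobs). On *continuum* data — a single
differentiation gradient — the mutual-top-K graph is connected and the
consensus collapses to one metacell. That is correct behaviour for a
consensus-of-components design, so the co-expression stage provides
`pseudobulk_by_rank` as its aggregation fallback: equal-size groups of
cells along the observable smoothed-stemness ordering, which yields
homogeneous pseudo-observations without consulting generator truth.

## Co-expression modules and the signature

The workflow keeps the top variable genes (by variance across
metacells), builds the unsigned adjacency `|cor|^β`, computes TOM, and
cuts the average-linkage tree of `1 − TOM` at a fixed height; clusters
under `min_module_size` go to module 0 and surviving modules are labelled
in decreasing size.

Two defaults differ from genome-scale practice, deliberately. On networks
of a few hundred genes the TOM distribution compresses toward 1, so (1)
the static cut default is 0.97 rather than the 0.99 used on
genome-scale dissimilarities, and (2) a fixed adjacency exponent β = 6 is
used by the pipeline: the scale-free criterion is a poor guide at this
size (it accepts β = 1, which destroys module separation, and β = 9
over-shrinks weak correlations). `pick_soft_threshold` implements the
scale-free selection rule exactly — smallest candidate power whose signed
R² of the binned log–log degree regression reaches 0.8, falling back to
9 — and is unit-tested against an independent re-evaluation of that rule;
it is simply not trusted blindly at desk scale. Signed networks were also
evaluated and performed worse here (they merge everything, because the
compositional anti-correlation an unsigned network might wrongly absorb
is weak relative to the positive module signal), so the unsigned default
stands.

Module eigengenes are first principal components across metacells of the
standardized module submatrix, sign-fixed so the correlation with the
module's mean expression profile is non-negative. Module–trait p-values
come from `t = r·sqrt((n−2)/(1−r²))` with n−2 df. Markers use a candidate
screen at |logFC| > 0.25 and a final rule avg_logFC > 0.5 with a
two-sided Wilcoxon rank-sum p < 0.05 (exact for small tie-free groups,
normal approximation otherwise); avg_logFC is the natural-log fold change
of de-logged normalized means with pseudocount 1. The signature is the
alphabetically ordered intersection of the best-|r| module with the
marker list.

## AUC gene-set scoring

Genes are ranked per observation in descending expression with ties
broken by a deterministic shuffle keyed on (tie_seed, observation index).
With `H(k)` the number of set genes at rank ≤ k and m the effective set
size, `AUC = Σ_{k=1..maxRank} H(k) / Σ_{k=1..maxRank} min(k, m)`;
`maxRank = ⌈0.05 · n_genes⌉`. The normalizer is the area of a perfectly
front-loaded set, so AUC ∈ [0, 1] with 1 attained exactly at perfect
front-loading; the statistic is invariant to any strictly monotone
transform of expression. Sample-level CSC scores are means over malignant
observations; the median split sends at-median ties to "low".

## CNV inference and malignant calling

Genes with mean normalized expression < 0.1 are dropped. Residuals
`log2(norm + 1)` minus the reference per-gene mean are clipped at ±3,
smoothed per chromosome by a centred 51-gene moving average (truncated at
chromosome ends), median-centred per observation, and denoised by zeroing
entries within 1.5 reference standard deviations of zero. Six states come
from cuts at (−t₃, −t₁, t₁, t₂, t₃) with (t₁, t₂, t₃) = (0.1, 0.2, 0.3):
two deletion grades below neutral state 3 and three amplification grades
above, mirroring six-state copy-number semantics where amplification is
finer-grained. Gene score = |state − 3|; a cluster's score sums the
scores of its per-gene modal-state profile (the alternative — summing
per-spot scores — is a config-free one-liner a caller can do from the
states matrix; the modal profile is less sensitive to sporadic noise
states).

The reference cluster is the first-phase (Leiden, resolution 0.8) cluster
with the highest median NormalScore (mean log-normalized expression of
the ten immune markers; missing markers are skipped with a warning; ties
go to the lowest cluster id). Non-reference spots are Ward-clustered into
8 clusters on their smoothed profiles, and malignant clusters are the
high group of a 1-D 2-means split of cluster scores. A fixed absolute
score threshold was rejected because the score scales with the number of
retained genes; the 2-means split preserves the intended "high group vs
low group" contrast at any data scale, and degenerates to "no malignant
clusters" when all scores are equal.

## Boundary geometry and co-location

Spots are adjacent when their centre distance is ≤ 1.2 × the minimum
pairwise distance (pixel coordinates when present, else coordinates
derived from the offset lattice), giving ≤ 6 neighbours per spot. The
outer rim contains tumor-cluster spots with a neighbour outside the
cluster *or* fewer than six neighbours (so a tumor reaching the tissue
border still has a rim there). The boundary band is all spots within
hex-graph BFS distance `width` (default 3) of any rim spot, on both sides
of the rim — the band deliberately includes tumor-side and
non-tumor-side spots, each labelled. Graph distance was chosen over
Euclidean distance because the band is specified in spot widths.
Co-location is quantified by Spearman correlation of two per-spot
signature scores plus an odds ratio and two-sided Fisher exact p from the
median-split 2×2 table.

## Communication scoring

Group summaries are Tukey trimeans `(q25 + 2·q50 + q75)/4`, robust to the
zero-inflation of sparse data. Receptor complexes use the geometric mean
of subunit trimeans with a hard zero if any subunit is silent. The score
`L·R/(0.5 + L·R)` is a saturating law-of-mass-action form (half
saturation 0.5 on the summary scale), bounded in [0, 1) and monotone in
both factors. Permutation p-values shuffle group labels (default 100
permutations) with the +1 correction, hence valid if conservative;
p-values are uniform under a continuous-expression null (tested by KS),
while heavily tied count data makes them conservative — a property, not a
bug, of the ≥-counting rule.

## Survival utilities

The log-rank statistic is computed from the standard risk-table
observed-minus-expected sums with hypergeometric variances (verified
against lifelines to 9 decimal places in the suite); maxstat scans all
cutpoints leaving ≥ 10 % of records on each side and returns the argmax
of |O−E|/√V, ties to the smaller cutpoint. The suite demonstrates the
selection anti-pattern explicitly: testing the selected split with a
naive log-rank p inflates type-I error above nominal, which is why the
returned statistic should be referred to maximally-selected-rank
critical values before interpretation. The IHC composite is the product
of intensity (0–3) and positive-area (0–4) scores, giving the 9 distinct
values in [0, 12].

## Problem sizes and determinism

The test and acceptance runs use desk-scale sizes chosen to keep every
planted effect well above its estimation noise: 200–3000 cells, 500–1000
genes, 30×30 to 40×40 lattices, 50–100 resampling iterations, 99–100
permutations. Every stage takes an explicit seed; the pipeline driver
derives per-stage seeds from one master seed and writes a manifest with
content checksums, and two runs from the same config are byte-identical.

## Known limitations

- The consensus metacell partition is not a graph-cover algorithm; on
  gradient-only data it returns one metacell (see above).
- The six-state discretization is a fixed threshold ladder, not an HMM;
  states 5 and 6 are separated only by the (t₂, t₃) spacing, and
  threshold defaults are tied to the residual scale of log2 expression.
- The maxstat statistic is returned uncorrected; no small-sample
  correction for the log-rank variance is applied.
- AUC tie-shuffling makes scores on all-zero observations arbitrary but
  reproducible.
- The module-detection static cut trades the adaptivity of dynamic tree
  cutting for determinism; very unequal module sizes at small n may
  require adjusting `cut_height`.
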