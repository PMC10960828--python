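# stemniche

A Python toolkit for deriving a cancer-stem-cell (CSC) gene signature from
single-cell RNA-seq and localizing CSC / macrophage co-location at tumor
boundaries in Visium-style spatial transcriptomics — built for
hepatocellular-carcinoma-style analyses and exercised end-to-end on
synthetic data with planted ground truth.

## Who it is for

Computational biologists who want a transparent, fully tested
re-implementation of the common analysis chain

```
stemness scoring → metacell aggregation → co-expression modules →
signature derivation → gene-set (AUC) scoring → CNV-based malignant-spot
calling → tumor-boundary geometry → ligand–receptor communication →
survival cutpoints
```

without depending on the half-dozen R packages that usually provide the
individual steps — and who need every stage to be testable against
simulated data whose truth is known.

## The methods, briefly

- **Stemness score.** Cells lower in a differentiation hierarchy express
  more genes. Per cell, count expressed genes `G_c`; correlate every
  gene's log-normalized expression with `G`; average the top-200
  correlates into a raw score; smooth by iterating
  `s ← α·M·s + (1−α)·raw` over a row-normalized kNN transition operator
  `M` in PCA space; rank-normalize to [0, 1]. Top/bottom quartiles are
  CSC / non-CSC.
- **Metacells.** Pearson cell–cell similarity on over-dispersed feature
  genes (variance/mean of down-sampled counts > 0.08, "MT-" genes
  removed), balanced kNN (K = 100, in-degree cap 3K), 75 % resampling
  with consensus over mutual-top-K connected components, minimum metacell
  size 50. Metacell expression = member mean.
- **Modules.** Unsigned weighted network `a_jk = |cor(x_j, x_k)|^β`,
  topological overlap `TOM_jk = (Σ_u a_ju a_uk + a_jk)/(min(k_j,k_k)+1−a_jk)`,
  average-linkage clustering of `1 − TOM` with a static cut; module
  eigengene = first principal component across metacells; module–trait
  Pearson `r` with a t-distribution p-value. The signature is the
  best-correlated module intersected with malignant markers
  (avg_logFC > 0.5, Wilcoxon p < 0.05 vs stroma).
- **AUC gene-set score.** Per observation, rank genes descending;
  `AUC = Σ_{k≤maxRank} H(k) / Σ_{k≤maxRank} min(k, m)` with
  `maxRank = ⌈0.05·n_genes⌉` — 1 for a perfectly front-loaded set.
- **CNV calling.** Residual log2 expression vs a reference cluster
  (highest median immune-marker NormalScore), chromosome-wise moving
  average, median centring, 1.5 σ denoising; six states via cuts at
  (−t₃, −t₁, t₁, t₂, t₃); per-gene score `|state − 3|`; cluster score =
  sum over the cluster's modal-state profile; Ward clustering into 8
  clusters; malignant = high group of a 2-means split of cluster scores.
- **Boundary band.** Rim = tumor spots with a neighbour outside the
  cluster (or on the lattice border); band = all spots within hex-graph
  BFS distance 3 of the rim, split into tumor / non-tumor sides.
- **Communication.** Tukey-trimean group summaries, geometric-mean
  receptor complexes, score `L·R/(0.5 + L·R)`, label-permutation p-values
  with the +1 correction.
- **Survival.** Maximally selected rank-statistic cutpoints over a
  standardized log-rank statistic; two-sided log-rank test; IHC composite
  = intensity (0–3) × area (0–4) ∈ [0, 12].

## Worked example

```bash
python examples/stemness_scoring.py
```

prints

```
cells scored:            500
score range:             [0.00, 1.00]
Spearman vs true depth:  0.951
state counts:            {'intermediate': 250, 'nonCSC': 125, 'CSC': 125}
```

The generator plants a differentiation hierarchy (depth 0 = root); the
score recovers it with Spearman ρ = 0.95, spans exactly [0, 1] by rank
normalization, and labels exactly a quarter of the cells CSC. The other
examples cover signature derivation (`derive_signature.py`, Jaccard 0.95
against the planted module), malignant-spot calling and boundary
co-location (`spatial_tumor_calling.py`, spot accuracy 1.000, band
co-location ρ = 0.31 at p = 2×10⁻⁷), ligand–receptor scoring
(`cell_communication.py`, the planted SPP1–CD44 pair ranks first at the
permutation-p floor 0.0099), and survival cutpoints
(`survival_cutpoint.py`).

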