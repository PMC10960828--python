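"""Per-cell differentiation-state (stemness) scoring.

The score follows the expressed-gene-count premise: cells lower in a
differentiation hierarchy express more genes.  A signature of genes whose
expression tracks the per-cell expressed-gene count is averaged into a raw
score, smoothed over a kNN graph in PCA space, and rank-normalized to
[0, 1] (1 = most stem-like).  Cells in the top and bottom quantiles are
labelled CSC and non-CSC respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "StemnessParams",
    "StemnessResult",
    "compute_gene_counts",
    "log_normalize",
    "score_stemness",
    "classify_states",
]


@dataclass
class StemnessParams:
    top_k_genes: int = 200      # signature size
    knn_k: int = 30             # smoothing-graph neighbours
    n_pcs: int = 30             # PCA dimensions for the graph
    diffusion_alpha: float = 0.9
    max_iter: int = 200
    tol: float = 1e-4
    csc_quantile: float = 0.25  # top/bottom quantile labelled CSC / non-CSC

    def validate(self, n_genes: int) -> None:
        if not 0.0 < self.csc_quantile < 0.5:
            raise ValueError("csc_quantile must lie in (0, 0.5)")
        if self.top_k_genes > n_genes:
            raise ValueError("top_k_genes cannot exceed the number of genes")
        if not 0.0 <= self.diffusion_alpha < 1.0:
            raise ValueError("diffusion_alpha must lie in [0, 1)")


@dataclass
class StemnessResult:
    gene_counts: np.ndarray
    signature_genes: list[str]
    raw_score: np.ndarray
    smoothed_score: np.ndarray
    final_score: np.ndarray
    state: np.ndarray = field(default=None)


def compute_gene_counts(adata: ad.AnnData) -> np.ndarray:
    """Number of genes with at least one raw count, per cell."""
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty matrix")
    X = adata.X
    if hasattr(X, "toarray"):
        counts = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        counts = (np.asarray(X) > 0).sum(axis=1)
    return counts.astype(np.int64)


def log_normalize(adata: ad.AnnData, layer: str = "lognorm") -> np.ndarray:
    """log1p of counts scaled to the median library size; stored as a layer."""
    X = np.asarray(adata.X.toarray() if hasattr(adata.X, "toarray") else adata.X, dtype=float)
    lib = X.sum(axis=1)
    if (lib == 0).any():
        lib = np.where(lib == 0, 1.0, lib)
    target = np.median(lib)
    norm = np.log1p(X / lib[:, None] * target)
    adata.layers[layer] = norm
    return norm


def _rank_unit_interval(values: np.ndarray) -> np.ndarray:
    """Average ranks mapped onto [0, 1] (0 = minimum, 1 = maximum)."""
    n = len(values)
    if n < 2:
        return np.zeros(n)
    r = stats.rankdata(values, method="average") - 1.0
    return r / (n - 1.0)


def score_stemness(adata: ad.AnnData, params: StemnessParams | None = None,
                   seed: int = 0) -> StemnessResult:
    """Score stemness on [0, 1] for every cell of a raw count matrix.

    Pipeline: log-normalize; correlate each gene with the expressed-gene
    count; average the top ``top_k_genes`` correlates into a raw score;
    smooth by iterating ``s <- alpha * M s + (1 - alpha) * raw`` over a
    row-normalized kNN transition operator built on the top PCA components
    (self-loops included so smoothing is aperiodic); rank-normalize.
    """
    params = params or StemnessParams()
    params.validate(adata.n_vars)
    n = adata.n_obs
    if n < max(10, params.knn_k + 1):
        raise ValueError(f"need at least {max(10, params.knn_k + 1)} cells")

    gene_counts = compute_gene_counts(adata)
    if np.all(gene_counts == gene_counts[0]):
        raise ValueError("degenerate input: expressed-gene count is constant")

    norm = adata.layers.get("lognorm")
    if norm is None:
        norm = log_normalize(adata)
    norm = np.asarray(norm)

    gc = gene_counts - gene_counts.mean()
    gc_sd = gc.std()
    centered = norm - norm.mean(axis=0)
    sd = centered.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered * gc[:, None]).mean(axis=0) / (sd * gc_sd)
    corr = np.nan_to_num(corr, nan=-np.inf)  # constant genes can never be signature

    order = np.argsort(corr)[::-1]
    sig_idx = np.sort(order[: params.top_k_genes])
    signature = [adata.var_names[i] for i in sig_idx]
    raw = norm[:, sig_idx].mean(axis=1)

    n_pcs = min(params.n_pcs, n - 1, adata.n_vars)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(norm)
    nn = NearestNeighbors(n_neighbors=min(params.knn_k + 1, n)).fit(pcs)
    _, idx = nn.kneighbors(pcs)  # first column is the cell itself (self-loop)

    s = raw.copy()
    for _ in range(params.max_iter):
        ms = s[idx].mean(axis=1)  # row-normalized adjacency incl. self-loop
        s_new = params.diffusion_alpha * ms + (1.0 - params.diffusion_alpha) * raw
        if np.max(np.abs(s_new - s)) < params.tol:
            s = s_new
            break
        s = s_new

    final = _rank_unit_interval(s)
    result = StemnessResult(
        gene_counts=gene_counts,
        signature_genes=signature,
        raw_score=raw,
        smoothed_score=s,
        final_score=final,
    )
    result.state = classify_states(final, params.csc_quantile)
    return result


def classify_states(final_score: np.ndarray, q: float = 0.25) -> np.ndarray:
    """Label cells CSC / intermediate / nonCSC by strict score quantiles.

    Cells strictly above the (1-q) quantile are CSC, strictly below the q
    quantile non-CSC; cells exactly at a threshold stay intermediate
    (conservative tie policy).
    """
    if not 0.0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    final_score = np.asarray(final_score, dtype=float)
    hi = np.quantile(final_score, 1.0 - q)
    lo = np.quantile(final_score, q)
    state = np.full(len(final_score), "intermediate", dtype=object)
    state[final_score > hi] = "CSC"
    state[final_score < lo] = "nonCSC"
    return state.astype(str)
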