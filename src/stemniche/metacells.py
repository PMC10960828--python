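"""Metacell partitioning by balanced kNN graphs and resampled co-clustering.

Transcriptionally homogeneous groups of cells ("metacells") are derived by
(1) selecting over-dispersed feature genes on down-sampled counts,
(2) building a balanced kNN graph from Pearson cell-cell similarities,
(3) repeatedly resampling cells and recording which pairs co-cluster in the
mutual-top-K subgraph of each resample, and (4) consensus clustering of the
co-clustering frequencies with a minimum metacell size.  Metacell
expression is the arithmetic mean of member cells' (log-normalized)
expression; the metacell trait value is the mean of its members'.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .stemness import log_normalize

__all__ = [
    "MetacellParams",
    "MetacellPartition",
    "select_feature_genes",
    "partition_metacells",
    "pseudobulk_by_rank",
]


@dataclass
class MetacellParams:
    var_threshold: float = 0.08   # scaled variance (var/mean) cutoff on down-sampled counts
    knn_k: int = 100
    balance_factor: int = 3       # in-degree cap = balance_factor * knn_k
    resample_fraction: float = 0.75
    n_iterations: int = 500
    min_size: int = 50
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.resample_fraction <= 1.0:
            raise ValueError("resample_fraction must lie in (0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.knn_k < 1 or self.n_iterations < 1:
            raise ValueError("knn_k and n_iterations must be positive")


@dataclass
class MetacellPartition:
    assignment: np.ndarray            # cell -> metacell id (0..M-1)
    metacell_expression: pd.DataFrame  # metacell x gene, mean member expression
    metacell_trait: np.ndarray | None  # per-metacell mean trait (e.g. stemness)


def select_feature_genes(
    adata: ad.AnnData, var_threshold: float = 0.08, seed: int = 0
) -> list[str]:
    """Over-dispersed genes: variance/mean on down-sampled counts above threshold.

    Mitochondrial genes ("MT-" prefix) are removed first.  Each cell is
    down-sampled by binomial thinning to the 5th-percentile library size so
    the variance/mean ratio is comparable across cells of different depth;
    a Poisson gene then sits near ratio 1.
    """
    rng = np.random.default_rng(seed)
    keep = ~adata.var_names.str.upper().str.startswith("MT-")
    X = np.asarray(adata.X.toarray() if hasattr(adata.X, "toarray") else adata.X, dtype=float)
    X = X[:, np.asarray(keep)]
    names = adata.var_names[keep]

    lib = X.sum(axis=1)
    target = np.quantile(lib, 0.05)
    p = np.minimum(target / np.maximum(lib, 1.0), 1.0)
    down = rng.binomial(X.astype(np.int64), p[:, None])

    mean = down.mean(axis=0)
    var = down.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(mean > 0, var / mean, 0.0)
    selected = [names[i] for i in np.nonzero(ratio > var_threshold)[0]]
    if not selected:
        raise ValueError("no gene passes the scaled-variance threshold")
    return selected


def _mutual_topk_components(sim: np.ndarray, k: int) -> np.ndarray:
    """Connected components of the mutual-top-K graph of a similarity matrix."""
    n = sim.shape[0]
    k = min(k, n - 1)
    s = sim.copy()
    np.fill_diagonal(s, -np.inf)
    top = np.argpartition(-s, kth=k - 1, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    mask = np.zeros((n, n), dtype=bool)
    mask[rows, top.ravel()] = True
    mask &= np.isfinite(s)  # padding slots (-inf) are not edges
    mutual = mask & mask.T
    graph = coo_matrix(mutual)
    _, labels = connected_components(graph, directed=False)
    return labels


def partition_metacells(
    adata: ad.AnnData,
    params: MetacellParams | None = None,
    feature_genes: list[str] | None = None,
    trait: np.ndarray | None = None,
    layer: str = "lognorm",
) -> MetacellPartition:
    """Partition cells into metacells of at least ``min_size`` members.

    Pearson similarity is computed on feature genes of the log-normalized
    layer; a balanced kNN graph keeps edge (i, j) only if j is among i's
    top K and i among j's top ``balance_factor * K``; each resampling
    iteration clusters the sampled cells by connected components of the
    mutual-top-K subgraph and accumulates co-membership; the co-clustering
    frequency matrix is cut by average linkage at frequency 0.5 and
    undersized clusters are merged into their most co-clustered neighbour.
    """
    params = params or MetacellParams()
    params.validate()
    n = adata.n_obs
    if n < 2 * params.min_size:
        raise ValueError(f"need at least {2 * params.min_size} cells")
    rng = np.random.default_rng(params.seed)

    if layer not in adata.layers:
        log_normalize(adata, layer=layer)
    if feature_genes is None:
        feature_genes = select_feature_genes(adata, params.var_threshold, seed=params.seed)
    cols = adata.var_names.get_indexer(feature_genes)
    expr = np.asarray(adata.layers[layer])[:, cols]

    # Pearson cell-cell similarity on feature genes
    z = expr - expr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    norms[norms == 0] = 1.0
    z /= norms[:, None]
    sim = z @ z.T

    # balanced kNN restriction: out-edges limited to top K, in-degree to 3K
    k = min(params.knn_k, n - 1)
    s = sim.copy()
    np.fill_diagonal(s, -np.inf)
    out_top = np.argpartition(-s, kth=k - 1, axis=1)[:, :k]
    out_mask = np.zeros((n, n), dtype=bool)
    out_mask[np.repeat(np.arange(n), k), out_top.ravel()] = True
    k_in = min(params.balance_factor * k, n - 1)
    in_top = np.argpartition(-s.T, kth=k_in - 1, axis=1)[:, :k_in]
    in_mask = np.zeros((n, n), dtype=bool)
    in_mask[np.repeat(np.arange(n), k_in), in_top.ravel()] = True
    balanced = out_mask & in_mask.T
    sim_b = np.where(balanced | balanced.T, sim, -np.inf)

    co_same = np.zeros((n, n), dtype=np.int32)
    co_seen = np.zeros((n, n), dtype=np.int32)
    m = max(2, int(round(params.resample_fraction * n)))
    for _ in range(params.n_iterations):
        idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        labels = _mutual_topk_components(sim_b[np.ix_(idx, idx)], k)
        co_seen[np.ix_(idx, idx)] += 1
        for lab in np.unique(labels):
            members = idx[labels == lab]
            co_same[np.ix_(members, members)] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(co_seen > 0, co_same / np.maximum(co_seen, 1), 0.0)
    np.fill_diagonal(freq, 1.0)
    dist = 1.0 - (freq + freq.T) / 2.0
    np.fill_diagonal(dist, 0.0)

    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    assignment = hierarchy.fcluster(link, t=0.5, criterion="distance") - 1

    assignment = _merge_undersized(assignment, freq, params.min_size)

    ids = np.unique(assignment)
    remap = {old: new for new, old in enumerate(ids)}
    assignment = np.array([remap[a] for a in assignment])

    full = np.asarray(adata.layers[layer])
    rows = []
    traits = [] if trait is not None else None
    for mc in range(len(ids)):
        members = assignment == mc
        rows.append(full[members].mean(axis=0))
        if traits is not None:
            traits.append(float(np.mean(np.asarray(trait)[members])))
    expr_df = pd.DataFrame(
        np.vstack(rows),
        index=[f"metacell_{i}" for i in range(len(ids))],
        columns=adata.var_names,
    )
    return MetacellPartition(
        assignment=assignment,
        metacell_expression=expr_df,
        metacell_trait=np.array(traits) if traits is not None else None,
    )


def pseudobulk_by_rank(
    adata: ad.AnnData,
    values: np.ndarray,
    group_size: int = 25,
    trait: np.ndarray | None = None,
    layer: str = "lognorm",
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Equal-size pseudo-metacells along a 1-D ordering of the cells.

    On continuum data (a single differentiation gradient with no discrete
    subpopulations) consensus co-clustering can collapse to very few
    groups; ordering cells by an observable score (e.g. the smoothed
    stemness score) and averaging consecutive chunks still yields
    homogeneous pseudo-observations for co-expression analysis.
    """
    if layer not in adata.layers:
        log_normalize(adata, layer=layer)
    order = np.argsort(np.asarray(values), kind="stable")
    n = len(order)
    n_groups = max(1, n // group_size)
    bounds = np.array_split(order, n_groups)
    full = np.asarray(adata.layers[layer])
    expr = pd.DataFrame(
        np.vstack([full[idx].mean(axis=0) for idx in bounds]),
        index=[f"pseudobulk_{i}" for i in range(n_groups)],
        columns=adata.var_names,
    )
    agg_trait = None
    if trait is not None:
        t = np.asarray(trait, dtype=float)
        agg_trait = np.array([t[idx].mean() for idx in bounds])
    return expr, agg_trait


def _merge_undersized(assignment: np.ndarray, freq: np.ndarray, min_size: int) -> np.ndarray:
    """Merge clusters below min_size into their most co-clustered neighbour."""
    assignment = assignment.copy()
    while True:
        ids, sizes = np.unique(assignment, return_counts=True)
        if len(ids) <= 1:
            break
        small = ids[sizes < min_size]
        if len(small) == 0:
            break
        # merge the smallest offender first
        victim = small[np.argmin(sizes[np.isin(ids, small)])]
        vm = assignment == victim
        best, best_f = None, -1.0
        for other in ids:
            if other == victim:
                continue
            f = freq[np.ix_(vm, assignment == other)].mean()
            if f > best_f:
                best, best_f = other, f
        assignment[vm] = best
    return assignment
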