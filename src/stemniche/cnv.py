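"""Reference-relative copy-number inference for spots or cells.

Residual log-expression relative to a reference population is smoothed
along each chromosome, discretized into six copy-number states (state 3 =
neutral), and scored as |state - 3| per gene.  A reference cluster is
chosen by the highest median immune marker score (NormalScore); malignant
clusters are the high group of a 2-means split of the per-cluster CNV
scores, replacing fixed absolute score thresholds that depend on the data
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .simulate import IMMUNE_MARKERS
from .stemness import log_normalize

__all__ = [
    "CNVParams",
    "CNVResult",
    "normal_score",
    "select_reference",
    "initial_clusters",
    "smoothed_cnv_profiles",
    "discretize_states",
    "cnv_scores",
    "cluster_and_call",
    "call_malignant_spots",
]


@dataclass
class CNVParams:
    mean_expr_cutoff: float = 0.1
    window: int = 51
    clip: float = 3.0
    denoise_sd: float = 1.5
    state_thresholds: tuple[float, float, float] = (0.1, 0.2, 0.3)
    n_clusters: int = 8
    resolution: float = 0.8

    def validate(self) -> None:
        t1, t2, t3 = self.state_thresholds
        if not (0 < t1 < t2 < t3):
            raise ValueError("state thresholds must satisfy 0 < t1 < t2 < t3")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")


@dataclass
class CNVResult:
    smoothed: pd.DataFrame          # obs x gene residual profile
    states: pd.DataFrame            # obs x gene in {1..6}
    cluster_labels: np.ndarray      # per non-reference obs
    cluster_scores: pd.Series       # per cluster sum of gene |state-3|
    malignant_clusters: set[int]
    reference_cluster: int | None = None


def normal_score(adata: ad.AnnData, markers: tuple[str, ...] = IMMUNE_MARKERS,
                 layer: str = "lognorm") -> np.ndarray:
    """Mean log-normalized expression of the immune marker panel per spot."""
    if layer not in adata.layers:
        log_normalize(adata, layer=layer)
    present = [m for m in markers if m in adata.var_names]
    if not present:
        raise ValueError("none of the immune markers are measured")
    if len(present) < len(markers):
        import warnings

        warnings.warn(f"missing markers skipped: {sorted(set(markers) - set(present))}")
    cols = adata.var_names.get_indexer(present)
    return np.asarray(adata.layers[layer])[:, cols].mean(axis=1)


def select_reference(cluster_labels: np.ndarray, normal_scores: np.ndarray) -> int:
    """Cluster with the highest median NormalScore; ties to the lowest id."""
    cluster_labels = np.asarray(cluster_labels)
    ids = np.unique(cluster_labels)
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    medians = np.array([np.median(normal_scores[cluster_labels == c]) for c in ids])
    best = medians.max()
    return int(min(ids[medians == best]))


def initial_clusters(adata: ad.AnnData, resolution: float = 0.8, seed: int = 0,
                     layer: str = "lognorm") -> np.ndarray:
    """First-phase graph clustering (Leiden on a PCA kNN graph) of spots."""
    import scanpy as sc

    if layer not in adata.layers:
        log_normalize(adata, layer=layer)
    tmp = ad.AnnData(X=np.asarray(adata.layers[layer]), obs=adata.obs[[]].copy())
    sc.pp.pca(tmp, n_comps=min(30, tmp.n_obs - 1, tmp.n_vars - 1), random_state=seed)
    sc.pp.neighbors(tmp, n_neighbors=15, random_state=seed)
    sc.tl.leiden(tmp, resolution=resolution, random_state=seed, flavor="igraph",
                 n_iterations=2, directed=False)
    return tmp.obs["leiden"].astype(int).to_numpy()


def smoothed_cnv_profiles(
    adata: ad.AnnData,
    reference_mask: np.ndarray,
    params: CNVParams | None = None,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Chromosome-smoothed residual CNV profile per observation.

    Steps: drop genes with mean normalized expression below the cutoff;
    subtract the reference per-gene mean from log2(norm + 1); clip; apply a
    centred moving average of the configured window per chromosome
    (truncated at chromosome ends); subtract each observation's median;
    zero residuals within ``denoise_sd`` reference standard deviations of
    zero.
    """
    params = params or CNVParams()
    params.validate()
    if not {"chromosome", "start"} <= set(adata.var.columns):
        raise ValueError("gene annotation (chromosome, start) required")
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference is empty")
    if layer not in adata.layers:
        log_normalize(adata, layer=layer)
    norm = np.asarray(adata.layers[layer])

    keep = norm.mean(axis=0) >= params.mean_expr_cutoff
    var = adata.var.loc[np.asarray(keep)]
    expr = np.log2(np.expm1(norm[:, keep]) + 1.0)

    order = np.lexsort((var["start"].to_numpy(), var["chromosome"].to_numpy()))
    var = var.iloc[order]
    expr = expr[:, order]

    resid = expr - expr[reference_mask].mean(axis=0)
    resid = np.clip(resid, -params.clip, params.clip)

    smoothed = np.empty_like(resid)
    half = params.window // 2
    chroms = var["chromosome"].to_numpy()
    col = 0
    for chrom in pd.unique(chroms):
        span = np.sum(chroms == chrom)
        block = resid[:, col : col + span]
        csum = np.cumsum(np.pad(block, ((0, 0), (1, 0))), axis=1)
        for j in range(span):
            lo, hi = max(0, j - half), min(span, j + half + 1)
            smoothed[:, col + j] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
        col += span

    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    sd_ref = smoothed[reference_mask].std()
    smoothed[np.abs(smoothed) < params.denoise_sd * sd_ref] = 0.0
    return pd.DataFrame(smoothed, index=adata.obs_names, columns=var.index)


def discretize_states(smoothed: pd.DataFrame, params: CNVParams | None = None) -> pd.DataFrame:
    """Six-state discretization of smoothed residuals.

    Cuts at (-t3, -t1, t1, t2, t3) give states 1..6: two deletion grades,
    the neutral state 3 at zero, and three amplification grades, mirroring
    the semantics of a six-state copy-number model.
    """
    params = params or CNVParams()
    params.validate()
    v = smoothed.to_numpy()
    if not np.isfinite(v).all():
        raise ValueError("non-finite smoothed values")
    t1, t2, t3 = params.state_thresholds
    cuts = np.array([-t3, -t1, t1, t2, t3])
    states = np.digitize(v, cuts, right=False) + 1
    return pd.DataFrame(states, index=smoothed.index, columns=smoothed.columns)


def cnv_scores(states: pd.DataFrame, cluster_labels: np.ndarray) -> pd.Series:
    """Per-cluster CNV score: sum over genes of |modal state - 3|.

    The cluster profile is the per-gene modal state over member
    observations; its score is the sum of the gene scores.
    """
    cluster_labels = np.asarray(cluster_labels)
    s = states.to_numpy()
    out = {}
    for c in np.unique(cluster_labels):
        members = s[cluster_labels == c]
        if members.shape[0] == 0:
            import warnings

            warnings.warn(f"cluster {c} is empty; skipped")
            continue
        profile = np.apply_along_axis(
            lambda col: np.bincount(col, minlength=7).argmax(), 0, members
        )
        out[c] = int(np.abs(profile - 3).sum())
    return pd.Series(out, name="cnv_score")


def cluster_and_call(
    smoothed: pd.DataFrame,
    params: CNVParams | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, set[int], pd.Series]:
    """Ward clustering of smoothed profiles and malignant-cluster calling.

    Profiles are cut into ``n_clusters`` clusters; cluster CNV scores are
    computed from the discretized states and split by 1-D 2-means, the high
    group being called malignant.  If the split is degenerate (all scores
    equal) no cluster is called malignant.
    """
    params = params or CNVParams()
    params.validate()
    X = smoothed.to_numpy()
    if X.shape[0] < params.n_clusters:
        raise ValueError("fewer observations than clusters")
    link = hierarchy.linkage(X, method="ward")
    labels = hierarchy.fcluster(link, t=params.n_clusters, criterion="maxclust") - 1

    states = discretize_states(smoothed, params)
    scores = cnv_scores(states, labels)

    vals = scores.to_numpy(dtype=float).reshape(-1, 1)
    if np.allclose(vals, vals[0]):
        return labels, set(), scores
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(vals)
    high = int(np.argmax(km.cluster_centers_.ravel()))
    malignant = {int(c) for c, lab in zip(scores.index, km.labels_) if lab == high}
    return labels, malignant, scores


def call_malignant_spots(
    adata: ad.AnnData,
    params: CNVParams | None = None,
    seed: int = 0,
) -> CNVResult:
    """End-to-end malignant-spot calling for one spatial sample.

    First-phase graph clustering selects the reference cluster by
    NormalScore; smoothed CNV profiles relative to that reference are
    clustered (Ward, ``n_clusters``) over the non-reference spots and the
    high-CNV-score clusters are called malignant.  ``obs`` gains
    ``cnv_cluster`` (-1 for reference spots) and ``malignant_call``.
    """
    params = params or CNVParams()
    ns = normal_score(adata)
    first = initial_clusters(adata, resolution=params.resolution, seed=seed)
    ref_cluster = select_reference(first, ns)
    ref_mask = first == ref_cluster

    smoothed = smoothed_cnv_profiles(adata, ref_mask, params)
    non_ref = ~ref_mask
    labels, malignant, scores = cluster_and_call(smoothed.loc[non_ref], params, seed=seed)

    states = discretize_states(smoothed, params)
    full_labels = np.full(adata.n_obs, -1)
    full_labels[non_ref] = labels
    adata.obs["cnv_cluster"] = full_labels
    adata.obs["malignant_call"] = np.isin(full_labels, list(malignant))
    return CNVResult(
        smoothed=smoothed,
        states=states,
        cluster_labels=full_labels,
        cluster_scores=scores,
        malignant_clusters=malignant,
        reference_cluster=ref_cluster,
    )
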