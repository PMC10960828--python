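"""Weighted co-expression module detection over metacells.

Implements the classical weighted-network workflow: soft-threshold power
selection by scale-free topology fit, unsigned adjacency |cor|^beta,
topological overlap, average-linkage module detection with a static tree
cut, module eigengenes (first principal component across metacells), and
module-trait correlation.  The stemness signature is the intersection of
the best-correlated module with malignant-cell marker genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "WGCNAParams",
    "ModuleSet",
    "MarkerResult",
    "pick_soft_threshold",
    "tom_matrix",
    "detect_modules",
    "module_eigengenes",
    "module_trait_correlation",
    "malignant_markers",
    "derive_signature",
]


@dataclass
class WGCNAParams:
    n_top_genes: int = 5000
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2: float = 0.8
    soft_power_fallback: int = 9
    soft_power: int | None = None  # fixed adjacency exponent; None = pick by scale-free fit
    min_module_size: int = 30
    # static average-linkage cut on 1-TOM.  On small (few-hundred-gene)
    # networks TOM values compress toward 1, so the cut sits slightly below
    # the noise plateau rather than at the 0.99 used for genome-scale runs.
    cut_height: float = 0.97
    merge_modules: bool = False  # no eigengene-similarity merging by default


@dataclass
class ModuleSet:
    module_of: pd.Series                 # gene -> module id (0 = unassigned)
    eigengene: pd.DataFrame              # module x metacell, unit-norm rows
    trait_correlation: pd.DataFrame      # per module: r, p
    selected_module: int | None = None
    signature: list[str] = field(default_factory=list)


@dataclass
class MarkerResult:
    table: pd.DataFrame  # per gene: avg_logFC, p_value, is_marker

    @property
    def markers(self) -> list[str]:
        return list(self.table.index[self.table["is_marker"]])


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression."""
    k = connectivity[connectivity > 0]
    if len(k) < n_bins:
        return -1.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    centers, probs = [], []
    for b in range(n_bins):
        kb = k[which == b]
        if len(kb):
            centers.append(kb.mean())
            probs.append(len(kb) / len(k))
    if len(centers) < 3:
        return -1.0
    x = np.log10(np.asarray(centers))
    y = np.log10(np.asarray(probs))
    slope, _, r, _, _ = stats.linregress(x, y)
    return r**2 * np.sign(-slope)


def pick_soft_threshold(expr: pd.DataFrame, params: WGCNAParams | None = None) -> int:
    """Smallest candidate power whose network is approximately scale-free.

    ``expr`` is metacell x gene.  For each power beta the unsigned
    adjacency is |cor|^beta; the signed R^2 of a log10 p(k) on log10 k
    regression (10 connectivity bins) is compared against the target; the
    configured fallback power is returned when no candidate reaches it.
    """
    params = params or WGCNAParams()
    if expr.shape[0] < 20:
        raise ValueError("need at least 20 metacells")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 genes")
    cor = np.abs(np.corrcoef(expr.to_numpy(), rowvar=False))
    np.fill_diagonal(cor, 0.0)
    for beta in params.candidate_powers:
        adj = cor**beta
        k = adj.sum(axis=0)
        if _scale_free_fit(k) >= params.scale_free_r2:
            return int(beta)
    return params.soft_power_fallback


def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    TOM_jk = (sum_u a_ju a_uk + a_jk) / (min(k_j, k_k) + 1 - a_jk) with a
    unit diagonal; 1 - TOM is the module-detection dissimilarity.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        a = a.copy()
        np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(dissimilarity: np.ndarray, params: WGCNAParams | None = None) -> np.ndarray:
    """Average-linkage modules from a 1-TOM dissimilarity; static tree cut.

    Clusters smaller than ``min_module_size`` go to module 0 (unassigned);
    surviving modules are labelled 1..M in decreasing size.
    """
    params = params or WGCNAParams()
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=params.cut_height, criterion="distance")
    ids, sizes = np.unique(raw, return_counts=True)
    keep = ids[sizes >= params.min_module_size]
    order = keep[np.argsort(-sizes[np.isin(ids, keep)])]
    out = np.zeros(len(raw), dtype=int)
    for new, old in enumerate(order, start=1):
        out[raw == old] = new
    return out


def module_eigengenes(expr: pd.DataFrame, module_of: np.ndarray) -> pd.DataFrame:
    """First principal component of each module across metacells.

    Genes are standardized across metacells before the SVD.  Each
    eigengene (a unit-norm vector over metacells) is sign-fixed so that
    its correlation with the module's mean expression profile is
    non-negative.
    """
    X = expr.to_numpy()
    rows = {}
    for mod in sorted(set(module_of) - {0}):
        sub = X[:, module_of == mod]
        z = sub - sub.mean(axis=0)
        sd = z.std(axis=0)
        sd[sd == 0] = 1.0
        z = z / sd
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        eg = u[:, 0]
        mean_profile = sub.mean(axis=1)
        if np.corrcoef(eg, mean_profile)[0, 1] < 0:
            eg = -eg
        rows[mod] = eg
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.index)


def module_trait_correlation(eigengenes: pd.DataFrame, trait: np.ndarray) -> pd.DataFrame:
    """Pearson r of each eigengene with the trait; p from the t distribution."""
    trait = np.asarray(trait, dtype=float)
    n = len(trait)
    if n < 3:
        raise ValueError("need at least 3 metacells for a correlation p-value")
    if eigengenes.shape[1] != n:
        raise ValueError("trait length must match the number of metacells")
    out = {}
    for mod, eg in eigengenes.iterrows():
        r = float(np.corrcoef(eg.to_numpy(), trait)[0, 1])
        r_c = np.clip(r, -0.9999999999, 0.9999999999)
        t = r_c * np.sqrt((n - 2) / (1.0 - r_c**2))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        out[mod] = {"r": r, "p": p}
    return pd.DataFrame.from_dict(out, orient="index")


def malignant_markers(
    adata,
    malignant: np.ndarray,
    logfc_screen: float = 0.25,
    logfc_cut: float = 0.5,
    p_cut: float = 0.05,
    layer: str = "lognorm",
) -> MarkerResult:
    """Marker genes of malignant vs all other cells.

    avg_logFC is the natural-log fold change of mean de-logged normalized
    expression (pseudocount 1) between the groups.  Genes passing the
    |logFC| > ``logfc_screen`` candidate screen are tested by a two-sided
    Wilcoxon rank-sum; the final marker rule is avg_logFC > ``logfc_cut``
    and p < ``p_cut``.
    """
    from .stemness import log_normalize

    malignant = np.asarray(malignant, dtype=bool)
    if malignant.all() or not malignant.any():
        raise ValueError("both groups must be non-empty")
    if layer not in adata.layers:
        log_normalize(adata, layer=layer)
    norm = np.asarray(adata.layers[layer])

    in_g = norm[malignant]
    out_g = norm[~malignant]
    lfc = np.log(np.expm1(in_g).mean(axis=0) + 1.0) - np.log(np.expm1(out_g).mean(axis=0) + 1.0)

    pvals = np.ones(adata.n_vars)
    screened = np.abs(lfc) > logfc_screen
    for j in np.nonzero(screened)[0]:
        # exact for small tie-free groups, normal approximation otherwise
        pvals[j] = stats.mannwhitneyu(
            in_g[:, j], out_g[:, j], alternative="two-sided", method="auto"
        ).pvalue
    table = pd.DataFrame(
        {
            "avg_logFC": lfc,
            "p_value": pvals,
            "is_marker": (lfc > logfc_cut) & (pvals < p_cut),
        },
        index=adata.var_names,
    )
    return MarkerResult(table=table)


def derive_signature(
    expr: pd.DataFrame,
    module_of: np.ndarray,
    trait: np.ndarray,
    markers: MarkerResult,
) -> ModuleSet:
    """Select the module most correlated with the trait and intersect with markers.

    The module with the largest |trait correlation| is the stemness
    module; the signature is its genes intersected with the malignant
    marker list, in alphabetical order.
    """
    eg = module_eigengenes(expr, module_of)
    if eg.empty:
        raise ValueError("no modules to correlate")
    tc = module_trait_correlation(eg, trait)
    selected = int(tc["r"].abs().idxmax())
    module_genes = set(expr.columns[np.asarray(module_of) == selected])
    signature = sorted(module_genes & set(markers.markers))
    if not signature:
        import warnings

        warnings.warn("empty signature: selected module and markers do not intersect")
    return ModuleSet(
        module_of=pd.Series(module_of, index=expr.columns),
        eigengene=eg,
        trait_correlation=tc,
        selected_module=selected,
        signature=signature,
    )
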