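"""Synthetic single-cell and Visium-style data with planted ground truth.

Every generator emits its ground truth (differentiation depth, malignant
labels, CNV segments, spatial region, signature loadings) alongside the
counts so that downstream recovery tests never have to re-derive the truth
from the data they are checking.

Counts follow a negative-binomial (gamma-Poisson) model with per-gene mean
and a shared dispersion, the standard over-dispersed noise model for
droplet scRNA-seq.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "LineageConfig",
    "CNVGroundTruth",
    "SpatialConfig",
    "SpotProfiles",
    "simulate_lineage_cells",
    "simulate_stroma_cells",
    "simulate_cnv_profiles",
    "simulate_visium_sample",
    "IMMUNE_MARKERS",
]

#: The ten immune marker genes used for reference ("normal") scoring of spots:
#: pan-immune, pan-T, B-cell and myeloid markers.
IMMUNE_MARKERS = (
    "PTPRC", "CD2", "CD3D", "CD3E", "CD3G",
    "CD79A", "MS4A1", "CD79B", "CD68", "CD14",
)


@dataclass
class LineageConfig:
    """Parameters of the differentiation-hierarchy count simulator.

    Cells sit at integer depths ``0..tree_depth`` of a differentiation
    hierarchy; the number of active (expressed) genes decays geometrically
    with depth, so less differentiated cells express more genes.  A planted
    co-expression module of ``module_size`` genes has mean expression that
    increases toward the root, mimicking a stemness program.
    """

    n_cells: int = 500
    n_genes: int = 1000
    tree_depth: int = 4
    genes_active_root: int = 600
    activity_decay: float = 0.2
    module_size: int = 50
    module_effect: float = 2.0
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cells, self.n_genes, self.genes_active_root, self.module_size) <= 0:
            raise ValueError("all counts must be positive")
        if self.tree_depth < 1:
            raise ValueError("tree_depth must be >= 1")
        if not 0.0 <= self.activity_decay < 1.0:
            raise ValueError("activity_decay must lie in [0, 1)")
        if self.genes_active_root > self.n_genes:
            raise ValueError("genes_active_root cannot exceed n_genes")
        if self.module_size >= self.n_genes:
            raise ValueError("module_size must be smaller than n_genes")
        deepest = round(self.genes_active_root * (1.0 - self.activity_decay) ** self.tree_depth)
        if deepest < 1:
            raise ValueError(
                "degenerate config: no active genes at maximum depth "
                f"(root={self.genes_active_root}, decay={self.activity_decay}, "
                f"depth={self.tree_depth})"
            )


@dataclass
class CNVGroundTruth:
    """Planted copy-number segments.

    Each segment is ``(chromosome, start_gene_index, end_gene_index,
    multiplier)`` with the index range half-open over the gene order of the
    annotation and multiplier in {0.5, 1.5, 2.0} (loss, gain, amplification).
    """

    segments: list[tuple[str, int, int, float]] = field(default_factory=list)
    malignant_fraction: float = 0.5

    def validate(self, var: pd.DataFrame) -> None:
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise ValueError("malignant_fraction must lie in [0, 1]")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, mult in self.segments:
            if mult not in (0.5, 1.5, 2.0):
                raise ValueError(f"unsupported multiplier {mult}")
            if not (0 <= start < end <= var.shape[0]):
                raise ValueError(f"segment [{start}, {end}) outside gene annotation")
            if not (var["chromosome"].iloc[start:end] == chrom).all():
                raise ValueError(f"segment [{start}, {end}) crosses out of {chrom}")
            for s0, e0 in by_chrom.get(chrom, []):
                if start < e0 and s0 < end:
                    raise ValueError("segments overlap within a chromosome")
            by_chrom.setdefault(chrom, []).append((start, end))


@dataclass
class SpatialConfig:
    """Layout of a synthetic Visium-style sample.

    The lattice uses 10x offset coordinates: spot (row, col) exists when
    row and col have equal parity, so each interior spot has six
    neighbours.  A tumor disc of ``tumor_radius`` (in spot-pitch units) is
    centred at ``tumor_center``; the stemness signature loading rises
    toward the disc centre and the macrophage signature follows it with
    strength ``colocation_strength``.  Immune marker genes dominate a
    distal corner region that serves as the normal reference.
    """

    n_rows: int = 30
    n_cols: int = 30
    tumor_center: tuple[float, float] = (15.0, 15.0)
    tumor_radius: float = 6.0
    colocation_strength: float = 2.0
    cell_type_profiles: dict[str, list[int]] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_rows < 4 or self.n_cols < 4:
            raise ValueError("lattice too small")
        r, c = self.tumor_center
        xc, yc = float(c), r * np.sqrt(3.0) / 2.0
        xmax = self.n_cols - 0.5
        ymax = (self.n_rows - 1) * np.sqrt(3.0) / 2.0
        if (
            xc - self.tumor_radius < -0.5
            or xc + self.tumor_radius > xmax + 0.5
            or yc - self.tumor_radius < -0.5
            or yc + self.tumor_radius > ymax + 0.5
        ):
            raise ValueError("tumor disc does not fit inside the lattice")
        if self.colocation_strength < 0:
            raise ValueError("colocation_strength must be >= 0")
        if self.cell_type_profiles:
            seen: set[int] = set()
            for genes in self.cell_type_profiles.values():
                if seen & set(genes):
                    raise ValueError("marker sets must be disjoint per type")
                seen |= set(genes)


@dataclass
class SpotProfiles:
    """Gene-level expression programme for the spatial simulator."""

    n_genes: int = 500
    n_chromosomes: int = 5
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0
    cnv: CNVGroundTruth | None = None
    csc_genes: tuple[int, ...] = tuple(range(400, 430))
    macro_genes: tuple[int, ...] = tuple(range(430, 460))
    signature_effect: float = 3.0
    immune_boost: float = 10.0


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with mean `mean` and NB size parameter `dispersion`."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-12) / dispersion)
    return rng.poisson(lam).astype(np.int64)


def _gene_annotation(n_genes: int, n_chromosomes: int, names: list[str] | None = None) -> pd.DataFrame:
    per = int(np.ceil(n_genes / n_chromosomes))
    chroms = [f"chr{1 + i // per}" for i in range(n_genes)]
    starts = [1000 * (1 + i % per) for i in range(n_genes)]
    idx = names if names is not None else [f"gene_{i:04d}" for i in range(n_genes)]
    return pd.DataFrame({"chromosome": chroms, "start": starts}, index=idx)


def simulate_lineage_cells(cfg: LineageConfig) -> ad.AnnData:
    """Simulate a differentiation hierarchy of cells.

    Returns an :class:`anndata.AnnData` with raw counts in ``X``,
    ``obs['true_depth']`` (0 = root / most stem-like), and
    ``uns['module_genes']`` holding the planted module's gene names.
    The number of active genes per cell is
    ``round(genes_active_root * (1 - activity_decay)**depth)`` jittered by
    binomial thinning (roughly +/-5%), and the planted module's NB mean is
    scaled by ``1 + (1 - depth/tree_depth) * module_effect``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    depths = rng.integers(0, cfg.tree_depth + 1, size=cfg.n_cells)

    module_idx = np.arange(cfg.module_size)  # first genes form the planted module
    counts = np.zeros((cfg.n_cells, cfg.n_genes), dtype=np.int64)
    for i, d in enumerate(depths):
        target = round(cfg.genes_active_root * (1.0 - cfg.activity_decay) ** d)
        # jitter by thinning a slightly inflated pool: mean == target, sd ~ 5%
        n_active = int(rng.binomial(round(target / 0.95), 0.95))
        n_active = int(np.clip(n_active, 1, cfg.n_genes))
        active = rng.choice(cfg.n_genes, size=n_active, replace=False)
        means = np.full(n_active, cfg.nb_mean)
        boost = 1.0 + (1.0 - d / cfg.tree_depth) * cfg.module_effect
        means[np.isin(active, module_idx)] *= boost
        counts[i, active] = _nb_draw(rng, means, cfg.nb_dispersion)

    var = _gene_annotation(cfg.n_genes, n_chromosomes=5)
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {"true_depth": depths},
            index=[f"cell_{i:05d}" for i in range(cfg.n_cells)],
        ),
        var=var,
    )
    adata.uns["module_genes"] = list(var.index[module_idx])
    adata.uns["lineage_config"] = {"tree_depth": cfg.tree_depth, "seed": cfg.seed}
    return adata


def simulate_stroma_cells(
    cfg: LineageConfig, n_cells: int | None = None, seed: int | None = None,
    module_silencing: float = 0.9,
) -> ad.AnnData:
    """Simulate a stromal population that lacks the malignant programme.

    Stromal cells share the baseline expression model of the lineage
    simulator but do not run the planted module: module genes are thinned
    to a ``1 - module_silencing`` fraction of baseline, emulating a
    tumor-specific programme absent from stroma and immune cells.  Depth
    structure is irrelevant for stroma, so cells sit at the deepest level.
    """
    from dataclasses import replace

    if not 0.0 <= module_silencing <= 1.0:
        raise ValueError("module_silencing must lie in [0, 1]")
    scfg = replace(
        cfg,
        n_cells=n_cells if n_cells is not None else cfg.n_cells,
        module_effect=0.0,
        tree_depth=1,
        activity_decay=0.0,
        seed=seed if seed is not None else cfg.seed + 7919,
    )
    out = simulate_lineage_cells(scfg)
    rng = np.random.default_rng(scfg.seed + 1)
    X = np.asarray(out.X)
    X[:, : cfg.module_size] = rng.binomial(X[:, : cfg.module_size], 1.0 - module_silencing)
    out.X = X
    out.obs["true_depth"] = -1  # not part of the hierarchy
    return out


def simulate_cnv_profiles(adata: ad.AnnData, truth: CNVGroundTruth, seed: int = 0) -> ad.AnnData:
    """Overlay planted copy-number segments on a malignant subset of cells.

    A random ``malignant_fraction`` of cells is labelled malignant; on each
    planted segment their counts are resampled so the conditional mean is
    multiplied by the segment multiplier (binomial thinning for losses,
    Poisson top-up for gains).  Returns a modified copy with
    ``obs['malignant']`` and ``uns['cnv_segments']``.
    """
    if not {"chromosome", "start"} <= set(adata.var.columns):
        raise ValueError("gene annotation (chromosome, start) required")
    truth.validate(adata.var)
    rng = np.random.default_rng(seed)
    out = adata.copy()
    n = out.n_obs
    n_mal = int(round(truth.malignant_fraction * n))
    mal_idx = rng.choice(n, size=n_mal, replace=False) if n_mal else np.array([], dtype=int)
    malignant = np.zeros(n, dtype=bool)
    malignant[mal_idx] = True

    X = np.asarray(out.X)
    for chrom, start, end, mult in truth.segments:
        block = X[np.ix_(mal_idx, np.arange(start, end))]
        if mult < 1.0:
            block = rng.binomial(block, mult)
        elif mult > 1.0:
            block = block + rng.poisson((mult - 1.0) * block)
        X[np.ix_(mal_idx, np.arange(start, end))] = block
    out.X = X
    out.obs["malignant"] = malignant
    out.uns["cnv_segments"] = [list(s) for s in truth.segments]
    return out


def _hex_xy(rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Planar coordinates of Visium offset (array_row, array_col) in pitch units."""
    return cols * 0.5, rows * (np.sqrt(3.0) / 2.0)


def simulate_visium_sample(
    cfg: SpatialConfig, profiles: SpotProfiles | None = None
) -> ad.AnnData:
    """Simulate one Visium-style sample on an offset hex lattice.

    Spots live at (array_row, array_col) with matching parity.  Ground
    truth in ``obs``: ``region`` (tumor / boundary / normal), ``immune_region``
    (distal reference area), ``csc_loading`` and ``macro_loading`` (planted
    signature intensities).  ``obsm['spatial']`` holds pixel-like planar
    coordinates; ``uns`` records signature gene lists and CNV segments.
    """
    cfg.validate()
    profiles = profiles if profiles is not None else SpotProfiles()
    rng = np.random.default_rng(cfg.seed)

    rows, cols = [], []
    for r in range(cfg.n_rows):
        for c in range(r % 2, 2 * cfg.n_cols, 2):
            rows.append(r)
            cols.append(c)
    rows = np.array(rows)
    cols = np.array(cols)
    x, y = _hex_xy(rows, cols)
    cx, cy = _hex_xy(np.array([cfg.tumor_center[0]]), np.array([cfg.tumor_center[1] * 2]))
    # tumor_center given as (row, col) in lattice units; col doubled to array scale
    dist = np.hypot(x - cx[0], y - cy[0])

    tumor = dist <= cfg.tumor_radius
    boundary = (~tumor) & (dist <= cfg.tumor_radius + 1.0)
    region = np.where(tumor, "tumor", np.where(boundary, "boundary", "normal"))

    # distal immune corner: around the lattice corner farthest from the tumor
    corners = np.array([[0, 0], [0, cfg.n_cols - 1], [cfg.n_rows - 1, 0],
                        [cfg.n_rows - 1, cfg.n_cols - 1]], dtype=float)
    cxs, cys = _hex_xy(corners[:, 0], corners[:, 1] * 2)
    far = np.argmax(np.hypot(cxs - cx[0], cys - cy[0]))
    immune_d = np.hypot(x - cxs[far], y - cys[far])
    immune = immune_d <= 0.25 * min(cfg.n_rows * np.sqrt(3) / 2, cfg.n_cols)
    immune &= ~tumor & ~boundary

    n_plain = profiles.n_genes
    names = [f"gene_{i:04d}" for i in range(n_plain)] + list(IMMUNE_MARKERS)
    var = _gene_annotation(n_plain + len(IMMUNE_MARKERS), profiles.n_chromosomes, names)

    n_spots = len(rows)
    n_genes = len(names)
    base = rng.lognormal(mean=0.0, sigma=0.3, size=n_genes) * profiles.nb_mean

    # planted signature loadings: the CSC programme peaks at the disc centre;
    # the macrophage programme tracks it into a one-spot fringe beyond the
    # rim (multiplicative noise keeps it zero far from the tumor), or is
    # spatially unstructured when colocation_strength is 0
    csc_loading = np.clip(1.0 - dist / cfg.tumor_radius, 0.0, None)
    near_loading = np.clip(1.0 - dist / (cfg.tumor_radius + 1.5), 0.0, None)
    noise = rng.normal(0.0, 0.15, size=n_spots)
    if cfg.colocation_strength > 0:
        macro_loading = np.clip(
            cfg.colocation_strength * 0.5 * near_loading * (1.0 + 2.0 * noise), 0.0, None
        )
    else:
        macro_loading = np.clip(0.3 + noise, 0.0, None)

    means = np.tile(base, (n_spots, 1))
    csc = np.array(profiles.csc_genes)
    mac = np.array(profiles.macro_genes)
    means[:, csc] *= 1.0 + profiles.signature_effect * csc_loading[:, None]
    means[:, mac] *= 1.0 + profiles.signature_effect * macro_loading[:, None]

    immune_cols = np.arange(n_plain, n_genes)
    means[:, immune_cols] *= 0.2
    means[np.ix_(immune, immune_cols)] *= profiles.immune_boost / 0.2

    segments = profiles.cnv.segments if profiles.cnv is not None else []
    for chrom, start, end, mult in segments:
        means[np.ix_(tumor, np.arange(start, end))] *= mult

    counts = _nb_draw(rng, means, profiles.nb_dispersion).reshape(n_spots, n_genes)

    obs = pd.DataFrame(
        {
            "array_row": rows,
            "array_col": cols,
            "region": region,
            "immune_region": immune,
            "csc_loading": csc_loading,
            "macro_loading": macro_loading,
            "malignant_truth": tumor,
        },
        index=[f"spot_{i:05d}" for i in range(n_spots)],
    )
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.obsm["spatial"] = np.column_stack([x, y])
    adata.uns["csc_genes"] = [names[i] for i in csc]
    adata.uns["macro_genes"] = [names[i] for i in mac]
    adata.uns["cnv_segments"] = [list(s) for s in segments]
    return adata
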