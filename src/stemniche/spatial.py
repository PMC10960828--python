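"""Hex-lattice geometry: adjacency, tumor rim, boundary band, co-location.

Visium spots sit on an offset hexagonal lattice; adjacency links spots
whose centre distance is at most 1.2x the minimum pairwise distance, so
interior spots have six neighbours.  The tumor outer rim is the set of
tumor-cluster spots with a neighbour outside the cluster; the boundary
band collects all spots within a fixed hex-graph (BFS) distance of the rim
on both sides, split into tumor and non-tumor sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "SpatialLattice",
    "BoundaryBand",
    "build_adjacency",
    "outer_rim",
    "boundary_band",
    "colocation_stats",
]


@dataclass
class SpatialLattice:
    spot_ids: pd.Index
    coords: np.ndarray          # planar spot centres
    adjacency: csr_matrix       # symmetric, irreflexive
    cluster: np.ndarray | None = None

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency.indices[self.adjacency.indptr[i]: self.adjacency.indptr[i + 1]]


@dataclass
class BoundaryBand:
    rim: np.ndarray       # spot indices on the tumor outer rim
    band: np.ndarray      # spot indices within `width` of the rim
    side: pd.Series       # band spot index -> "tumor" / "non_tumor"
    width: int = 3


def build_adjacency(positions: pd.DataFrame, cluster: np.ndarray | None = None) -> SpatialLattice:
    """Neighbour graph from a tissue-positions table.

    Uses pixel coordinates (``pxl_col``/``pxl_row`` columns, any name
    containing "pxl") when present, otherwise plane coordinates derived
    from the Visium offset array coordinates (col * 1/2, row * sqrt(3)/2).
    Spots are adjacent iff their distance is <= 1.2x the minimum pairwise
    distance.
    """
    pxl = [c for c in positions.columns if "pxl" in c.lower()]
    if len(pxl) >= 2:
        coords = positions[pxl[:2]].to_numpy(dtype=float)
    else:
        coords = np.column_stack(
            [
                positions["array_col"].to_numpy(dtype=float) * 0.5,
                positions["array_row"].to_numpy(dtype=float) * np.sqrt(3.0) / 2.0,
            ]
        )
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    min_d = d[:, 1].min()
    if min_d == 0:
        raise ValueError("duplicate spot coordinates")
    pairs = tree.query_pairs(r=1.2 * min_d, output_type="ndarray")
    n = len(coords)
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    adj = csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n))
    return SpatialLattice(
        spot_ids=positions.index,
        coords=coords,
        adjacency=adj,
        cluster=None if cluster is None else np.asarray(cluster),
    )


def outer_rim(lattice: SpatialLattice, tumor_cluster) -> np.ndarray:
    """Tumor-cluster spots with at least one neighbour outside the cluster."""
    if lattice.cluster is None:
        raise ValueError("lattice has no cluster labels")
    in_tumor = np.asarray(lattice.cluster) == tumor_cluster
    if not in_tumor.any():
        raise ValueError("tumor cluster is empty")
    adj = lattice.adjacency
    # a spot is on the rim if its neighbour count outside the cluster is > 0,
    # or if it sits on the lattice border (fewer than 6 neighbours, all inside)
    outside_neigh = adj @ (~in_tumor).astype(np.int64)
    degree = np.asarray(adj.sum(axis=1)).ravel()
    rim = in_tumor & ((outside_neigh > 0) | (degree < 6))
    return np.nonzero(rim)[0]


def boundary_band(lattice: SpatialLattice, rim: np.ndarray, width: int = 3) -> BoundaryBand:
    """All spots within BFS distance ``width`` of any rim spot, with sides.

    The band extends on both sides of the rim ("tumor" side = member of the
    tumor cluster), matching a boundary area that includes tumor and
    non-tumor spots.  width=0 returns the rim itself.
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    dist = hex_distance_from(lattice, rim)
    band = np.nonzero(dist <= width)[0]
    side = None
    if lattice.cluster is not None:
        tumor_cluster_of_rim = lattice.cluster[rim[0]] if len(rim) else None
        side = pd.Series(
            np.where(lattice.cluster[band] == tumor_cluster_of_rim, "tumor", "non_tumor"),
            index=band,
        )
    return BoundaryBand(rim=np.asarray(rim), band=band, side=side, width=width)


def hex_distance_from(lattice: SpatialLattice, sources: np.ndarray) -> np.ndarray:
    """Hex-graph BFS distance of every spot from the nearest source spot."""
    if len(sources) == 0:
        return np.full(lattice.n_spots, np.inf)
    d = dijkstra(lattice.adjacency, directed=False, unweighted=True, indices=sources)
    return d.min(axis=0)


def colocation_stats(
    score_a: np.ndarray,
    score_b: np.ndarray,
    subset: np.ndarray | None = None,
) -> dict:
    """Spearman correlation plus a median-split 2x2 Fisher test of two scores.

    Quantifies co-location of two per-spot signature scores over a spot
    subset (e.g. the tumor region or the boundary band).
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        a, b = a[subset], b[subset]
    if len(a) < 10:
        raise ValueError("need at least 10 spots")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant score vector: correlation undefined")
    rho, p = stats.spearmanr(a, b)
    hi_a = a > np.median(a)
    hi_b = b > np.median(b)
    table = np.array(
        [
            [np.sum(hi_a & hi_b), np.sum(hi_a & ~hi_b)],
            [np.sum(~hi_a & hi_b), np.sum(~hi_a & ~hi_b)],
        ]
    )
    odds, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(p),
        "odds_ratio": float(odds),
        "fisher_p": float(fisher_p),
        "table": table,
    }
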