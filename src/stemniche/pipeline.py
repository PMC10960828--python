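"""End-to-end pipeline driver on synthetic data.

Runs the full chain — lineage simulation with planted CNV, stemness
scoring, metacell aggregation, co-expression module detection, signature
derivation, AUCell-style scoring with a sample-level split, spatial
simulation with CNV-based malignant calling, boundary-band extraction,
co-location statistics, and ligand-receptor scoring — from a single
config, writing TSV outputs plus a JSON manifest with content checksums.

Every stage seeds its own RNG from the master seed, so two runs with the
same config produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnvmod
from . import communication as comm
from . import io as snio
from . import metacells as mc
from . import modules as mods
from . import scoring
from . import simulate as sim
from . import spatial as geo
from . import stemness as stem

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "lineage": {"n_cells": 800, "n_genes": 500, "genes_active_root": 300, "module_size": 40},
    "cnv_truth": {
        "segments": [["chr1", 0, 80, 2.0], ["chr3", 200, 260, 0.5]],
        "malignant_fraction": 0.6,
    },
    "n_stroma": 300,
    "stemness": {},
    "metacell": {"knn_k": 20, "min_size": 25, "n_iterations": 50},
    "wgcna": {"min_module_size": 20, "soft_power": 6, "n_top_genes": 125},
    "spatial": {"n_rows": 24, "n_cols": 24, "tumor_center": [12, 12], "tumor_radius": 5.0},
    "boundary_width": 3,
    "n_samples": 4,
    "n_perm": 50,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides or {})


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | None = None, outdir: str | Path = "stemniche_run") -> dict:
    """Execute the full synthetic pipeline; returns the manifest."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    manifest: dict = {"config": cfg, "stages": {}, "outputs": {}}

    # --- single-cell arm ---------------------------------------------------
    import anndata as ad

    lincfg = sim.LineageConfig(seed=master, **cfg["lineage"])
    tumor = sim.simulate_lineage_cells(lincfg)
    truth = sim.CNVGroundTruth(
        segments=[tuple(s) for s in cfg["cnv_truth"]["segments"]],
        malignant_fraction=cfg["cnv_truth"]["malignant_fraction"],
    )
    tumor = sim.simulate_cnv_profiles(tumor, truth, seed=master + 1)
    stroma = sim.simulate_stroma_cells(lincfg, n_cells=cfg["n_stroma"])
    adata = ad.concat([tumor, stroma], label="population",
                      keys=["malignant", "stroma"], index_unique="-")
    adata.var = tumor.var.copy()
    adata.uns["module_genes"] = tumor.uns["module_genes"]
    malignant = (adata.obs["population"] == "malignant").to_numpy()

    sub = adata[malignant].copy()
    res = stem.score_stemness(sub, stem.StemnessParams(**cfg["stemness"]), seed=master + 2)
    scores_df = pd.DataFrame(
        {
            "gene_count": res.gene_counts,
            "raw": res.raw_score,
            "smoothed": res.smoothed_score,
            "final": res.final_score,
            "state": res.state,
        },
        index=sub.obs_names,
    )
    scores_df.to_csv(outdir / "stemness.tsv", sep="\t")

    part = mc.partition_metacells(
        sub,
        mc.MetacellParams(seed=master + 3, **cfg["metacell"]),
        trait=res.final_score,
    )
    expr = part.metacell_expression
    trait = part.metacell_trait
    if expr.shape[0] < 20:
        # continuum data can collapse the consensus partition; fall back to
        # equal-size pseudo-metacells along the stemness ordering
        expr, trait = mc.pseudobulk_by_rank(sub, res.smoothed_score, group_size=25,
                                            trait=res.final_score)
    expr.to_csv(outdir / "metacells.tsv", sep="\t")

    wparams = mods.WGCNAParams(**cfg["wgcna"])
    n_top = min(wparams.n_top_genes, expr.shape[1])
    top = expr.var(axis=0).nlargest(n_top).index
    expr_top = expr[top]
    beta = wparams.soft_power or mods.pick_soft_threshold(expr_top, wparams)
    cor = np.abs(np.corrcoef(expr_top.to_numpy(), rowvar=False))
    np.fill_diagonal(cor, 0.0)
    tom = mods.tom_matrix(cor**beta)
    module_of = mods.detect_modules(1.0 - tom, wparams)
    markers = mods.malignant_markers(adata, malignant)
    modset = mods.derive_signature(expr_top, module_of, trait, markers)
    pd.Series(modset.signature, name="gene").to_csv(outdir / "signature.csv", index=False)
    manifest["stages"]["modules"] = {
        "soft_power": int(beta),
        "n_modules": int(module_of.max()),
        "selected_module": modset.selected_module,
        "n_signature_genes": len(modset.signature),
    }

    gene_set = modset.signature or list(adata.uns["module_genes"])
    auc = scoring.auc_score(
        np.asarray(sub.layers["lognorm"]), list(sub.var_names), gene_set,
        scoring.AUCParams(tie_seed=master + 4),
    )
    rng = np.random.default_rng(master + 5)
    sample_of = rng.integers(0, cfg["n_samples"], size=sub.n_obs)
    split = scoring.sample_scores_and_split(auc, sample_of)
    split.to_csv(outdir / "sample_split.tsv", sep="\t")

    # --- spatial arm -------------------------------------------------------
    spcfg = sim.SpatialConfig(
        seed=master + 6,
        **{**cfg["spatial"], "tumor_center": tuple(cfg["spatial"]["tumor_center"])},
    )
    profiles = sim.SpotProfiles(
        cnv=sim.CNVGroundTruth(
            segments=[("chr1", 0, 60, 2.0), ("chr2", 100, 150, 0.5)], malignant_fraction=1.0
        )
    )
    spots = sim.simulate_visium_sample(spcfg, profiles)
    cnv_res = cnvmod.call_malignant_spots(spots, seed=master + 7)
    snio.write_tissue_positions(spots, outdir / "tissue_positions.csv")
    cnv_res.cluster_scores.to_csv(outdir / "cnv_cluster_scores.tsv", sep="\t")

    lattice = geo.build_adjacency(spots.obs, cluster=spots.obs["malignant_call"].to_numpy())
    rim = geo.outer_rim(lattice, True)
    band = geo.boundary_band(lattice, rim, width=cfg["boundary_width"])
    pd.DataFrame(
        {"spot": spots.obs_names[band.band], "side": band.side.to_numpy()}
    ).to_csv(outdir / "boundary_band.tsv", sep="\t", index=False)

    csc_auc = scoring.auc_score(
        np.asarray(spots.layers["lognorm"]), list(spots.var_names),
        list(spots.uns["csc_genes"]), scoring.AUCParams(tie_seed=master + 8),
    )
    mac_auc = scoring.auc_score(
        np.asarray(spots.layers["lognorm"]), list(spots.var_names),
        list(spots.uns["macro_genes"]), scoring.AUCParams(tie_seed=master + 8),
    )
    coloc = geo.colocation_stats(csc_auc, mac_auc, band.band)
    manifest["stages"]["colocation"] = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in coloc.items()
    }

    pairs = [
        comm.LRPair(spots.uns["macro_genes"][0], (spots.uns["csc_genes"][0],), "planted")
    ] + [
        comm.LRPair(f"gene_{i:04d}", (f"gene_{i + 1:04d}",), "decoy")
        for i in range(100, 140, 2)
    ]
    labels = np.where(
        spots.obs["malignant_call"], "tumor",
        np.where(spots.obs["immune_region"], "immune", "stroma"),
    )
    comm_res = comm.lr_scores(
        np.asarray(spots.layers["lognorm"]), labels, list(spots.var_names), pairs,
        n_perm=cfg["n_perm"], seed=master + 9,
    )
    comm_res.scores.to_csv(outdir / "communication.tsv", sep="\t", index=False)

    for f in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.csv")):
        manifest["outputs"][f.name] = _checksum(f)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
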