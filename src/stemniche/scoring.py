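"""AUCell-style recovery-curve gene-set scoring and sample-level splits.

For each observation genes are ranked by expression (descending, ties
broken by a deterministic seeded shuffle); the AUC is the area under the
step curve counting how many signature genes appear within the top
``maxRank = ceil(max_rank_fraction * n_genes)`` positions, normalized by
the area of a perfectly front-loaded set so a signature occupying ranks
1..m scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AUCParams", "auc_score", "sample_scores_and_split"]


@dataclass
class AUCParams:
    max_rank_fraction: float = 0.05  # AUCell's default top-rank cutoff
    tie_seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.max_rank_fraction <= 1.0:
            raise ValueError("max_rank_fraction must lie in (0, 1]")


def auc_score(
    expr: np.ndarray | pd.DataFrame,
    gene_names: list[str],
    gene_set: list[str],
    params: AUCParams | None = None,
) -> np.ndarray:
    """Per-observation recovery-curve AUC of a gene set.

    ``expr`` is observation x gene.  With ranks ``r_g`` of the set genes
    (1-based) and ``H(k) = |{set genes with rank <= k}|``,
    ``AUC = sum_{k<=maxRank} H(k) / sum_{k<=maxRank} min(k, m)`` where m is
    the effective set size.
    """
    params = params or AUCParams()
    params.validate()
    if isinstance(expr, pd.DataFrame):
        gene_names = list(expr.columns)
        expr = expr.to_numpy()
    expr = np.asarray(expr, dtype=float)
    n_obs, n_genes = expr.shape

    name_pos = {g: i for i, g in enumerate(gene_names)}
    set_cols = np.array([name_pos[g] for g in gene_set if g in name_pos], dtype=int)
    m = len(set_cols)
    if m == 0:
        raise ValueError("gene set has no overlap with the measured genes")

    max_rank = int(np.ceil(params.max_rank_fraction * n_genes))
    denom = _max_area(max_rank, m)

    in_set = np.zeros(n_genes, dtype=bool)
    in_set[set_cols] = True

    aucs = np.empty(n_obs)
    for i in range(n_obs):
        rng = np.random.default_rng([params.tie_seed, i])
        perm = rng.permutation(n_genes)  # deterministic tie shuffle per observation
        order = perm[np.argsort(-expr[i, perm], kind="stable")]
        ranks = np.nonzero(in_set[order])[0] + 1  # 1-based ranks of set genes
        within = ranks[ranks <= max_rank]
        # sum_{k=1..maxRank} H(k) = sum over hits of (maxRank - rank + 1)
        aucs[i] = (max_rank - within + 1).sum() / denom
    return aucs


def _max_area(max_rank: int, m: int) -> float:
    """Area of the recovery curve for a perfectly front-loaded set."""
    if m >= max_rank:
        return max_rank * (max_rank + 1) / 2.0
    return m * (m + 1) / 2.0 + m * (max_rank - m)


def sample_scores_and_split(
    scores: np.ndarray,
    sample_of: np.ndarray,
    malignant_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-sample mean score over malignant observations and a median split.

    Samples strictly above the across-sample median are "high", the rest
    "low" (at-median ties go to low).  Samples without malignant
    observations are excluded with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    sample_of = np.asarray(sample_of)
    mask = np.ones(len(scores), dtype=bool) if malignant_mask is None else np.asarray(
        malignant_mask, dtype=bool
    )

    rows = {}
    for s in pd.unique(sample_of):
        sel = (sample_of == s) & mask
        if not sel.any():
            import warnings

            warnings.warn(f"sample {s!r} has no malignant observations; excluded")
            continue
        rows[s] = float(scores[sel].mean())
    if len(rows) < 2:
        raise ValueError("need at least 2 samples with malignant observations")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["mean_score"])
    med = table["mean_score"].median()
    table["group"] = np.where(table["mean_score"] > med, "high", "low")
    return table
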