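"""Simplified ligand-receptor communication scoring with a permutation null.

Group-level expression is summarized by Tukey's trimean; multi-subunit
receptors by the geometric mean of subunit trimeans; the interaction score
follows a saturating law-of-mass-action form L*R / (Kh + L*R) with
half-saturation Kh = 0.5, so scores live in [0, 1).  Significance comes
from shuffling group labels: p = (1 + #{perm >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LRPair", "CommResult", "group_summary", "lr_scores", "read_lr_database"]

KH = 0.5  # half-saturation constant of the interaction score


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: tuple[str, ...]  # one or more subunits
    pathway: str = ""

    def __post_init__(self):
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and at least one receptor subunit required")


@dataclass
class CommResult:
    scores: pd.DataFrame        # (sender, receiver, ligand, receptor): score, p
    pathway_strength: pd.Series
    outgoing: pd.Series         # per group: total sent
    incoming: pd.Series         # per group: total received
    dropped_pairs: list[LRPair] = field(default_factory=list)


def read_lr_database(path) -> list[LRPair]:
    """Read a ligand-receptor CSV: ligand, receptor (';'-separated), pathway."""
    df = pd.read_csv(path)
    return [
        LRPair(
            ligand=row["ligand"],
            receptor=tuple(str(row["receptor"]).split(";")),
            pathway=row.get("pathway", ""),
        )
        for _, row in df.iterrows()
    ]


def group_summary(expr: np.ndarray, labels: np.ndarray, gene_names: list[str],
                  min_group: int = 3) -> pd.DataFrame:
    """Tukey trimean (q25 + 2*median + q75)/4 per gene per group."""
    labels = np.asarray(labels)
    expr = np.asarray(expr, dtype=float)
    rows = {}
    for g in pd.unique(labels):
        sel = labels == g
        if sel.sum() < min_group:
            import warnings

            warnings.warn(f"group {g!r} has fewer than {min_group} observations; skipped")
            continue
        q25, q50, q75 = np.quantile(expr[sel], [0.25, 0.5, 0.75], axis=0)
        rows[g] = (q25 + 2 * q50 + q75) / 4.0
    if not rows:
        raise ValueError("no group large enough to summarize")
    return pd.DataFrame.from_dict(rows, orient="index", columns=gene_names)


def _pair_score(summary: pd.DataFrame, pair: LRPair) -> pd.DataFrame:
    """Group x group score matrix for one pair (rows send, columns receive)."""
    lig = summary[pair.ligand].to_numpy()
    rec = np.exp(np.log(summary[list(pair.receptor)].to_numpy() + 1e-300).mean(axis=1))
    rec[np.any(summary[list(pair.receptor)].to_numpy() == 0, axis=1)] = 0.0
    lr = np.outer(lig, rec)
    return pd.DataFrame(lr / (KH + lr), index=summary.index, columns=summary.index)


def lr_scores(
    expr: np.ndarray,
    labels: np.ndarray,
    gene_names: list[str],
    pairs: list[LRPair],
    n_perm: int = 100,
    seed: int = 0,
) -> CommResult:
    """Score every (sender, receiver, pair) triple with a permutation p-value.

    Pairs whose ligand or all receptor subunits are unmeasured are dropped
    with a warning; measured-but-silent genes yield score 0 and p = 1 by
    construction of the null.
    """
    gene_names = list(gene_names)
    measured = set(gene_names)
    usable, dropped = [], []
    for p in pairs:
        if p.ligand in measured and all(r in measured for r in p.receptor):
            usable.append(p)
        else:
            dropped.append(p)
    if dropped:
        import warnings

        warnings.warn(f"{len(dropped)} pair(s) reference unmeasured genes; dropped")
    if not usable:
        raise ValueError("no usable ligand-receptor pairs")

    labels = np.asarray(labels)
    summary = group_summary(expr, labels, gene_names)
    groups = list(summary.index)

    observed = {p: _pair_score(summary, p) for p in usable}

    rng = np.random.default_rng(seed)
    exceed = {p: np.zeros((len(groups), len(groups)), dtype=np.int64) for p in usable}
    genes_needed = sorted({g for p in usable for g in (p.ligand, *p.receptor)})
    cols = [gene_names.index(g) for g in genes_needed]
    sub_expr = np.asarray(expr, dtype=float)[:, cols]
    for _ in range(n_perm):
        perm_labels = rng.permutation(labels)
        perm_summary = group_summary(sub_expr, perm_labels, genes_needed)
        perm_summary = perm_summary.reindex(index=groups).fillna(0.0)
        for p in usable:
            ps = _pair_score(perm_summary, p)
            exceed[p] += (ps.to_numpy() >= observed[p].to_numpy()).astype(np.int64)

    records = []
    for p in usable:
        pv = (1.0 + exceed[p]) / (n_perm + 1.0)
        obs = observed[p]
        for i, snd in enumerate(groups):
            for j, rcv in enumerate(groups):
                records.append(
                    {
                        "sender": snd,
                        "receiver": rcv,
                        "ligand": p.ligand,
                        "receptor": ";".join(p.receptor),
                        "pathway": p.pathway,
                        "score": float(obs.iloc[i, j]),
                        "p": float(pv[i, j]),
                    }
                )
    scores = pd.DataFrame.from_records(records)

    pathway_strength = scores.groupby("pathway")["score"].sum()
    outgoing = scores.groupby("sender")["score"].sum()
    incoming = scores.groupby("receiver")["score"].sum()
    return CommResult(
        scores=scores,
        pathway_strength=pathway_strength,
        outgoing=outgoing,
        incoming=incoming,
        dropped_pairs=dropped,
    )
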