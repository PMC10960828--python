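"""Score ligand-receptor communication between labelled groups with a
permutation null; a planted macrophage-to-tumor pair should rank first."""

import numpy as np

import stemniche as sn

rng = np.random.default_rng(0)
genes = [f"g{i}" for i in range(50)] + ["SPP1", "CD44"]
labels = np.repeat(["macro", "tumor", "other"], 40)
expr = rng.poisson(1.0, size=(120, 52)).astype(float)
expr[labels == "macro", 50] += rng.poisson(5.0, 40)   # ligand in macrophages
expr[labels == "tumor", 51] += rng.poisson(5.0, 40)   # receptor on tumor cells

pairs = [sn.LRPair("SPP1", ("CD44",), "SPP1")] + [
    sn.LRPair(f"g{i}", (f"g{i + 1}",), "decoy") for i in range(0, 40, 2)
]
result = sn.lr_scores(expr, labels, genes, pairs, n_perm=100, seed=1)

mt = result.scores[(result.scores.sender == "macro") & (result.scores.receiver == "tumor")]
ranked = mt.sort_values("score", ascending=False)

print("top macro -> tumor interactions:")
print(ranked[["ligand", "receptor", "score", "p"]].head(3).to_string(index=False))
print()
print(f"outgoing totals: {result.outgoing.round(2).to_dict()}")
print(f"incoming totals: {result.incoming.round(2).to_dict()}")
print()
print("The planted SPP1-CD44 pair should top the macro->tumor ranking with a")
print("permutation p at the 1/(n_perm+1) floor; decoy pairs built from")
print("unstructured genes stay low.")
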