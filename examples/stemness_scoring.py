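"""Score per-cell stemness on a simulated differentiation hierarchy.

Cells lower in the hierarchy express more genes; the scorer turns that
premise into a [0, 1] score (1 = most stem-like) and labels the top/bottom
quartiles CSC / non-CSC.
"""

import collections

from scipy import stats

import stemniche as sn

adata = sn.simulate_lineage_cells(sn.LineageConfig(n_cells=500, seed=1))
result = sn.score_stemness(adata, seed=1)

rho = stats.spearmanr(result.final_score, -adata.obs["true_depth"]).statistic
counts = collections.Counter(result.state)

print(f"cells scored:            {adata.n_obs}")
print(f"score range:             [{result.final_score.min():.2f}, {result.final_score.max():.2f}]")
print(f"Spearman vs true depth:  {rho:.3f}")
print(f"state counts:            {dict(counts)}")
print()
print("The Spearman correlation compares the score against the generator's")
print("planted depth (0 = root): values near 1 mean the score recovers the")
print("differentiation hierarchy. Exactly a quarter of cells are CSC.")
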