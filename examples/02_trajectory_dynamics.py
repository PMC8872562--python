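"""Pseudotime inference, orientation and dynamic-gene detection.

Orders 500 synthetic cells along the inferred developmental axis,
orients it with base-low marker genes, and tests every expressed gene
for pseudotime dependence with the NB spline likelihood-ratio test.
"""

import numpy as np
from scipy.stats import spearmanr

import mesotraject as mt

grn = mt.syndata.simulate_grn(n_tf=10, density=0.15, seed=3)
matrix, truth = mt.syndata.simulate_cells(grn, n_cells=500, n_lowq=0, seed=4)

hvg = mt.cells.select_hvg(matrix, n=150)
traj = mt.trajectory.infer_pseudotime(matrix.subset_genes(hvg), seed=0)
rho = spearmanr(traj.pseudotime, truth.true_time).statistic
print(f"pseudotime vs latent time: |Spearman| = {abs(rho):.3f}")

# orient so "increasing" genes (lowest at the developmental origin,
# like the AspAT/NADP-MDH/PPDK/CA/PEPC panel in real leaves) rise
markers = [g for g, lab in truth.dynamic_gene_labels.items()
           if lab == "increasing"][:5]
traj = mt.trajectory.orient_trajectory(traj, matrix, markers)
rho = spearmanr(traj.pseudotime, truth.true_time).statistic
print(f"after marker orientation: signed Spearman = {rho:.3f} "
      "(positive: root sits at the developmental origin)")

dyn = mt.trajectory.test_dynamic_genes(matrix, traj, min_mean=0.1)
n_sig = int((dyn["q"] < 0.01).sum())
print(f"dynamic genes: {int(dyn['tested'].sum())} tested, "
      f"{n_sig} with q < 0.01")

labels = mt.trajectory.cluster_gene_profiles(dyn, matrix, traj, k=6)
print("profile clusters:",
      dict(labels.value_counts().sort_index()))
# G1 peaks earliest, G6 latest; the planted increasing/decreasing/
# transient templates distribute across the six clusters by peak time.
flat = [g for g, lab in truth.dynamic_gene_labels.items() if lab == "flat"]
trans = [g for g, lab in truth.dynamic_gene_labels.items()
         if lab == "transient"]
print(f"median LRT statistic: flat templates "
      f"{dyn.loc[flat, 'lrt_stat'].median():.1f} vs transient templates "
      f"{dyn.loc[trans, 'lrt_stat'].median():.1f}")
# Flat-template genes keep a small residual statistic because UMI counts
# are compositional: as truly dynamic genes rise, everyone else's share
# shifts slightly. The planted dynamics dominate by orders of magnitude.
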