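"""Simulate a study-shaped count matrix and inspect depth/QC structure.

Generates 2,000 genes over the 18-sample factorial design (2 diets x 3
temperatures x 3 replicates), estimates size factors with both schemes, and
runs PCA on the variance-stabilized matrix.
"""

from wormtx.normalization import pca, regularized_log, size_factors_median_ratio, size_factors_tmm
from wormtx.simulate import SimulationConfig, simulate_counts

cfg = SimulationConfig(n_genes=2000, seed=1)
matrix, truth = simulate_counts(cfg)
print(f"simulated {matrix.counts.shape[0]} genes x {matrix.counts.shape[1]} samples")
print("planted classes:", truth.labels.value_counts().to_dict())

f_mr = size_factors_median_ratio(matrix)
f_tmm = size_factors_tmm(matrix)
print("\nmedian-ratio size factors (first 6):",
      f_mr.factors.head(6).round(3).to_dict())
print("TMM size factors agree within",
      f"{abs(f_tmm.factors / f_mr.factors * f_mr.factors.prod()**(1/18) - 1).max():.1%}")

rld = regularized_log(matrix, f_mr)
scores, _, var_exp = pca(rld, n_components=2)
print(f"\nPC1 explains {var_exp[0]:.1%} of variance, PC2 {var_exp[1]:.1%}")
print("PC1 by sample (positive/negative should track the dominant effect):")
print(scores["PC1"].round(1).to_string())
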