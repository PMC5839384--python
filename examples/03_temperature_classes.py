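"""Classify temperature responses per diet and overlap the classes across diets.

Runs the three within-diet temperature contrasts for each diet, feeds the
consensus calls to the classifier, and scores the cross-diet overlap of each
class with a representation factor.  "Exclusively hot" genes switch on only
at 25 degC; "false hot" genes are really down-regulated at 15 degC (the
mirror classes swap the roles of 15 and 25 degC).
"""

from wormtx.classify import ContrastCallSet, classify_temperature_response
from wormtx.de import Contrast, consensus, estimate_dispersions, exact_test_nb, wald_test
from wormtx.normalization import size_factors_median_ratio, size_factors_tmm
from wormtx.overlap import OverlapStat
from wormtx.simulate import SimulationConfig, simulate_counts

cfg = SimulationConfig(n_genes=2000, seed=1)
matrix, truth = simulate_counts(cfg)
f_mr = size_factors_median_ratio(matrix)
f_tmm = size_factors_tmm(matrix)
groups = list(matrix.condition_groups().values())
d_mr = estimate_dispersions(matrix, f_mr, groups)
d_tmm = estimate_dispersions(matrix, f_tmm, groups)

classifications = {}
for diet in ("ecoli", "bsubtilis"):
    calls = {}
    for key, (hi, lo) in {"25v15": (25, 15), "25v20": (25, 20), "20v15": (20, 15)}.items():
        c = Contrast.between(matrix, (diet, hi), (diet, lo))
        calls[key] = consensus(wald_test(matrix, f_mr, c, d_mr),
                               exact_test_nb(matrix, f_tmm, c, d_tmm))
    classifications[diet] = classify_temperature_response(
        ContrastCallSet(diet=diet, calls=calls))
    print(diet, classifications[diet].counts())

print("\ncross-diet overlaps (background = tested genes):")
for label in ("exclusively_hot", "false_hot", "exclusively_cold", "false_cold"):
    a = classifications["ecoli"].genes(label)
    b = classifications["bsubtilis"].genes(label)
    if a and b:
        s = OverlapStat.from_sets(a, b, matrix.counts.shape[0])
        print(f"  {label}: k={s.k} of {s.n1}/{s.n2}, RF={s.rf:.1f}, log10 p={s.log10_p:.1f}")
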