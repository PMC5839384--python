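import numpy as np
import pandas as pd
import pytest

from wormtx.io import CountMatrix
from wormtx.normalization import size_factors_median_ratio, size_factors_tmm
from wormtx.de import estimate_dispersions
from wormtx.simulate import SimulationConfig, simulate_counts


def make_matrix(counts, sample_conditions, gene_ids=None):
    """Hand-built CountMatrix: counts is a list of rows, sample_conditions a
    list of (diet, temperature) per column."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    seen: dict[tuple, int] = {}
    sids, diets, temps, reps = [], [], [], []
    for cond in sample_conditions:
        seen[cond] = seen.get(cond, 0) + 1
        sids.append(f"{cond[0]}_{cond[1]}_r{seen[cond]}")
        diets.append(cond[0])
        temps.append(cond[1])
        reps.append(seen[cond])
    samples = pd.DataFrame(
        {"diet": diets, "temperature": temps, "replicate": reps},
        index=pd.Index(sids, name="sample"),
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sids), samples=samples
    )


PLANTED_COUNTS = {
    "exclusively_hot": 80,
    "false_hot": 80,
    "exclusively_cold": 80,
    "false_cold": 80,
    "diet_ecoli_up": 40,
    "diet_bsub_up": 40,
}


@pytest.fixture(scope="session")
def planted_sim():
    """A 1600-gene planted simulation shared across test modules."""
    cfg = SimulationConfig(n_genes=1600, class_counts=dict(PLANTED_COUNTS), seed=11)
    matrix, truth = simulate_counts(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def planted_de(planted_sim):
    """Size factors and dispersions for the shared planted simulation."""
    _, matrix, _ = planted_sim
    f_mr = size_factors_median_ratio(matrix)
    f_tmm = size_factors_tmm(matrix)
    groups = list(matrix.condition_groups().values())
    return {
        "mr": (f_mr, estimate_dispersions(matrix, f_mr, groups)),
        "tmm": (f_tmm, estimate_dispersions(matrix, f_tmm, groups)),
    }


@pytest.fixture(scope="session")
def null_sim():
    """A simulation with no planted effects (every gene null)."""
    cfg = SimulationConfig(
        n_genes=1500, class_counts={}, dispersion_a0=0.1, dispersion_a1=0.0, seed=23
    )
    matrix, truth = simulate_counts(cfg)
    return cfg, matrix, truth
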