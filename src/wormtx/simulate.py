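"""Negative-binomial count simulator with planted diet/temperature effect classes.

Emulates the study design the rest of the package targets: 18 bulk RNA-seq
samples = 2 diets (*E. coli*, *B. subtilis*) x 3 growth temperatures
(15, 20, 25 degC) x 3 biological replicates, ~17,600 expressed genes.  Each
gene gets a log-normal baseline mean, a gene-level NB dispersion following
the parametric trend ``alpha(mu) = a0 + a1/mu``, and a per-sample uniform
depth factor; counts are drawn gamma-Poisson so that
``var = mu + alpha * mu**2``.

Genes are planted into known response classes so every downstream stage has
a recovery target:

====================  =====================================================
class                 expected-mean pattern (both diets unless noted)
====================  =====================================================
``exclusively_hot``   up by ``2**lfc`` at 25 degC only
``false_hot``         down by ``2**lfc`` at 15 degC only
``exclusively_cold``  up by ``2**lfc`` at 15 degC only
``false_cold``        down by ``2**lfc`` at 25 degC only
``diet_ecoli_up``     up by ``2**lfc`` on the E. coli diet at all temperatures
``diet_bsub_up``      up by ``2**lfc`` on the B. subtilis diet at all temperatures
``null``              flat across all six conditions
====================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import DIETS, TEMPERATURES, CountMatrix, GeneSetCollection

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "simulate_counts",
    "simulate_gene_sets",
    "default_class_counts",
    "CLASS_LABELS",
]

CLASS_LABELS = (
    "exclusively_hot",
    "false_hot",
    "exclusively_cold",
    "false_cold",
    "diet_ecoli_up",
    "diet_bsub_up",
    "null",
)

_CONDITIONS = [(d, t) for d in DIETS for t in TEMPERATURES]


#: planted-class sizes at the full study scale of 17,600 genes; the
#: magnitudes echo the published E. coli-side list sizes
_FULL_SCALE_CLASS_COUNTS = {
    "exclusively_hot": 180,
    "false_hot": 390,
    "exclusively_cold": 30,
    "false_cold": 630,
    "diet_ecoli_up": 70,
    "diet_bsub_up": 170,
}
_FULL_SCALE_N_GENES = 17600


def default_class_counts(n_genes: int = _FULL_SCALE_N_GENES) -> dict[str, int]:
    """Planted-class sizes with the default fractions, scaled to ``n_genes``."""
    scale = n_genes / _FULL_SCALE_N_GENES
    return {k: max(1, round(v * scale)) for k, v in _FULL_SCALE_CLASS_COUNTS.items()}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``lfc`` may be a single log2 effect size applied to every planted class
    or a per-class mapping.  ``baseline_log_mean_mu``/``sigma`` parameterize
    the log10-normal baseline expression distribution (default: median mean
    count 100, one decade of spread — the dynamic range typical of bulk
    RNA-seq).  Dispersion follows ``alpha(mu) = dispersion_a0 +
    dispersion_a1 / mu``.  Depth factors are uniform on
    ``[size_factor_low, size_factor_high]``.
    """

    n_genes: int = _FULL_SCALE_N_GENES
    class_counts: dict[str, int] | None = None
    lfc: float | Mapping[str, float] = 2.0
    baseline_log_mean_mu: float = 2.0
    baseline_log_mean_sigma: float = 1.0
    dispersion_a0: float = 0.05
    dispersion_a1: float = 5.0
    size_factor_low: float = 0.7
    size_factor_high: float = 1.4
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.class_counts is None:
            self.class_counts = default_class_counts(self.n_genes)
        unknown = set(self.class_counts) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class label(s): {sorted(unknown)}")
        planted = sum(v for k, v in self.class_counts.items() if k != "null")
        total = planted + self.class_counts.get("null", 0)
        if total > self.n_genes:
            raise ValueError(
                f"class counts sum to {total} > n_genes = {self.n_genes}"
            )
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        if not (0 < self.size_factor_low <= self.size_factor_high):
            raise ValueError("size factor bounds must be positive with low <= high")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ValueError("dispersion trend coefficients must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per condition")
        lfcs = self.lfc.values() if isinstance(self.lfc, Mapping) else [self.lfc]
        if not all(np.isfinite(v) for v in lfcs):
            raise ValueError("all lfc values must be finite")

    def lfc_for(self, label: str) -> float:
        if isinstance(self.lfc, Mapping):
            return float(self.lfc.get(label, 0.0))
        return float(self.lfc)


@dataclass
class PlantedTruth:
    """Ground truth of a simulation run.

    ``labels``/``direction`` are per-gene Series; ``expected_means`` holds
    the noise-free mean for each of the six (diet, temperature) conditions,
    columns named ``{diet}_{temperature}``.
    """

    labels: pd.Series
    direction: pd.Series
    expected_means: pd.DataFrame
    #: the per-sample depth factors that were drawn (simulation provenance)
    size_factors: pd.Series | None = None

    def genes_in_class(self, label: str) -> set[str]:
        return set(self.labels.index[self.labels == label])

    def to_frame(self) -> pd.DataFrame:
        out = self.expected_means.copy()
        out.insert(0, "direction", self.direction)
        out.insert(0, "class", self.labels)
        out.index.name = "gene"
        return out


def _condition_multipliers(label: str, lfc: float) -> dict[tuple[str, int], float]:
    up, down = 2.0**lfc, 2.0**-lfc
    mult = {c: 1.0 for c in _CONDITIONS}
    if label == "exclusively_hot":
        for d in DIETS:
            mult[(d, 25)] = up
    elif label == "false_hot":
        for d in DIETS:
            mult[(d, 15)] = down
    elif label == "exclusively_cold":
        for d in DIETS:
            mult[(d, 15)] = up
    elif label == "false_cold":
        for d in DIETS:
            mult[(d, 25)] = down
    elif label == "diet_ecoli_up":
        for t in TEMPERATURES:
            mult[("ecoli", t)] = up
    elif label == "diet_bsub_up":
        for t in TEMPERATURES:
            mult[("bsubtilis", t)] = up
    return mult


_DIRECTION = {
    "exclusively_hot": 1,
    "false_hot": -1,
    "exclusively_cold": 1,
    "false_cold": -1,
    "diet_ecoli_up": 1,
    "diet_bsub_up": 1,
    "null": 0,
}


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, PlantedTruth]:
    """Draw a count matrix and its planted truth from the factorial design.

    Deterministic for a fixed ``config.seed``; each gene consumes its own
    counter-based random substream, so changing ``n_genes`` never reshuffles
    the counts of earlier genes.
    """
    cfg = config
    n_rep = cfg.n_replicates
    sample_ids, diets, temps, reps = [], [], [], []
    for d, t in _CONDITIONS:
        for r in range(1, n_rep + 1):
            sample_ids.append(f"{d}_{t}_r{r}")
            diets.append(d)
            temps.append(t)
            reps.append(r)
    samples = pd.DataFrame(
        {"diet": diets, "temperature": temps, "replicate": reps},
        index=pd.Index(sample_ids, name="sample"),
    )
    cond_of_sample = [(d, t) for d, t in zip(diets, temps)]

    sf_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    size_factors = sf_rng.uniform(cfg.size_factor_low, cfg.size_factor_high, size=len(sample_ids))

    labels = []
    for lab in CLASS_LABELS[:-1]:
        labels.extend([lab] * cfg.class_counts.get(lab, 0))
    labels.extend(["null"] * (cfg.n_genes - len(labels)))
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]

    counts = np.empty((cfg.n_genes, len(sample_ids)), dtype=np.int64)
    exp_means = np.empty((cfg.n_genes, len(_CONDITIONS)))
    for i, (gid, lab) in enumerate(zip(gene_ids, labels)):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1, i)))
        baseline = 10.0 ** rng.normal(cfg.baseline_log_mean_mu, cfg.baseline_log_mean_sigma)
        mult = _condition_multipliers(lab, cfg.lfc_for(lab))
        q = {c: baseline * mult[c] for c in _CONDITIONS}
        exp_means[i] = [q[c] for c in _CONDITIONS]
        mu = np.array([q[c] for c in cond_of_sample]) * size_factors
        if cfg.dispersion_a0 == 0 and cfg.dispersion_a1 == 0:
            lam = mu  # Poisson limit
        else:
            # dispersion follows the trend at each condition's expected mean
            alpha = cfg.dispersion_a0 + cfg.dispersion_a1 / np.array(
                [q[c] for c in cond_of_sample]
            )
            lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
        counts[i] = rng.poisson(lam)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=sample_ids),
        samples=samples,
    )
    truth = PlantedTruth(
        labels=pd.Series(labels, index=gene_ids, name="class"),
        direction=pd.Series([_DIRECTION[lab] for lab in labels], index=gene_ids, name="direction"),
        expected_means=pd.DataFrame(
            exp_means, index=gene_ids, columns=[f"{d}_{t}" for d, t in _CONDITIONS]
        ),
        size_factors=pd.Series(size_factors, index=sample_ids, name="size_factor"),
    )
    return matrix, truth


def simulate_gene_sets(
    truth: PlantedTruth,
    n_terms: int,
    term_size_range: tuple[int, int] = (10, 50),
    n_enriched_terms: int = 0,
    seed: int = 0,
    enriched_fraction: float = 0.8,
) -> GeneSetCollection:
    """Build a GMT-representable gene-set collection over the simulated genes.

    The first ``n_enriched_terms`` terms draw ``enriched_fraction`` of their
    members from one planted (non-null) class, cycling through the classes
    present in ``truth``; the rest of each enriched term, and all remaining
    terms, are sampled uniformly from the whole gene universe.  Byte-identical
    output for a fixed seed.
    """
    if not (n_terms >= n_enriched_terms >= 0):
        raise ValueError("need n_terms >= n_enriched_terms >= 0")
    lo, hi = term_size_range
    universe = list(truth.labels.index)
    if hi > len(universe):
        raise ValueError(f"term size {hi} larger than universe of {len(universe)} genes")
    if not (1 <= lo <= hi):
        raise ValueError("invalid term size range")
    planted_classes = [
        lab for lab in CLASS_LABELS[:-1] if (truth.labels == lab).any()
    ]
    if n_enriched_terms > 0 and not planted_classes:
        raise ValueError("cannot build enriched terms: no planted classes in truth")

    rng = np.random.default_rng(seed)
    universe_arr = np.array(universe)
    terms: dict[str, tuple[str, list[str]]] = {}
    for j in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        if j < n_enriched_terms:
            lab = planted_classes[j % len(planted_classes)]
            pool = np.array(sorted(truth.genes_in_class(lab)))
            n_from_class = min(int(round(enriched_fraction * size)), len(pool))
            picked = list(rng.choice(pool, size=n_from_class, replace=False))
            rest_pool = universe_arr[~np.isin(universe_arr, picked)]
            picked += list(rng.choice(rest_pool, size=size - n_from_class, replace=False))
            desc = f"enriched:{lab}"
        else:
            picked = list(rng.choice(universe_arr, size=size, replace=False))
            desc = "random"
        terms[f"TERM{j:04d}"] = (desc, sorted(picked))
    return GeneSetCollection(terms=terms)
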