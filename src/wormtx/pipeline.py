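"""End-to-end orchestration: counts -> normalization -> dual DE -> consensus ->
response classification -> overlap statistics -> enrichment -> report.

``run_full_analysis`` is deterministic given the seed and inputs; every
stage's table is persisted (CSV/TSV) so single stages can be re-run from
intermediates, and a JSON summary records every count the tables support,
plus the configuration echo and the declared deviations from the reference
tooling (no regularized-log shrinkage, no independent filtering, no fold-
change shrinkage priors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from ._version import __version__ as _VERSION
from .classify import (
    ContrastCallSet,
    TemperatureClassification,
    classify_diet_response,
    classify_temperature_response,
)
from .de import Contrast, consensus, estimate_dispersions, exact_test_nb, wald_test
from .enrichment import overrepresentation_test
from .io import (
    DIETS,
    TEMPERATURES,
    CountMatrix,
    read_counts,
    read_gmt,
    read_sample_sheet,
    write_counts,
    write_results,
    write_sample_sheet,
)
from .normalization import (
    pca,
    regularized_log,
    sample_distances,
    size_factors_median_ratio,
    size_factors_tmm,
)
from .overlap import OverlapStat
from .simulate import SimulationConfig, simulate_counts

__all__ = ["RunConfig", "run_full_analysis"]

log = logging.getLogger("wormtx")

DEVIATIONS = (
    "regularized_log_implemented_as_log2_normalized_plus_1",
    "no_independent_filtering_or_cooks_outlier_filtering",
    "no_lfc_shrinkage_prior_moderation_constant_0.5",
    "dispersion_shrinkage_fixed_weight_0.5_toward_trend",
)

#: within-diet temperature contrasts, warmer condition first
TEMP_CONTRAST_KEYS = ("25v15", "25v20", "20v15")
_TEMP_PAIRS = {"25v15": (25, 15), "25v20": (25, 20), "20v15": (20, 15)}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``counts`` (+ ``sample_sheet``) or ``simulation`` must be
    given.  ``background_n`` sets the gene universe for cross-diet overlap
    statistics; when None, the number of tested genes is used (the right
    choice for user data — the published constant 17,611 applies only to
    analyses quoted against the full *C. elegans* expressed-gene universe).
    """

    counts: str | None = None
    sample_sheet: str | None = None
    simulation: SimulationConfig | dict | None = None
    gene_sets: str | None = None
    alpha: float = 0.05
    background_n: int | None = None
    min_term: int = 5
    max_term: int = 2000
    outdir: str = "wormtx_results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        has_files = self.counts is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError("exactly one of counts / simulation must be configured")
        if has_files and self.sample_sheet is None:
            raise ValueError("counts input requires a sample sheet")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**{**self.simulation, "seed": self.seed})


def _contrast_tables(matrix, contrast, f_mr, f_tmm, disp_mr, disp_tmm, alpha):
    t_wald = wald_test(matrix, f_mr, contrast, disp_mr, alpha=alpha)
    t_exact = exact_test_nb(matrix, f_tmm, contrast, disp_tmm, alpha=alpha)
    up, down = consensus(t_wald, t_exact, alpha=alpha)
    return t_wald, t_exact, (up, down)


def _overlap_row(label, common, n1, n2, N) -> dict[str, Any]:
    row: dict[str, Any] = {"label": label, "k": len(common), "n1": n1, "n2": n2, "N": N}
    if n1 > 0 and n2 > 0:
        stat = OverlapStat.from_counts(len(common), n1, n2, N)
        row.update(rf=round(stat.rf, 1), p=stat.p, log10_p=stat.log10_p)
    else:
        row.update(rf=None, p=None, log10_p=None)
    return row


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Run every stage and return the run summary (also written as JSON).

    The summary holds per-contrast DE counts for both engines and the
    consensus, the per-diet temperature-class counts, the diet-response
    counts, the cross-diet common sets with representation factors, the
    enrichment hits (when a gene-set collection is configured) and
    provenance (seed, version, config echo, declared deviations).
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulation is not None:
        log.info("simulating counts: %d genes, seed %d", config.simulation.n_genes, config.seed)
        matrix, truth = simulate_counts(config.simulation)
        write_counts(matrix, outdir / "counts.tsv")
        write_sample_sheet(matrix.samples, outdir / "samples.tsv")
        truth.to_frame().to_csv(outdir / "planted_truth.csv", float_format="%.12g")
    else:
        matrix = read_counts(config.counts)
        matrix = CountMatrix(counts=matrix.counts, samples=read_sample_sheet(config.sample_sheet))

    # drop genes with zero counts everywhere; they are untestable
    expressed = matrix.counts.sum(axis=1) > 0
    n_dropped = int((~expressed).sum())
    matrix = CountMatrix(counts=matrix.counts.loc[expressed], samples=matrix.samples)
    tested_genes = set(matrix.counts.index)
    background_n = config.background_n or len(tested_genes)
    alpha = config.alpha
    log.info("testing %d genes (%d all-zero dropped), alpha=%g", len(tested_genes), n_dropped, alpha)

    f_mr = size_factors_median_ratio(matrix)
    f_tmm = size_factors_tmm(matrix)
    groups = list(matrix.condition_groups().values())
    disp_mr = estimate_dispersions(matrix, f_mr, groups)
    disp_tmm = estimate_dispersions(matrix, f_tmm, groups)

    # QC on the variance-stabilized matrix
    rld = regularized_log(matrix, f_mr)
    scores, _, var_exp = pca(rld, n_components=2)
    dist = sample_distances(rld)
    tables: dict[str, pd.DataFrame] = {
        "qc_pca_scores": scores,
        "qc_sample_distances": dist,
        "size_factors": pd.DataFrame(
            {"median_ratio": f_mr.factors, "tmm": f_tmm.factors}
        ),
    }

    contrast_counts: dict[str, dict[str, int]] = {}
    call_sets: dict[str, ContrastCallSet] = {}
    for diet in DIETS:
        calls = {}
        for key in TEMP_CONTRAST_KEYS:
            hi, lo = _TEMP_PAIRS[key]
            contrast = Contrast.between(matrix, (diet, hi), (diet, lo))
            t_wald, t_exact, (up, down) = _contrast_tables(
                matrix, contrast, f_mr, f_tmm, disp_mr, disp_tmm, alpha
            )
            name = f"{diet}_{key}"
            tables[f"de_wald_{name}"] = t_wald
            tables[f"de_exact_{name}"] = t_exact
            tables[f"consensus_{name}"] = pd.DataFrame(
                {"direction": ["up"] * len(up) + ["down"] * len(down)},
                index=pd.Index(sorted(up) + sorted(down), name="gene"),
            )
            calls[key] = (up, down)
            contrast_counts[name] = {
                "wald_up": int((t_wald["call"] == "up").sum()),
                "wald_down": int((t_wald["call"] == "down").sum()),
                "exact_up": int((t_exact["call"] == "up").sum()),
                "exact_down": int((t_exact["call"] == "down").sum()),
                "consensus_up": len(up),
                "consensus_down": len(down),
            }
        call_sets[diet] = ContrastCallSet(diet=diet, calls=calls)

    diet_calls: dict[int, tuple[set[str], set[str]]] = {}
    for temp in TEMPERATURES:
        contrast = Contrast.between(matrix, ("ecoli", temp), ("bsubtilis", temp))
        t_wald, t_exact, (up, down) = _contrast_tables(
            matrix, contrast, f_mr, f_tmm, disp_mr, disp_tmm, alpha
        )
        name = f"diet_{temp}"
        tables[f"de_wald_{name}"] = t_wald
        tables[f"de_exact_{name}"] = t_exact
        tables[f"consensus_{name}"] = pd.DataFrame(
            {"direction": ["up"] * len(up) + ["down"] * len(down)},
            index=pd.Index(sorted(up) + sorted(down), name="gene"),
        )
        diet_calls[temp] = (up, down)
        contrast_counts[name] = {
            "wald_up": int((t_wald["call"] == "up").sum()),
            "wald_down": int((t_wald["call"] == "down").sum()),
            "exact_up": int((t_exact["call"] == "up").sum()),
            "exact_down": int((t_exact["call"] == "down").sum()),
            "consensus_up": len(up),
            "consensus_down": len(down),
        }

    classifications: dict[str, TemperatureClassification] = {
        diet: classify_temperature_response(call_sets[diet]) for diet in DIETS
    }
    class_rows = []
    for diet, cls in classifications.items():
        for gene in sorted(cls.labels):
            class_rows.append(
                {
                    "gene": gene,
                    "diet": diet,
                    "label": cls.labels[gene],
                    "up_25v15": gene in call_sets[diet].up("25v15"),
                    "down_25v15": gene in call_sets[diet].down("25v15"),
                    "up_25v20": gene in call_sets[diet].up("25v20"),
                    "down_25v20": gene in call_sets[diet].down("25v20"),
                    "sig_20v15": gene in call_sets[diet].significant("20v15"),
                }
            )
    tables["temperature_classes"] = pd.DataFrame(
        class_rows, columns=["gene", "diet", "label", "up_25v15", "down_25v15",
                             "up_25v20", "down_25v20", "sig_20v15"]
    ).set_index("gene")

    diet_labels = classify_diet_response(diet_calls)
    tables["diet_classes"] = diet_labels.to_frame()
    tables["diet_classes"].index.name = "gene"

    overlap_rows = []
    common_sets: dict[str, list[str]] = {}
    for label in ("exclusively_hot", "false_hot", "exclusively_cold", "false_cold"):
        common, n1, n2 = (
            classifications["ecoli"].genes(label) & classifications["bsubtilis"].genes(label),
            len(classifications["ecoli"].genes(label)),
            len(classifications["bsubtilis"].genes(label)),
        )
        overlap_rows.append(_overlap_row(label, common, n1, n2, background_n))
        common_sets[label] = sorted(common)
    tables["cross_diet_overlaps"] = pd.DataFrame(overlap_rows).set_index("label")

    enrichment_hits: dict[str, int] = {}
    if config.gene_sets is not None:
        collection = read_gmt(config.gene_sets)
        query_sets: dict[str, set[str]] = {}
        for diet, cls in classifications.items():
            for label in ("exclusively_hot", "false_hot", "exclusively_cold", "false_cold"):
                genes = cls.genes(label)
                if genes:
                    query_sets[f"{diet}_{label}"] = genes
        for lab in ("ecoli_up", "bsubtilis_up"):
            genes = set(diet_labels.index[diet_labels == lab])
            if genes:
                query_sets[f"diet_{lab}"] = genes
        for qname, genes in query_sets.items():
            enr = overrepresentation_test(
                genes & tested_genes, collection, tested_genes,
                min_term=config.min_term, max_term=config.max_term,
            )
            tables[f"enrichment_{qname}"] = enr
            bars = pd.DataFrame(
                {"neg_log10_q": -np.log10(np.maximum(enr["q"], 1e-300)), "k": enr["k"]}
            )
            bars.to_csv(outdir / f"enrichment_{qname}_bars.tsv", sep="\t", float_format="%.6g")
            enrichment_hits[qname] = int((enr["q"] < alpha).sum())

    summary: dict[str, Any] = {
        "version": _VERSION,
        "seed": config.seed,
        "alpha": alpha,
        "background_n": background_n,
        "n_genes_tested": len(tested_genes),
        "n_genes_dropped_all_zero": n_dropped,
        "pca_variance_explained": [round(float(v), 6) for v in var_exp],
        "contrasts": contrast_counts,
        "temperature_classes": {d: classifications[d].counts() for d in DIETS},
        "temperature_class_candidates": {
            d: {
                "both_hot": len(classifications[d].both_hot_candidates),
                "both_cold": len(classifications[d].both_cold_candidates),
            }
            for d in DIETS
        },
        "diet_classes": {
            "ecoli_up": int((diet_labels == "ecoli_up").sum()),
            "bsubtilis_up": int((diet_labels == "bsubtilis_up").sum()),
        },
        "cross_diet_overlaps": overlap_rows,
        "cross_diet_common_genes": common_sets,
        "enrichment_significant_terms": enrichment_hits,
        "deviations": list(DEVIATIONS),
        "config": {
            "counts": config.counts,
            "sample_sheet": config.sample_sheet,
            "gene_sets": config.gene_sets,
            "simulated": config.simulation is not None,
            "min_term": config.min_term,
            "max_term": config.max_term,
        },
    }
    if truth is not None:
        summary["planted_class_counts"] = {
            lab: int((truth.labels == lab).sum()) for lab in sorted(truth.labels.unique())
        }
    write_results(tables, outdir, summary=summary)
    log.info("wrote %d tables and run_summary.json to %s", len(tables), outdir)
    return summary
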