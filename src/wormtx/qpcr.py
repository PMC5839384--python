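"""Relative quantification of RT-qPCR data and cross-platform concordance.

Implements the standard comparative-Ct (2^-ddCt) method: target-gene Ct
values are normalized to a reference gene (here typically the actin *act-1*)
within each condition, and the condition-vs-control difference of those
differences gives the fold change on the linear scale.  A small concordance
report compares the qPCR fold changes with RNA-seq log2 fold changes for
the same genes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["ddct_fold_change", "compare_platforms", "ddct_from_table"]


def ddct_fold_change(
    ct_target_cond: float,
    ct_refgene_cond: float,
    ct_target_ctrl: float,
    ct_refgene_ctrl: float,
) -> float:
    """Fold change 2^-ddCt of the target gene in condition vs control.

    ddCt = (Ct_target,cond - Ct_ref,cond) - (Ct_target,ctrl - Ct_ref,ctrl).
    Lower Ct means more template, hence the negated exponent.  Invariant
    under adding any constant to all four Ct values.
    """
    cts = (ct_target_cond, ct_refgene_cond, ct_target_ctrl, ct_refgene_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError(f"non-finite Ct value in {cts}")
    ddct = (ct_target_cond - ct_refgene_cond) - (ct_target_ctrl - ct_refgene_ctrl)
    return 2.0**-ddct


def ddct_from_table(
    ct: pd.DataFrame,
    target: str,
    reference_gene: str,
    condition: str,
    control: str,
) -> float:
    """2^-ddCt from a long-format Ct table (gene, condition, replicate, ct).

    Replicate Ct values are arithmetically averaged per (gene, condition)
    before the differences are taken.
    """
    for col in ("gene", "condition", "ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")

    def mean_ct(gene, cond):
        sel = ct[(ct["gene"] == gene) & (ct["condition"] == cond)]["ct"]
        if sel.empty:
            raise ValueError(f"no Ct values for gene {gene!r} in condition {cond!r}")
        return float(sel.mean())

    return ddct_fold_change(
        mean_ct(target, condition),
        mean_ct(reference_gene, condition),
        mean_ct(target, control),
        mean_ct(reference_gene, control),
    )


def compare_platforms(fold_qpcr, log2fc_rnaseq, labels=None) -> pd.DataFrame:
    """Concordance of qPCR fold changes (linear) with RNA-seq log2 fold changes.

    Returns one row per paired measurement with the qPCR value on the log2
    scale, a sign-agreement flag and the log2 magnitude gap, plus a
    ``fraction_concordant`` attribute in ``DataFrame.attrs``.
    """
    fold_qpcr = np.asarray(fold_qpcr, dtype=float)
    log2fc_rnaseq = np.asarray(log2fc_rnaseq, dtype=float)
    if fold_qpcr.shape != log2fc_rnaseq.shape:
        raise ValueError(
            f"length mismatch: {fold_qpcr.shape} qPCR vs {log2fc_rnaseq.shape} RNA-seq values"
        )
    if (fold_qpcr <= 0).any():
        raise ValueError("qPCR fold changes must be positive (linear scale)")
    log2_qpcr = np.log2(fold_qpcr)
    concordant = np.sign(log2_qpcr) == np.sign(log2fc_rnaseq)
    out = pd.DataFrame(
        {
            "log2_qpcr": log2_qpcr,
            "log2fc_rnaseq": log2fc_rnaseq,
            "concordant": concordant,
            "log2_gap": np.abs(log2_qpcr - log2fc_rnaseq),
        },
        index=labels if labels is not None else pd.RangeIndex(len(log2_qpcr)),
    )
    out.attrs["fraction_concordant"] = float(concordant.mean()) if len(concordant) else float("nan")
    return out
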