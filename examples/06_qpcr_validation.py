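"""Relative quantification by the comparative-Ct method, and platform concordance.

A gene measured at Ct 24 (vs reference *act-1* at 18) in the hot condition and
Ct 25.5 (reference 18.5) in the control has ddCt = -1, i.e. a twofold
up-regulation; the concordance report compares such qPCR fold changes with
RNA-seq log2 fold changes for the same genes.
"""

from wormtx.qpcr import compare_platforms, ddct_fold_change

fold = ddct_fold_change(ct_target_cond=24.0, ct_refgene_cond=18.0,
                        ct_target_ctrl=25.5, ct_refgene_ctrl=18.5)
print(f"2^-ddCt fold change: {fold:.2f}x")

qpcr_folds = [fold, 4.2, 0.3]
rnaseq_log2fc = [0.9, 2.1, -1.8]
report = compare_platforms(qpcr_folds, rnaseq_log2fc, labels=["nex-1", "T05E11.9", "D2045.2"])
print("\nqPCR vs RNA-seq concordance:")
print(report.round(2).to_string())
print(f"fraction concordant: {report.attrs['fraction_concordant']:.0%}")
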