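"""Depth normalization, variance-stabilizing transform, PCA and sample-distance QC.

Two size-factor estimators are provided, one per differential-expression
engine: the median-of-ratios estimator (each sample's median ratio to the
per-gene geometric mean, the DESeq2 convention) and the trimmed mean of
M-values (TMM, the edgeR convention, renormalized to geometric mean 1).

The variance-stabilizing transform is ``log2(normalized + pseudocount)`` — a
monotone stand-in for a regularized log transform, sufficient for the
qualitative QC questions asked of it (do samples cluster by diet?).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import CountMatrix

__all__ = [
    "SizeFactors",
    "size_factors_median_ratio",
    "size_factors_tmm",
    "normalize",
    "regularized_log",
    "pca",
    "sample_distances",
]


@dataclass
class SizeFactors:
    """Per-sample positive depth scale factors plus the estimator tag."""

    factors: pd.Series
    method: str

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValueError("all size factors must be positive")
        if self.method not in ("median_ratio", "tmm"):
            raise ValueError(f"unknown size-factor method {self.method!r}")


def size_factors_median_ratio(matrix: CountMatrix) -> SizeFactors:
    """Median-of-ratios estimator.

    For each sample, the factor is the median over genes of
    ``count / geometric-mean-across-samples``, computed over genes with a
    nonzero count in every sample.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    eligible = (counts > 0).all(axis=1)
    if not eligible.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = counts[eligible]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo)
    factors = np.median(ratios, axis=0)
    return SizeFactors(
        factors=pd.Series(factors, index=matrix.counts.columns, name="size_factor"),
        method="median_ratio",
    )


def _uq(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    # 75th percentile of nonzero-inclusive scaled counts, per sample
    return np.percentile(counts / lib, 75, axis=0)


def size_factors_tmm(
    matrix: CountMatrix,
    reference_sample: str | None = None,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    include_library_size: bool = True,
) -> SizeFactors:
    """Trimmed mean of M-values.

    M (log2 expression ratio vs the reference sample) and A (average log2
    abundance) are computed on library-size-scaled counts over genes nonzero
    in both samples; the upper and lower ``logratio_trim`` fraction of M and
    ``abs_trim`` fraction of A are discarded and the rest averaged with
    inverse asymptotic-variance weights.  Factors are renormalized to
    geometric mean 1.  The reference defaults to the sample whose
    upper-quartile expression is closest to the mean upper quartile.

    With ``include_library_size=True`` (default) the returned factors are
    effective depth factors — library size times the compositional TMM
    component — directly usable to divide counts.  With ``False`` only the
    compositional component is returned (the classical TMM "norm factor":
    a pure depth change between samples then yields factors of 1, because
    depth is carried by library size, not by TMM).
    """
    counts = matrix.counts.to_numpy(dtype=float)
    samples = list(matrix.counts.columns)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    if reference_sample is None:
        uq = _uq(counts, lib)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = samples.index(reference_sample)

    factors = np.ones(len(samples))
    ref = counts[:, ref_idx]
    for j in range(len(samples)):
        if j == ref_idx:
            continue
        obs = counts[:, j]
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            raise ValueError(
                f"sample {samples[j]!r} shares no co-expressed genes with the reference"
            )
        y, r = obs[keep], ref[keep]
        p_y, p_r = y / lib[j], r / lib[ref_idx]
        m = np.log2(p_y / p_r)
        a = 0.5 * np.log2(p_y * p_r)
        w = (lib[j] - y) / (lib[j] * y) + (lib[ref_idx] - r) / (lib[ref_idx] * r)
        n = len(m)
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep2.any() and np.isfinite(w[keep2]).all():
            f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
        else:
            f = 0.0
        factors[j] = 2.0**f
    if include_library_size:
        factors = factors * lib / np.exp(np.mean(np.log(lib)))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return SizeFactors(
        factors=pd.Series(factors, index=matrix.counts.columns, name="size_factor"),
        method="tmm",
    )


def normalize(matrix: CountMatrix, factors: SizeFactors) -> pd.DataFrame:
    """Counts divided by their sample's size factor."""
    if list(factors.factors.index) != list(matrix.counts.columns):
        raise ValueError("size factors do not match the matrix samples")
    return matrix.counts / factors.factors


def regularized_log(matrix: CountMatrix, factors: SizeFactors, pseudocount: float = 1.0) -> pd.DataFrame:
    """``log2(normalized count + pseudocount)`` — monotone variance-stabilizer."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log2(normalize(matrix, factors) + pseudocount)


def pca(values: pd.DataFrame, n_components: int = 2):
    """PCA of samples over genes via SVD of the column-centered data.

    ``values`` is genes x samples (e.g. the regularized-log matrix); samples
    are the observations.  Returns ``(scores, loadings, variance_explained)``
    where scores is samples x components and variance_explained fractions of
    total variance (non-increasing, summing to <= 1).
    """
    x = values.to_numpy(dtype=float).T  # samples x genes
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min(samples, genes)={min(n, p)}")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = np.sum(s**2)
    var_exp = (s**2 / total) if total > 0 else np.zeros_like(s)
    scores = pd.DataFrame(
        (u * s)[:, :n_components],
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    loadings = pd.DataFrame(
        vt[:n_components].T,
        index=values.index,
        columns=scores.columns,
    )
    return scores, loadings, var_exp[:n_components]


def sample_distances(values: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances between sample columns (symmetric, zero diagonal)."""
    d = squareform(pdist(values.to_numpy(dtype=float).T, metric="euclidean"))
    return pd.DataFrame(d, index=values.columns, columns=values.columns)
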