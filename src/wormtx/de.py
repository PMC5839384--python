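"""Two negative-binomial differential-expression engines, BH correction and consensus.

Each two-group contrast is tested twice, by estimators in the style of the
two standard bulk RNA-seq packages:

* ``wald_test`` — a DESeq2-style Wald test: moderated log2 fold change of
  group means of normalized counts, delta-method standard error under the
  NB variance ``mu + alpha * mu**2``, two-sided normal p-value.
* ``exact_test_nb`` — an edgeR-style conditional exact test: counts are
  rescaled to a common library size ("pseudo-counts"), per-group sums are
  NB with equalized means, and the two-sided p-value sums the conditional
  probabilities of all splits at most as likely as the observed one.

Genes significant in the same direction by BOTH engines at BH-adjusted
p < alpha form the consensus sets that all downstream classification uses —
the intersection rule that guards against single-method false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .io import CountMatrix
from .normalization import SizeFactors, normalize

__all__ = [
    "Contrast",
    "DispersionEstimates",
    "estimate_dispersions",
    "wald_test",
    "exact_test_nb",
    "bh_adjust",
    "consensus",
    "DE_COLUMNS",
]

DE_COLUMNS = ["base_mean", "log2fc", "se", "stat", "p", "padj", "call"]

#: moderation constant (normalized counts) added to group means before the
#: log-ratio, so genes with zeros get finite fold changes
LFC_MODERATION = 0.5

#: floor on the final per-gene dispersion
MIN_DISPERSION = 1e-8


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; ``condition_a`` is the numerator of the fold change."""

    condition_a: tuple[str, int]
    condition_b: tuple[str, int]
    samples_a: tuple[str, ...]
    samples_b: tuple[str, ...]

    def __post_init__(self):
        if not self.samples_a or not self.samples_b:
            raise ValueError("both contrast groups must be non-empty")
        if set(self.samples_a) & set(self.samples_b):
            raise ValueError("contrast groups must be disjoint")

    @classmethod
    def between(cls, matrix: CountMatrix, condition_a, condition_b) -> "Contrast":
        groups = matrix.condition_groups()
        ca = (condition_a[0], int(condition_a[1]))
        cb = (condition_b[0], int(condition_b[1]))
        for c in (ca, cb):
            if c not in groups:
                raise ValueError(f"no samples for condition {c}")
        return cls(ca, cb, tuple(groups[ca]), tuple(groups[cb]))

    @property
    def name(self) -> str:
        def tag(c):
            return f"{c[0]}{c[1]}"

        return f"{tag(self.condition_a)}_vs_{tag(self.condition_b)}"


@dataclass
class DispersionEstimates:
    """Per-gene NB dispersions: raw moment estimates, trend fit, shrunk finals.

    The trend is ``alpha_tr(mu) = a0 + a1 / mu`` (non-increasing in the mean
    for non-negative coefficients); finals shrink the raw estimate halfway
    toward the trend and are floored at ``MIN_DISPERSION``.
    """

    raw: pd.Series
    a0: float
    a1: float
    final: pd.Series

    def trend(self, mu):
        return self.a0 + self.a1 / np.asarray(mu, dtype=float)


def estimate_dispersions(
    matrix: CountMatrix,
    factors: SizeFactors,
    groups: list[list[str]],
    shrinkage_weight: float = 0.5,
) -> DispersionEstimates:
    """Method-of-moments dispersion per gene, trend fit, and shrinkage.

    The raw estimate is ``max(0, (pooled within-group variance - mu) / mu**2)``
    on normalized counts (replicates within a condition are the units); the
    trend coefficients come from least squares of the raw estimates on
    ``1/mu`` over genes with positive estimates, clipped at zero.  The fit
    is iteratively reweighted (weights 1 / fitted-trend^2, i.e. relative
    error), because the sampling noise of moment dispersion estimates scales
    with their magnitude and an unweighted fit is dominated by the few
    low-expression genes with the largest, noisiest estimates.
    """
    norm_counts = normalize(matrix, factors)
    n_rep = [len(g) for g in groups]
    if all(n <= 1 for n in n_rep):
        raise ValueError("dispersion estimation needs >= 2 replicates in some group")

    x = norm_counts.to_numpy(dtype=float)
    cols = list(norm_counts.columns)
    ss = np.zeros(x.shape[0])
    s_mu = np.zeros(x.shape[0])
    s_mu2 = np.zeros(x.shape[0])
    dof = 0
    for g in groups:
        idx = [cols.index(s) for s in g]
        if len(idx) < 2:
            continue
        sub = x[:, idx]
        w = len(idx) - 1
        gm = sub.mean(axis=1)
        gv = sub.var(axis=1, ddof=1)
        ss += gv * w
        s_mu += gm * w
        # gm^2 - s^2/n is unbiased for mu_g^2 (the square of a noisy mean
        # overstates it by its own sampling variance); capped at gm^2/2 so a
        # noisy variance cannot zero the denominator
        s_mu2 += np.maximum(gm**2 - gv / len(idx), 0.5 * gm**2) * w
        dof += w
    pooled_var = ss / dof
    mu = s_mu / dof
    mu2 = s_mu2 / dof  # mean squared group mean: the NB quadratic term
    if not (pooled_var > 0).any():
        raise ValueError("no gene with positive within-group variance")

    # moment match per group: E[s2_g] = mu_g + alpha * mu_g^2, pooled with
    # the same weights, hence alpha = (pooled_var - mean mu_g) / mean mu_g^2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu2 > 0, (pooled_var - mu) / mu2, 0.0)
    raw = np.clip(raw, 0.0, None)

    fit_mask = (raw > 0) & (mu > 0)
    if fit_mask.sum() >= 2:
        y = raw[fit_mask]
        design = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu[fit_mask]])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        for _ in range(20):  # IRLS, relative-error weights
            pred = np.maximum(design @ np.clip(coef, 0.0, None), MIN_DISPERSION)
            w = 1.0 / pred
            new_coef, *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
            if np.allclose(new_coef, coef, rtol=1e-6):
                coef = new_coef
                break
            coef = new_coef
        a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
    else:
        a0, a1 = 0.0, 0.0

    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / mu, a0)
    final = np.maximum((1 - shrinkage_weight) * raw + shrinkage_weight * trend, MIN_DISPERSION)
    genes = norm_counts.index
    return DispersionEstimates(
        raw=pd.Series(raw, index=genes, name="raw"),
        a0=a0,
        a1=a1,
        final=pd.Series(final, index=genes, name="final"),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _finalize(genes, base_mean, lfc, se, stat, p, alpha: float) -> pd.DataFrame:
    padj = bh_adjust(p)
    call = np.where(
        (padj < alpha) & (lfc > 0), "up", np.where((padj < alpha) & (lfc < 0), "down", "ns")
    )
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": lfc,
            "se": se,
            "stat": stat,
            "p": p,
            "padj": padj,
            "call": call,
        },
        index=pd.Index(genes, name="gene"),
    )


def wald_test(
    matrix: CountMatrix,
    factors: SizeFactors,
    contrast: Contrast,
    dispersions: DispersionEstimates,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """DESeq2-style two-group NB Wald test.

    log2fc = log2((m_a + c)/(m_b + c)) on group means of normalized counts
    with moderation ``c = LFC_MODERATION``; Var(ln m_g) is approximated by
    the delta method as ``(1/n_g) * (1/(m_g + c) + alpha_gene)``; the Wald
    statistic log2fc/se is referred to a standard normal, two-sided.
    """
    norm_counts = normalize(matrix, factors)
    a = norm_counts.loc[:, list(contrast.samples_a)].to_numpy(dtype=float)
    b = norm_counts.loc[:, list(contrast.samples_b)].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    alpha_g = dispersions.final.reindex(norm_counts.index).to_numpy()
    c = LFC_MODERATION
    lfc = np.log2((m_a + c) / (m_b + c))
    var_ln = (1.0 / n_a) * (1.0 / (m_a + c) + alpha_g) + (1.0 / n_b) * (1.0 / (m_b + c) + alpha_g)
    se = np.sqrt(var_ln) / np.log(2.0)
    stat = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * norm.sf(np.abs(stat))
    p = np.minimum(p, 1.0)
    base_mean = np.concatenate([a, b], axis=1).mean(axis=1)
    return _finalize(norm_counts.index, base_mean, lfc, se, stat, p, alpha)


def _nb_logpmf(x: np.ndarray, mean: float, alpha: float, logfact: np.ndarray) -> np.ndarray:
    """log NB(x; mean, dispersion) with var = mean + alpha*mean^2; Poisson at alpha=0."""
    if mean <= 0:
        out = np.full(x.shape, -np.inf)
        out[x == 0] = 0.0
        return out
    if alpha <= 0:
        return x * np.log(mean) - mean - logfact[x]
    r = 1.0 / alpha
    logp = np.log(mean) - np.log(r + mean)
    log1mp = np.log(r) - np.log(r + mean)
    return gammaln(x + r) - gammaln(r) - logfact[x] + r * log1mp + x * logp


def exact_test_nb(
    matrix: CountMatrix,
    factors: SizeFactors,
    contrast: Contrast,
    dispersions: DispersionEstimates,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """edgeR-style conditional NB exact test for a two-group contrast.

    Counts are rescaled to the common (geometric-mean) library size by the
    size factors and rounded to pseudo-counts.  For each gene, conditional
    on the total ``t = y_a + y_b``, the group-a sum under the null is NB
    with mean ``n_a * t / (n_a + n_b)`` and dispersion ``alpha_gene / n_a``
    (likewise for b); the two-sided p-value sums P(split | t) over all
    splits no more probable than the observed one.  Genes with ``t = 0``
    get p = 1 and log2fc = 0 by convention.
    """
    if list(factors.factors.index) != list(matrix.counts.columns):
        raise ValueError("size factors do not match the matrix samples")
    pseudo = np.round(matrix.counts.to_numpy(dtype=float) / factors.factors.to_numpy()).astype(
        np.int64
    )
    cols = list(matrix.counts.columns)
    ia = [cols.index(s) for s in contrast.samples_a]
    ib = [cols.index(s) for s in contrast.samples_b]
    y_a = pseudo[:, ia].sum(axis=1)
    y_b = pseudo[:, ib].sum(axis=1)
    n_a, n_b = len(ia), len(ib)
    alpha_g = dispersions.final.reindex(matrix.counts.index).to_numpy()

    t_all = y_a + y_b
    max_t = int(t_all.max(initial=0))
    logfact = gammaln(np.arange(max_t + 1, dtype=float) + 1.0)  # logfact[x] = log(x!)

    p_out = np.ones(len(t_all))
    for i in np.nonzero(t_all > 0)[0]:
        t = int(t_all[i])
        mu = t / (n_a + n_b)
        xs = np.arange(t + 1)
        la = _nb_logpmf(xs, n_a * mu, alpha_g[i] / n_a, logfact)
        lb = _nb_logpmf(xs[::-1], n_b * mu, alpha_g[i] / n_b, logfact)
        joint = la + lb
        joint -= logsumexp(joint)
        obs = joint[int(y_a[i])]
        # tolerance absorbs float ties (e.g. the symmetric split)
        p = float(np.exp(logsumexp(joint[joint <= obs + 1e-10])))
        p_out[i] = min(p, 1.0)

    c = LFC_MODERATION
    m_a, m_b = y_a / n_a, y_b / n_b
    lfc = np.where(t_all > 0, np.log2((m_a + c) / (m_b + c)), 0.0)
    base_mean = (y_a + y_b) / (n_a + n_b)
    se = np.full(len(t_all), np.nan)
    stat = np.full(len(t_all), np.nan)
    return _finalize(matrix.counts.index, base_mean, lfc, se, stat, p_out, alpha)


def consensus(
    table_a: pd.DataFrame, table_b: pd.DataFrame, alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Genes called significant in the same direction by both engines.

    Returns ``(up_set, down_set)``; a gene up in one table and down in the
    other is discordant and excluded from both.  The two tables must cover
    the same gene universe.
    """
    if set(table_a.index) != set(table_b.index):
        raise ValueError("DE tables cover different gene universes")

    def sets(tab):
        sig = tab["padj"] < alpha
        up = set(tab.index[sig & (tab["log2fc"] > 0)])
        down = set(tab.index[sig & (tab["log2fc"] < 0)])
        return up, down

    up_a, down_a = sets(table_a)
    up_b, down_b = sets(table_b)
    return up_a & up_b, down_a & down_b
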