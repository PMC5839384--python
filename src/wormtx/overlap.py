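"""Gene-list overlap statistics: representation factor and hypergeometric tails.

The representation factor (RF) quantifies how much two gene lists drawn from a
common background of ``N`` genes overlap relative to chance::

    RF = k * N / (n1 * n2)

where ``k`` is the observed overlap and ``n1``, ``n2`` the list sizes.  RF > 1
means more overlap than expected for independent lists, RF < 1 less, RF = 1
exactly the independent expectation.  Significance is attached with the
hypergeometric upper tail P(X >= k), evaluated in log space so that the
extremely small p-values typical of transcriptome-scale overlaps (down to
~1e-300) neither under- nor overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "OverlapStat",
    "representation_factor",
    "hypergeom_overlap_pvalue",
    "infer_background",
]


def _check_domain(k: int, n1: int, n2: int, N: int) -> None:
    if not (0 <= k <= min(n1, n2)):
        raise ValueError(f"overlap k={k} must lie in [0, min(n1, n2)] = [0, {min(n1, n2)}]")
    if n1 > N or n2 > N:
        raise ValueError(f"set sizes (n1={n1}, n2={n2}) cannot exceed the background N={N}")
    if N <= 0:
        raise ValueError("background N must be positive")


def representation_factor(k: int, n1: int, n2: int, N: int) -> float:
    """Observed overlap divided by the overlap expected for independent sets.

    Parameters
    ----------
    k : overlap count between the two gene sets.
    n1, n2 : sizes of the two sets (must be positive).
    N : size of the common background universe.

    Returns
    -------
    float
        ``k * N / (n1 * n2)``; 0 when the sets are disjoint.
    """
    _check_domain(k, n1, n2, N)
    if n1 <= 0 or n2 <= 0:
        raise ValueError("set sizes must be positive for a representation factor")
    return k * N / (n1 * n2)


def _log_hypergeom_pmf(x: np.ndarray, N: int, n1: int, n2: int) -> np.ndarray:
    # log C(n1, x) + log C(N-n1, n2-x) - log C(N, n2), via log-gamma
    x = np.asarray(x, dtype=float)

    def logC(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    return logC(n1, x) + logC(N - n1, n2 - x) - logC(N, n2)


def hypergeom_overlap_pvalue(
    k: int, n1: int, n2: int, N: int, *, return_log10: bool = False
) -> float | tuple[float, float]:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, n1, n2).

    This is the chance that two independent sets of sizes ``n1`` and ``n2``
    drawn from ``N`` genes share at least ``k`` members.  Evaluated by
    summing the log-scale mass function with ``logsumexp``, so values down
    to ~1e-300 are returned accurately; ``return_log10=True`` additionally
    returns log10(p), which stays finite even when p itself underflows.
    """
    _check_domain(k, n1, n2, N)
    lo = max(0, n1 + n2 - N)
    hi = min(n1, n2)
    if k <= lo:
        p, log10p = 1.0, 0.0
    else:
        xs = np.arange(k, hi + 1)
        logp = float(logsumexp(_log_hypergeom_pmf(xs, N, n1, n2)))
        logp = min(logp, 0.0)
        p = float(np.exp(logp))
        log10p = logp / math.log(10.0)
    if return_log10:
        return p, log10p
    return p


@dataclass(frozen=True)
class OverlapStat:
    """Overlap of two gene sets against a background universe.

    Attributes
    ----------
    k : overlap count
    n1, n2 : set sizes
    N : background universe size
    rf : representation factor, ``k * N / (n1 * n2)``
    p : hypergeometric upper-tail probability P(X >= k)
    log10_p : base-10 log of ``p`` (finite even when ``p`` underflows)
    """

    k: int
    n1: int
    n2: int
    N: int
    rf: float
    p: float
    log10_p: float

    @classmethod
    def from_counts(cls, k: int, n1: int, n2: int, N: int) -> "OverlapStat":
        rf = representation_factor(k, n1, n2, N)
        p, log10p = hypergeom_overlap_pvalue(k, n1, n2, N, return_log10=True)
        return cls(k=k, n1=n1, n2=n2, N=N, rf=rf, p=p, log10_p=log10p)

    @classmethod
    def from_sets(cls, a, b, N: int) -> "OverlapStat":
        a, b = set(a), set(b)
        return cls.from_counts(len(a & b), len(a), len(b), N)


def infer_background(k: int, n1: int, n2: int, rf_target: float) -> tuple[float, tuple[int, int]]:
    """Invert the RF formula: which background N yields a given (rounded) RF?

    Returns the exact real solution ``N = rf_target * n1 * n2 / k`` together
    with the closed integer interval of N values whose RF, rounded to one
    decimal, equals ``rf_target``.  Useful for auditing published RF values
    when the background size is not reported.
    """
    if k <= 0:
        raise ValueError("cannot invert an RF with zero overlap")
    if rf_target <= 0:
        raise ValueError("rf_target must be positive")
    exact = rf_target * n1 * n2 / k
    # RF rounds to rf_target (1 decimal) iff RF in [rf_target-0.05, rf_target+0.05)
    lo_real = (rf_target - 0.05) * n1 * n2 / k
    hi_real = (rf_target + 0.05) * n1 * n2 / k
    lo = math.ceil(lo_real)
    hi = math.ceil(hi_real) - 1
    # guard against float edge effects at the interval ends
    while round(lo * k / (n1 * n2), 1) != round(rf_target, 1) and lo <= hi:
        lo += 1
    while round(hi * k / (n1 * n2), 1) != round(rf_target, 1) and hi >= lo:
        hi -= 1
    return exact, (lo, hi)
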