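"""Exact small-sample statistics shared across the toolkit.

Recombinant counts in this setting are small (tens of events out of a few
hundred informative meioses), so all interval estimation is exact binomial
(Clopper–Pearson) rather than normal-approximate, and 2x2 comparisons use
Fisher's exact test. Both are conservative by construction, which is the
behaviour wanted when the downstream use is forensic weight-of-evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BinomialCi",
    "clopper_pearson",
    "fisher_exact_2x2",
    "binomial_coverage_sim",
]


@dataclass(frozen=True)
class BinomialCi:
    """An exact binomial confidence interval for k successes in n trials.

    ``low`` and ``high`` are fractions in [0, 1]; they satisfy
    ``low <= k/n <= high`` whenever ``n > 0``, with ``low == 0`` at ``k == 0``
    and ``high == 1`` at ``k == n``.
    """

    k: int
    n: int
    alpha: float
    low: float
    high: float

    @property
    def point(self) -> float:
        return self.k / self.n if self.n > 0 else float("nan")


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> BinomialCi:
    """Exact (Clopper–Pearson) two-sided confidence interval for a proportion.

    The lower bound solves ``P(X >= k | p) = alpha/2`` and the upper bound
    ``P(X <= k | p) = alpha/2`` for a Binomial(n, p) variate X; the solutions
    are the standard beta-quantile expressions. Bounds at ``k == 0`` and
    ``k == n`` are pinned to 0 and 1 respectively.

    Parameters
    ----------
    k
        Number of successes, ``0 <= k <= n``.
    n
        Number of trials. ``n == 0`` yields an undefined (NaN) interval.
    alpha
        Two-sided error rate in (0, 1); 0.05 gives a 95% CI.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n < 0 or not 0 <= k <= max(n, 0):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        return BinomialCi(k=0, n=0, alpha=alpha, low=float("nan"), high=float("nan"))
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return BinomialCi(k=k, n=n, alpha=alpha, low=low, high=high)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Uses the probability-mass rule: the p-value sums the hypergeometric
    probabilities of every table with the same margins whose probability does
    not exceed that of the observed table. Degenerate tables with an empty
    margin return p = 1.
    """
    a, b = table[0]
    c, d = table[1]
    if min(a, b, c, d) < 0:
        raise ValueError("contingency table counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def binomial_coverage_sim(
    p_true: float,
    n: int,
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int = 0,
) -> float:
    """Empirical coverage of the Clopper–Pearson interval by simulation.

    Draws ``reps`` Binomial(n, p_true) counts and reports the fraction of
    replicates whose exact interval contains ``p_true``. Since only n+1
    distinct counts exist, intervals are computed once per observed count.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a meaningful coverage estimate")
    rng = np.random.default_rng(seed)
    ks = rng.binomial(n, p_true, size=reps)
    covered = 0
    cache: dict[int, BinomialCi] = {}
    for k in ks:
        ci = cache.get(int(k))
        if ci is None:
            ci = cache[int(k)] = clopper_pearson(int(k), n, alpha)
        if ci.low <= p_true <= ci.high:
            covered += 1
    return covered / reps
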