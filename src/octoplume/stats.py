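"""Hypothesis tests against perimeter-density null models.

The null model for station approaches is that crossing locations are uniform
per unit length of a region's external boundary, so the expected share of
approaches through a labeled boundary segment is its geometric length
fraction.  Counts of labeled approaches are tested against these geometric
ratios with a one-sided binomial test, and full count vectors against the
uniform-per-length density with a Pearson chi-squared test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

ALPHA = 0.05

#: significance cut-offs mapped to star labels, checked in order
_STAR_CUTOFFS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (0.05, "*"),
    (0.1, "."),
)


@dataclass
class TestResult:
    """Outcome of one null-model test."""

    test: str
    statistic: float
    p_value: float
    k: int | None = None
    n: int | None = None
    expected_ratios: tuple = ()
    counts: tuple = ()
    alpha: float = ALPHA
    stars: str = field(init=False)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")
        self.stars = significance_stars(self.p_value)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "k": self.k,
            "n": self.n,
            "expected_ratios": list(self.expected_ratios),
            "counts": list(self.counts),
            "alpha": self.alpha,
            "stars": self.stars,
        }


def binomial_one_sided(k: int, n: int, p0: float, alternative: str = "greater") -> float:
    """One-sided exact binomial tail probability.

    Computes ``P(X >= k)`` (or ``P(X <= k)`` for ``alternative='less'``) for
    ``X ~ Binomial(n, p0)``.  The sum runs over log-pmf terms combined with
    logsumexp, so extreme tails (e.g. 1e-16) keep full relative precision.

    Parameters
    ----------
    k : observed count, ``0 <= k <= n``.
    n : number of trials.
    p0 : null success probability, in (0, 1).
    alternative : 'greater' (default) or 'less'.
    """
    k = int(k)
    n = int(n)
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"need 0 < p0 < 1, got p0={p0}")
    if alternative == "greater":
        j = np.arange(k, n + 1)
    elif alternative == "less":
        j = np.arange(0, k + 1)
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    log_pmf = (
        gammaln(n + 1)
        - gammaln(j + 1)
        - gammaln(n - j + 1)
        + j * np.log(p0)
        + (n - j) * np.log1p(-p0)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def binomial_test_result(k: int, n: int, p0: float, alternative: str = "greater") -> TestResult:
    """`binomial_one_sided` wrapped into a :class:`TestResult`."""
    p = binomial_one_sided(k, n, p0, alternative=alternative)
    return TestResult(
        test="binomial_one_sided",
        statistic=float(k),
        p_value=p,
        k=k,
        n=n,
        expected_ratios=(p0,),
    )


def chisq_uniform(counts, segment_lengths) -> TestResult:
    """Pearson chi-squared test of counts against uniform-per-length density.

    Expected counts are ``total * length_share``; the statistic is
    ``sum((obs - exp)^2 / exp)`` on ``len(counts) - 1`` degrees of freedom.
    """
    obs = np.asarray(counts, dtype=float)
    lengths = np.asarray(segment_lengths, dtype=float)
    if obs.shape != lengths.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("need >= 2 aligned segments")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    if np.any(lengths <= 0):
        raise ValueError("segment lengths must be positive")
    ratios = lengths / lengths.sum()
    expected = obs.sum() * ratios
    if np.any(expected == 0):
        raise ValueError("zero expected count (no observations?)")
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = obs.size - 1
    p = float(chi2.sf(stat, df))
    return TestResult(
        test="chisq_uniform",
        statistic=stat,
        p_value=p,
        n=int(obs.sum()),
        expected_ratios=tuple(ratios),
        counts=tuple(int(c) for c in obs),
    )


def significance_stars(p: float) -> str:
    """Map a p-value to star notation ('.', '*' .. '****', or 'n.s.')."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of range: {p}")
    for cutoff, label in _STAR_CUTOFFS:
        if p < cutoff:
            return label
    return "n.s."
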