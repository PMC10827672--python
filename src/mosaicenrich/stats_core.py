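"""Exact and resampling statistics shared by all pipeline stages.

The central primitive is the two-sided Fisher exact test under the
minimum-likelihood rule: the p-value is the sum of hypergeometric point
probabilities, over all tables with the observed margins, that do not exceed
the observed table's point probability.  Small tables are evaluated in exact
integer arithmetic; large tables fall back to a log-space enumeration over
the smaller margin, which stays exact in practice because every table this
pipeline meets has one small margin (a cohort of a few hundred against a
population database).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "ContingencyTable2x2",
    "EmpiricalPValue",
    "MultipleTestingResult",
    "fisher_exact_two_sided",
    "hypergeometric_pmf",
    "empirical_p",
    "adjust_p",
    "cosine_similarity",
    "poisson_exact_power",
]

#: relative tolerance when deciding whether a point probability ties the
#: observed one (same convention as R's fisher.test)
TIE_REL_TOL = 1e-7

#: table sizes up to this total are evaluated with exact integer arithmetic
_EXACT_MAX_N = 2000


def _as_count(x, name: str) -> int:
    if isinstance(x, bool) or (not isinstance(x, (int, np.integer))):
        # accept exactly-integral floats, reject the rest
        if isinstance(x, float) and x.is_integer():
            x = int(x)
        else:
            raise InvalidInputError(f"{name} must be a non-negative integer, got {x!r}")
    x = int(x)
    if x < 0:
        raise InvalidInputError(f"{name} must be non-negative, got {x}")
    return x


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 contingency table.

    ``a``/``b`` are group-1 positives/negatives, ``c``/``d`` group-2
    positives/negatives.  All counts must be non-negative integers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            object.__setattr__(self, name, _as_count(getattr(self, name), name))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _coerce_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    flat = np.asarray(table).ravel().tolist()
    if len(flat) != 4:
        raise InvalidInputError("a 2x2 table requires exactly four counts")
    return ContingencyTable2x2(*flat)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact test p-value (minimum-likelihood rule).

    Parameters
    ----------
    table
        A :class:`ContingencyTable2x2` or any flat sequence of four
        non-negative integer counts ``(a, b, c, d)``.

    Returns
    -------
    float
        The sum of hypergeometric point probabilities over all tables with
        the observed margins whose point probability does not exceed the
        observed one (up to a relative tie tolerance of 1e-7), in ``(0, 1]``.
    """
    t = _coerce_table(table)
    a, b, c, d = t.a, t.b, t.c, t.d
    if t.n == 0:
        raise DegenerateInputError("all-zero table cannot be tested")

    # orient so that the enumerated margin (row 1 x col 1 support) is smallest
    if a + b > c + d:
        a, b, c, d = c, d, a, b
    if a + c > b + d:
        a, b, c, d = b, a, d, c

    r1, r2, c1 = a + b, c + d, a + c
    n_tot = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)

    if n_tot <= _EXACT_MAX_N:
        # exact integer path: point probability numerators share the
        # denominator C(n_tot, c1)
        num = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
        obs = num[a - lo]
        # keep k with num[k] <= obs * (1 + TIE_REL_TOL), in exact arithmetic
        scale = 10**9
        thresh = obs * (scale + int(TIE_REL_TOL * scale))
        total = sum(m for m in num if m * scale <= thresh)
        return float(Fraction(total, math.comb(n_tot, c1)))

    ks = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(ks, n_tot, c1, r1)
    log_obs = logp[a - lo]
    sel = logp <= log_obs + math.log1p(TIE_REL_TOL)
    return float(min(1.0, math.exp(logsumexp(logp[sel]))))


def hypergeometric_pmf(k: int, K: int, n: int, N: int) -> float:
    """Exact point probability of drawing ``k`` positives in ``n`` draws
    without replacement from ``N`` items of which ``K`` are positive.

    Computed in log space so that population sizes up to ~1e6 do not
    overflow.
    """
    k, K, n, N = (_as_count(v, s) for v, s in zip((k, K, n, N), "kKnN"))
    if K > N or n > N or k > min(K, n):
        raise InvalidInputError(
            f"impossible hypergeometric configuration k={k}, K={K}, n={n}, N={N}"
        )
    if k < max(0, K + n - N):
        return 0.0
    if max(0, K + n - N) == min(K, n):
        return 1.0  # a margin forces a single table
    return float(math.exp(stats.hypergeom.logpmf(k, N, K, n)))


@dataclass(frozen=True)
class EmpiricalPValue:
    """Empirical p-value from a permutation test.

    ``p`` is a deterministic function of the exceedance count ``r`` and the
    number of permutations ``n`` under the chosen convention.
    """

    exceedances: int
    permutations: int
    p: float

    def __float__(self) -> float:
        return self.p


def empirical_p(exceedances: int, permutations: int, *, pseudocount: bool = False) -> EmpiricalPValue:
    """Empirical permutation p-value.

    Default convention is ``max(r, 1) / n`` (resolution floor ``1/n``); the
    ``(r + 1) / (n + 1)`` pseudocount convention is selectable by flag.
    """
    r = _as_count(exceedances, "exceedances")
    n = _as_count(permutations, "permutations")
    if n < 1:
        raise InvalidInputError("permutations must be >= 1")
    if r > n:
        raise InvalidInputError("exceedances cannot exceed permutations")
    p = (r + 1) / (n + 1) if pseudocount else max(r, 1) / n
    return EmpiricalPValue(exceedances=r, permutations=n, p=p)


@dataclass(frozen=True)
class MultipleTestingResult:
    raw_p: tuple
    method: str
    adjusted_p: tuple
    n_tests: int


def adjust_p(raw_p: Sequence[float], method: str, n_tests: int | None = None) -> MultipleTestingResult:
    """Multiple-testing correction.

    ``bonferroni``: ``min(1, p * n_tests)``; ``n_tests`` may exceed the
    number of supplied p-values (tests whose p-values are not of interest).
    ``benjamini_hochberg``: standard step-up adjusted values over the
    supplied p-values.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        raise InvalidInputError("raw_p must be non-empty")
    if np.any(p <= 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        m = len(p) if n_tests is None else _as_count(n_tests, "n_tests")
        if m < len(p):
            raise InvalidInputError("n_tests cannot be smaller than the number of p-values")
        adj = np.minimum(1.0, p * m)
    elif method == "benjamini_hochberg":
        if n_tests is not None and n_tests != len(p):
            raise InvalidInputError("benjamini_hochberg adjusts exactly the supplied p-values")
        m = len(p)
        adj = stats.false_discovery_control(p, method="bh")
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    return MultipleTestingResult(
        raw_p=tuple(p.tolist()), method=method, adjusted_p=tuple(adj.tolist()), n_tests=m
    )


def cosine_similarity(u, v) -> float:
    """Cosine of the angle between two non-negative spectra; in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise InvalidInputError("vectors must be one-dimensional and of equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise InvalidInputError("spectra must be non-negative")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateInputError("cosine similarity undefined for a zero vector")
    return float(min(1.0, np.dot(u, v) / (nu * nv)))


def poisson_exact_power(expected_null: float, fold: float, alpha: float) -> float:
    """Power of a one-sided exact Poisson test for enrichment.

    Finds the smallest integer critical value ``k*`` whose upper-tail
    probability under ``Poisson(expected_null)`` is at most ``alpha``, and
    returns the upper-tail probability of ``k*`` under
    ``Poisson(expected_null * fold)``.
    """
    if not expected_null > 0:
        raise InvalidInputError("expected_null must be positive")
    if fold < 0:
        raise InvalidInputError("fold must be non-negative")
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must lie in (0, 1)")
    k = int(stats.poisson.ppf(1 - alpha, expected_null))
    # walk to the smallest k with P(X >= k) <= alpha  (sf(k-1) = P(X >= k))
    while k > 0 and stats.poisson.sf(k - 2, expected_null) <= alpha:
        k -= 1
    while stats.poisson.sf(k - 1, expected_null) > alpha:
        k += 1
    return float(stats.poisson.sf(k - 1, expected_null * fold))
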