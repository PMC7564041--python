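"""Exact hypergeometric probabilities and tail p-values.

The urn model underlying every rule significance computation: an urn holds
``a`` marbles of which ``b`` are "of interest"; drawing ``c`` marbles without
replacement, the number ``d`` of interest marbles among the draw follows the
hypergeometric distribution

    P(d, c; b, a) = C(b, d) * C(a - b, c - d) / C(a, c)

on the support max(0, c + b - a) <= d <= min(b, c).  A rule that condenses
``c`` samples, ``d`` of them of interest, is scored by the upper tail
p(d+) = sum_{i >= d} P(i, c; b, a) (enrichment) and the lower tail
p(d-) = sum_{i <= d} P(i, c; b, a) (depletion); the two are linked by
p(d-) + p((d+1)+) = 1 and by the duality
p(d-, c; b, a) = p([b-d]+, a-c; b, a).

Two code paths are provided: a float path based on log-gamma binomials
(summing the shorter tail and complementing the longer one to bound rounding)
and an exact rational path over ``fractions.Fraction`` for small urns.
``TailTable`` vectorizes tail lookups for a fixed urn (a, b), which is what
rule-pool training and leave-one-out folds use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

__all__ = [
    "UrnCounts",
    "TailProbability",
    "support",
    "pmf",
    "upper_tail",
    "lower_tail",
    "moments",
    "TailTable",
    "tail_table",
]


def support(a: int, b: int, c: int) -> tuple[int, int]:
    """Inclusive (min, max) of the hypergeometric support for d."""
    return max(0, c + b - a), min(b, c)


def _validate_urn(a: int, b: int, c: int) -> None:
    for name, value in (("a", a), ("b", b), ("c", c)):
        if not isinstance(value, (int, np.integer)):
            raise TypeError(f"{name} must be an integer, got {value!r}")
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    if a < 1:
        raise ValueError(f"a must be a positive integer, got {a}")
    if b > a:
        raise ValueError(f"b must satisfy b <= a, got b={b} > a={a}")
    if c > a:
        raise ValueError(f"c must satisfy c <= a, got c={c} > a={a}")


@dataclass(frozen=True)
class UrnCounts:
    """Urn counts (a, b, c, d): library size, interest-class size, rule
    coverage and interest samples inside the coverage.

    Validates the support bounds max(0, c+b-a) <= d <= min(b, c); the error
    message names the violated bound.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        _validate_urn(self.a, self.b, self.c)
        if not isinstance(self.d, (int, np.integer)):
            raise TypeError(f"d must be an integer, got {self.d!r}")
        lo, hi = self.support
        if self.d < lo:
            raise ValueError(
                f"d={self.d} below support minimum max(0, c+b-a)={lo} "
                f"for a={self.a}, b={self.b}, c={self.c}"
            )
        if self.d > hi:
            raise ValueError(
                f"d={self.d} above support maximum min(b, c)={hi} "
                f"for a={self.a}, b={self.b}, c={self.c}"
            )

    @property
    def support(self) -> tuple[int, int]:
        return support(self.a, self.b, self.c)

    def pmf(self, *, exact: bool = False):
        return pmf(self, exact=exact)

    def upper_tail(self, *, exact: bool = False) -> "TailProbability":
        return upper_tail(self.a, self.b, self.c, self.d, exact=exact)

    def lower_tail(self, *, exact: bool = False) -> "TailProbability":
        return lower_tail(self.a, self.b, self.c, self.d, exact=exact)


@dataclass(frozen=True)
class TailProbability:
    """A one-sided hypergeometric p-value.

    ``value`` is the tail probability (float, or Fraction in exact mode),
    ``tail`` is ``"upper"`` (d or more, p(d+)) or ``"lower"`` (d or less,
    p(d-)), and ``counts`` holds the urn the query was evaluated on, with d
    clamped into the support when the query lay outside it.
    """

    value: float | Fraction
    tail: str
    counts: UrnCounts

    def __post_init__(self) -> None:
        if self.tail not in ("upper", "lower"):
            raise ValueError(f"tail must be 'upper' or 'lower', got {self.tail!r}")
        if not 0 <= self.value <= 1:
            raise ValueError(f"tail probability {self.value} outside [0, 1]")

    def __float__(self) -> float:
        return float(self.value)


def _log_pmf(a: int, b: int, c: int, d: int) -> float:
    # log C(b,d) + log C(a-b, c-d) - log C(a,c) via log-gamma
    return (
        _log_comb(b, d) + _log_comb(a - b, c - d) - _log_comb(a, c)
    )


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _pmf_fraction(a: int, b: int, c: int, d: int) -> Fraction:
    return Fraction(math.comb(b, d) * math.comb(a - b, c - d), math.comb(a, c))


def pmf(counts: UrnCounts, *, exact: bool = False):
    """Point probability P(d, c; b, a) of drawing exactly d interest samples.

    Float mode is accurate to <=1e-12 relative error; ``exact=True`` returns
    the exact ``Fraction`` (e.g. P(3, 4; 5, 9) = 20/63).
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if exact:
        return _pmf_fraction(a, b, c, d)
    return math.exp(_log_pmf(a, b, c, d))


def _tail_sum(a, b, c, d_lo, d_hi, exact):
    if exact:
        return sum(_pmf_fraction(a, b, c, i) for i in range(d_lo, d_hi + 1))
    return math.fsum(math.exp(_log_pmf(a, b, c, i)) for i in range(d_lo, d_hi + 1))


def upper_tail(
    a: int, b: int, c: int, d: int, *, exact: bool = False
) -> TailProbability:
    """p(d+, c; b, a): probability of drawing d or more interest samples.

    Total in d: below the support minimum the event is certain (returns 1),
    above the maximum impossible (returns 0).  Sums whichever tail is shorter
    and complements the other.
    """
    _validate_urn(a, b, c)
    lo, hi = support(a, b, c)
    one = Fraction(1) if exact else 1.0
    if d <= lo:
        return TailProbability(one, "upper", UrnCounts(a, b, c, lo))
    if d > hi:
        return TailProbability(one - one, "upper", UrnCounts(a, b, c, hi))
    counts = UrnCounts(a, b, c, d)
    n_upper = hi - d + 1
    n_lower = d - lo
    if n_upper <= n_lower:
        value = _tail_sum(a, b, c, d, hi, exact)
    else:
        value = one - _tail_sum(a, b, c, lo, d - 1, exact)
    return TailProbability(_clip01(value, exact), "upper", counts)


def lower_tail(
    a: int, b: int, c: int, d: int, *, exact: bool = False
) -> TailProbability:
    """p(d-, c; b, a): probability of drawing d or fewer interest samples.

    Total in d: at or above the support maximum returns 1, below the minimum
    returns 0.
    """
    _validate_urn(a, b, c)
    lo, hi = support(a, b, c)
    one = Fraction(1) if exact else 1.0
    if d >= hi:
        return TailProbability(one, "lower", UrnCounts(a, b, c, hi))
    if d < lo:
        return TailProbability(one - one, "lower", UrnCounts(a, b, c, lo))
    counts = UrnCounts(a, b, c, d)
    n_lower = d - lo + 1
    n_upper = hi - d
    if n_lower <= n_upper:
        value = _tail_sum(a, b, c, lo, d, exact)
    else:
        value = one - _tail_sum(a, b, c, d + 1, hi, exact)
    return TailProbability(_clip01(value, exact), "lower", counts)


def _clip01(value, exact):
    if exact:
        return value
    return min(1.0, max(0.0, value))


def moments(a: int, b: int, c: int) -> tuple[float, float]:
    """Mean and variance of the hypergeometric draw count:
    mu = c*b/a, sigma^2 = b*c*(a-b)*(a-c) / (a^2 * (a-1)).
    """
    _validate_urn(a, b, c)
    if a < 2:
        raise ValueError(f"variance requires a >= 2, got a={a}")
    mean = c * b / a
    variance = b * c * (a - b) * (a - c) / (a * a * (a - 1))
    return mean, variance


class TailTable:
    """Both tail p-values for every (c, d) of a fixed urn (a, b).

    ``upper[c, d]`` = p(d+, c; b, a) and ``lower[c, d]`` = p(d-, c; b, a),
    as (a+1, b+1) arrays built from a log-gamma PMF grid by cumulative sums
    (entries outside the support contribute zero, so queries outside the
    support resolve to the total-tail conventions 1 and 0 automatically).
    """

    def __init__(self, a: int, b: int) -> None:
        _validate_urn(a, b, 0)
        self.a = int(a)
        self.b = int(b)
        c = np.arange(a + 1)[:, None]
        d = np.arange(b + 1)[None, :]
        in_support = (d >= np.maximum(0, c + b - a)) & (d <= np.minimum(b, c))
        with np.errstate(invalid="ignore"):
            logp = (
                _gammaln_comb(b, d)
                + _gammaln_comb(a - b, c - d)
                - _gammaln_comb(a, c)
            )
        pmf_grid = np.where(in_support, np.exp(np.where(in_support, logp, -np.inf)), 0.0)
        self.pmf = pmf_grid
        self.upper = pmf_grid[:, ::-1].cumsum(axis=1)[:, ::-1]
        self.lower = pmf_grid.cumsum(axis=1)


def _gammaln_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    bad = (k < 0) | (k > n)
    k = np.where(bad, 0.0, k)
    n = np.where(n < 0, 0.0, n)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(bad, -np.inf, out)


@lru_cache(maxsize=64)
def tail_table(a: int, b: int) -> TailTable:
    """Memoized :class:`TailTable` for the urn (a, b)."""
    return TailTable(a, b)
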