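"""Exact null distribution for the direct image-matching task.

When n drawn images are matched one-to-one to n computed images uniformly
at random, the number of correct matches K follows the rencontres
distribution: P(K = k) = C(n, k) * !(n - k) / n!, where !m is the number
of derangements of m items. All arithmetic is exact (Python integers and
fractions); floats appear only at presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction


@dataclass(frozen=True)
class MatchingOutcome:
    """Observed result of a one-to-one matching task."""

    n: int
    n_correct: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0 <= self.n_correct <= self.n:
            raise ValueError(
                f"n_correct must be in 0..{self.n}, got {self.n_correct}"
            )


def derangement_count(m: int) -> int:
    """Exact number of fixed-point-free permutations of m items (!m).

    Computed by the recurrence !m = (m - 1)(!(m - 1) + !(m - 2)) with
    !0 = 1, !1 = 0, in arbitrary-precision integer arithmetic.
    """
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    if m == 0:
        return 1
    if m == 1:
        return 0
    prev2, prev1 = 1, 0  # !0, !1
    for i in range(2, m + 1):
        prev2, prev1 = prev1, (i - 1) * (prev1 + prev2)
    return prev1


def rencontres_pmf(n: int, k: int) -> Fraction:
    """Exact P(K = k) under random one-to-one matching of n items."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in 0..{n}, got {k}")
    return Fraction(
        math.comb(n, k) * derangement_count(n - k), math.factorial(n)
    )


def match_tail_probability(n: int, k: int) -> Fraction:
    """Exact upper-tail probability P(K >= k)."""
    if not 0 <= k <= n:
        raise ValueError(f"k must be in 0..{n}, got {k}")
    return sum((rencontres_pmf(n, j) for j in range(k, n + 1)), Fraction(0))


def expected_matches(n: int) -> Fraction:
    """E[K]; equals 1 for every n >= 1."""
    return sum(
        (Fraction(k) * rencontres_pmf(n, k) for k in range(n + 1)), Fraction(0)
    )


def exact_match_test(outcome: MatchingOutcome, alpha: float = 0.001) -> dict:
    """Exact test of an observed match count against random guessing.

    Reports the point probability, the upper-tail p-value P(K >= n_correct),
    the most likely outcome(s) under the null and a significance flag at
    ``alpha``.
    """
    n, k = outcome.n, outcome.n_correct
    pmf = {j: rencontres_pmf(n, j) for j in range(n + 1)}
    tail = match_tail_probability(n, k)
    mode_p = max(pmf.values())
    modes = [j for j, p in pmf.items() if p == mode_p]
    return {
        "n": n,
        "n_correct": k,
        "point_probability": float(pmf[k]),
        "point_probability_exact": pmf[k],
        "tail_p": float(tail),
        "tail_p_exact": tail,
        "alpha": alpha,
        "significant": float(tail) < alpha,
        "most_likely_outcomes": modes,
        "mode_probability": float(mode_p),
        "pmf": {j: float(p) for j, p in pmf.items()},
    }
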