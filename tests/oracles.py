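"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the code paths (and libraries' tail functions)
they are used to check: exact rational arithmetic via fractions, and naive
double loops for the kernel density.
"""

from fractions import Fraction
from math import comb, exp

import numpy as np


def naive_kernel_density(positions, grid, h, truncation_sigmas=4.0):
    """Double-loop Gaussian kernel sum with hard truncation at 4h."""
    out = np.zeros(len(grid))
    for gi, g in enumerate(grid):
        for x in positions:
            d = g - x
            if abs(d) <= truncation_sigmas * h:
                out[gi] += exp(-(d * d) / (2.0 * h * h))
    return out


def hypergeom_pmf(k, N, K, n) -> Fraction:
    """P(X = k) drawing n from N with K marked, exact rational."""
    if k < max(0, n + K - N) or k > min(n, K):
        return Fraction(0)
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def hypergeom_tail_ge(k, N, K, n) -> Fraction:
    return sum((hypergeom_pmf(j, N, K, n) for j in range(k, min(n, K) + 1)), Fraction(0))


def hypergeom_tail_le(k, N, K, n) -> Fraction:
    return sum((hypergeom_pmf(j, N, K, n) for j in range(0, k + 1)), Fraction(0))


def binom_tail_ge(k, n) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, 1/2), exact rational."""
    return Fraction(sum(comb(n, j) for j in range(k, n + 1)), 2**n)


def binom_tail_le(k, n) -> Fraction:
    return Fraction(sum(comb(n, j) for j in range(0, k + 1)), 2**n)


def binom_two_sided(k, n) -> Fraction:
    """2 x min(tail) sign-test p, capped at 1, exact rational."""
    p = 2 * min(binom_tail_ge(k, n), binom_tail_le(k, n))
    return min(p, Fraction(1))
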