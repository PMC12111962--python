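"""Independent brute-force oracles used only by the tests.

These deliberately avoid the implementation paths they check: exact
rational arithmetic for the Fisher test, direct series summation for the
Poisson tail, and exhaustive subset enumeration for the overlap null.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

# relative tie guard of the probability-mass rule, scaled to integers
_GUARD_NUM, _GUARD_DEN = 10**7 + 1, 10**7


def fisher_two_sided_oracle(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    All 2x2 tables with the observed margins are enumerated; tables whose
    probability is at most the observed one's (relative tolerance 1e-7)
    contribute. Integer arithmetic throughout, exact until the final
    float conversion.
    """
    r1, r2 = n1, n2
    c1 = k1 + k2
    # numerator of P(table with a successes in row 1); common denominator
    def num(a: int) -> int:
        b = c1 - a
        if a < 0 or a > r1 or b < 0 or b > r2:
            return 0
        return math.comb(r1, a) * math.comb(r2, b)

    n_obs = num(k1)
    denom = math.comb(r1 + r2, c1)
    total = 0
    for a in range(0, min(r1, c1) + 1):
        v = num(a)
        if v * _GUARD_DEN <= n_obs * _GUARD_NUM:
            total += v
    return float(min(Fraction(total, denom), Fraction(1)))


def poisson_upper_tail_oracle(k: int, mu: float) -> float:
    """P(X >= k) for X ~ Poisson(mu) by direct series summation."""
    log_term = -mu + k * math.log(mu) - math.lgamma(k + 1)
    term = math.exp(log_term)
    total = 0.0
    i = k
    while term > 1e-300 or i < k + 10:
        total += term
        i += 1
        term *= mu / i
    return total


def overlap_null_distribution_oracle(universe_size: int, size_a: int,
                                     size_b: int) -> dict[int, Fraction]:
    """Exact distribution of |A ∩ B| over all subset pairs of fixed sizes
    drawn from a universe, by exhaustive enumeration."""
    universe = range(universe_size)
    counts: dict[int, int] = {}
    total = 0
    for a in combinations(universe, size_a):
        sa = set(a)
        for b in combinations(universe, size_b):
            k = len(sa.intersection(b))
            counts[k] = counts.get(k, 0) + 1
            total += 1
    return {k: Fraction(v, total) for k, v in sorted(counts.items())}
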