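"""Brute-force reference implementations used only to check the package.

Everything here is deliberately naive: exact rational enumeration over
small supports, independent of the code paths under test.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_2x2_oracle(table) -> float:
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p <= p_obs * Fraction(10_000_001, 10_000_000):
            total += p
    return float(min(total, Fraction(1)))


def binomial_two_sided_oracle(k: int, n: int) -> float:
    """Minimum-likelihood two-sided binomial p against 0.5, exact."""
    pmf = [Fraction(comb(n, i), 2 ** n) for i in range(n + 1)]
    obs = pmf[k]
    total = sum(p for p in pmf if p <= obs * Fraction(10_000_001, 10_000_000))
    return float(min(total, Fraction(1)))


def hwe_oracle(hom_a: int, het: int, hom_b: int) -> float:
    """Exact HWE p by enumerating heterozygote counts, exact rationals."""
    n = hom_a + het + hom_b
    n_a = 2 * hom_a + het
    n_b = 2 * hom_b + het
    if n_a == 0 or n_b == 0:
        return 1.0
    from math import factorial
    probs = {}
    for h in range(n_a % 2, min(n_a, n_b) + 1, 2):
        ha = (n_a - h) // 2
        hb = (n_b - h) // 2
        probs[h] = Fraction(
            factorial(n) * 2 ** h * factorial(n_a) * factorial(n_b),
            factorial(ha) * factorial(h) * factorial(hb) * factorial(2 * n))
    obs = probs[het]
    total = sum(probs.values())
    keep = sum(p for p in probs.values()
               if p <= obs * Fraction(10_000_001, 10_000_000))
    return float(keep / total)
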