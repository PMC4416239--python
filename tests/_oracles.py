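"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the Fisher oracle
enumerates every table with the observed margins using factorial-product
rational arithmetic; the classification oracle scans raw genotype vectors;
the likelihood oracle multiplies per-read probabilities in linear space.
"""

from fractions import Fraction
from math import factorial


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins.

    Each table's probability is the multivariate hypergeometric
    r1! r2! c1! c2! / (n! a! b! c! d!); the p-value sums the probabilities
    of all tables no more probable than the observed one (exact rational
    comparison, so ties are handled without floating error).
    """
    n = a + b + c + d
    if n == 0:
        return Fraction(1)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    norm = Fraction(factorial(r1) * factorial(r2) * factorial(c1) * factorial(c2),
                    factorial(n))

    def prob(x):
        y, z, w = r1 - x, c1 - x, r2 - (c1 - x)
        if min(y, z, w) < 0:
            return None
        return norm / (factorial(x) * factorial(y) * factorial(z) * factorial(w))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p is not None and p <= p_obs:
            total += p
    return min(total, Fraction(1))


def classify_oracle(codes) -> str:
    """Classify a 0/1/2/None genotype vector by direct scanning."""
    has_homref = any(c == 0 for c in codes)
    has_het = any(c == 1 for c in codes)
    if not has_homref:
        return "A" if not has_het else "B"
    return "C" if has_het else "U"


def likelihoods_linear_oracle(observations, is_snv: bool = True):
    """Linear-space genotype likelihoods (products, no logs)."""
    import math

    result = []
    for g in (("ref", "ref"), ("ref", "alt"), ("alt", "alt")):
        prod = 1.0
        for obs in observations:
            e = 10.0 ** (-obs.base_quality / 10.0)
            miss = e / 3.0 if is_snv else e
            p = 0.0
            for allele in g:
                p += 0.5 * ((1.0 - e) if obs.allele_support == allele else miss)
            prod *= p
        result.append(math.log10(prod))
    return tuple(result)
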