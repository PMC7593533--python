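"""Calibrating sequence dissimilarity to resistance-like distances.

For the resistance analogy to apply to measured genetic distances, the
distance must add in series and combine in parallel by Ohm's law
D = D1 D2 / (D1 + D2).  This module provides the Jukes-Cantor and Kimura
two-parameter corrections, the parallel combination itself, and the expected
match count after a recombination event joining two equal-length, equally
distant parallel lineages.
"""

from __future__ import annotations

import math

__all__ = [
    "jukes_cantor",
    "jukes_cantor_from_matches",
    "kimura2p",
    "parallel_resistance",
    "recombined_matches",
]


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance D = -(3/4) ln(1 - (4/3) p) for a proportion p of
    disagreeing sites.  Returns ``inf`` at the saturation point p = 3/4."""
    if p < 0 or p > 1:
        raise ValueError("p must be a proportion in [0, 1]")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jukes_cantor_from_matches(c: float, m: int) -> float:
    """The same distance written in terms of c matching sites out of m:
    D(c) = (3/4) ln(3m / (4c - m)).  Valid for m/4 < c <= m."""
    if not m > 0:
        raise ValueError("alignment length m must be positive")
    if c > m:
        raise ValueError("cannot match more sites than the alignment length")
    if 4 * c - m <= 0:
        return math.inf
    return 0.75 * math.log(3.0 * m / (4.0 * c - m))


def kimura2p(p: float, q: float) -> float:
    """Kimura two-parameter distance for transition proportion p and
    transversion proportion q:

        K = -(1/2) ln( (1 - 2p - q) sqrt(1 - 2q) ).
    """
    if p < 0 or q < 0:
        raise ValueError("proportions must be non-negative")
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0 or b <= 0:
        return math.inf
    return -0.5 * math.log(a * math.sqrt(b))


def parallel_resistance(d1: float, d2: float) -> float:
    """Ohm's law for two circuit-parallel resistances: D = D1 D2 / (D1 + D2).

    Infinite branches are allowed: as D1 -> inf the total tends to D2; two
    zero branches give 0.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("resistances must be non-negative")
    if math.isinf(d1):
        return d2
    if math.isinf(d2):
        return d1
    if d1 + d2 == 0:
        return type(d1)(0) if not isinstance(d1, float) else 0.0
    return d1 * d2 / (d1 + d2)


def recombined_matches(c1: float, m: int) -> float:
    """Expected number of matching sites c after recombination of two
    parallel branches, each with c1 matches to the common ancestor.

    Defined by D(c) = D(c1)/2 under the Jukes-Cantor match-count form, whose
    unique solution is

        c = m/4 + sqrt( 3 ( (m/4) c1 - (m/4)^2 ) ).

    c is returned as a real number (an expected count), not rounded.
    """
    if not m > 0:
        raise ValueError("alignment length m must be positive")
    if c1 < m / 4 or c1 > m:
        raise ValueError("c1 must lie in [m/4, m]")
    q = m / 4.0
    return q + math.sqrt(3.0 * (q * c1 - q * q))
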