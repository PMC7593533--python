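"""Weighted circular split systems, the split metric, and the circular
decomposition of a Kalmanson metric.

A Kalmanson distance vector corresponds to a unique weighted circular split
system: each split is an arc of the circular order, and its weight is
recovered by the classical split-decomposition index

    w(arc c_i..c_j) = 1/2 * [ d(c_{i-1}, c_j) + d(c_i, c_{j+1})
                              - d(c_{i-1}, c_{j+1}) - d(c_i, c_j) ],

indices cyclic.  Exhaustive search over circular orders plus this index is an
exact, desk-scale replacement for agglomerative algorithms such as
neighbor-net; the recovered system reproduces the input metric exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

from .distance import DistanceVector, is_kalmanson, lex_pairs, min_path_vector
from .network import CircularOrder, Split, SplitSystem, orders_of_system

__all__ = [
    "WeightedSplitSystem",
    "NotKalmansonError",
    "split_metric",
    "circular_decompose",
    "is_outer_path",
    "is_faithfully_phylogenetic",
]


class NotKalmansonError(ValueError):
    """The metric is not circular-decomposable along the given order."""


@dataclass(frozen=True)
class WeightedSplitSystem:
    """Splits of [n] with non-negative weights; zero-weight splits dropped."""

    n: int
    weights: Mapping[Split, object]  # Split -> Fraction | float

    @staticmethod
    def of(n: int, weights: Mapping[Split, object], tol=0) -> "WeightedSplitSystem":
        clean = {}
        cutoff = -abs(tol) if tol else 0
        for sp, w in weights.items():
            if sp.n != n:
                raise ValueError(f"split {sp} is not a split of [{n}]")
            if w < cutoff:
                raise ValueError(f"negative split weight {w} for {sp}")
            if w > (tol or 0):
                clean[sp] = w
        return WeightedSplitSystem(n, dict(clean))

    @property
    def splits(self) -> frozenset:
        return frozenset(self.weights)

    @property
    def base(self) -> SplitSystem:
        """The unweighted split system (without forcing trivial splits)."""
        return SplitSystem(self.n, frozenset(self.weights))

    def base_with_trivial(self) -> SplitSystem:
        return SplitSystem.of(self.n, self.weights, add_trivial=True)

    def weight(self, sp: Split):
        return self.weights.get(sp, 0)

    def orders(self, bound: int = 9) -> set:
        """Circular orders with which every split is contiguous."""
        return orders_of_system(self.base_with_trivial(), bound=bound)

    def is_circular(self, bound: int = 9) -> bool:
        return bool(self.orders(bound=bound))

    def almost_equal(self, other: "WeightedSplitSystem", tol: float = 1e-9) -> bool:
        keys = self.splits | other.splits
        return self.n == other.n and all(
            abs(float(self.weight(k)) - float(other.weight(k))) <= tol for k in keys
        )

    def __len__(self) -> int:
        return len(self.weights)


def split_metric(system: WeightedSplitSystem) -> DistanceVector:
    """d_s(i, j) = sum of the weights of the splits separating i and j."""
    items = list(system.weights.items())

    def d(i, j):
        tot = 0
        for sp, w in items:
            if sp.separates(i, j):
                tot = tot + w
        return tot

    return DistanceVector.from_function(system.n, d)


def circular_decompose(
    d: DistanceVector, order: CircularOrder, tol=0
) -> WeightedSplitSystem:
    """The unique weighted circular split system with arcs contiguous in
    ``order`` whose split metric equals ``d``.

    Requires ``d`` Kalmanson with respect to ``order``; a split-weight more
    negative than ``-tol`` raises :class:`NotKalmansonError`.  With exact
    rational input and ``tol=0`` the round trip through
    :func:`split_metric` is bit-exact.
    """
    n = d.n
    seq = tuple(order)
    weights = {}
    for i in range(1, n):
        for j in range(i, n):
            # the arc seq[i..j]; its complement contains seq[0]
            prev_i, next_j = seq[i - 1], seq[(j + 1) % n]
            ci, cj = seq[i], seq[j]
            w = Fraction(1, 2) if isinstance(d.get(ci, cj), (Fraction, int)) else 0.5
            alpha = w * (
                d.get(prev_i, cj) + d.get(ci, next_j) - d.get(prev_i, next_j) - d.get(ci, cj)
            )
            if alpha < -(tol or 0):
                raise NotKalmansonError(
                    f"negative weight {alpha} for arc {seq[i:j+1]}; "
                    "metric is not Kalmanson along this order"
                )
            if alpha > (tol or 0):
                side = frozenset(seq[i : j + 1])
                sp = Split.of(side, set(seq) - side)
                weights[sp] = alpha
    return WeightedSplitSystem(n, weights)


def is_outer_path(system: WeightedSplitSystem, tol: float = 1e-9) -> bool:
    """True when between-leaf shortest paths of the system's split network can
    all run along the exterior, tested by the distance criterion: the minimum
    path metric of the weighted exterior network equals the split metric."""
    from .transforms import lw  # local import to avoid a cycle

    net = lw(system)
    return min_path_vector(net).almost_equal(split_metric(system), tol=tol)


def is_faithfully_phylogenetic(system: SplitSystem) -> bool:
    """True when the circular split system is exactly the set of splits
    displayed by its exterior 1-nested network (the range of Sigma)."""
    from .network import sigma_splits
    from .transforms import L_exterior

    net = L_exterior(system)
    return sigma_splits(net) == SplitSystem.of(system.n, system.splits, add_trivial=True)
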