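"""The gamma-statistic: diversification slowdown from an ultrametric tree.

gamma standardizes the internode intervals of an ultrametric phylogeny
against the constant-rates expectation.  Writing g_k for the time during
which exactly k lineages existed (k = 2..n) and T = sum_j j*g_j,

    gamma = [ (1/(n-2)) * sum_{i=2}^{n-1} (sum_{k=2}^{i} k*g_k)  -  T/2 ]
            / ( T * sqrt(1 / (12*(n-2))) )

Under a constant-rates pure-birth process gamma is approximately standard
normal; negative values mean branching events are concentrated early
(diversification slowdown), positive values that they crowd the present.
gamma is invariant to rescaling time, so trees in My or relative units give
the same value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tree import Tree, TreeError, check_ultrametric, crown_age

__all__ = ["GammaResult", "internode_intervals", "gamma_statistic"]


@dataclass(frozen=True)
class GammaResult:
    """gamma with the internals it is computed from.

    ``internode_intervals[k-2]`` is g_k, the duration with exactly k lineages,
    for k = 2..n; the g_k sum to the crown age.
    """

    gamma: float
    n: int
    internode_intervals: np.ndarray
    total_T: float

    def to_dict(self) -> dict:
        return {"gamma": self.gamma, "n": self.n, "total_T": self.total_T}


def internode_intervals(tree: Tree) -> np.ndarray:
    """g_2..g_n: durations between successive branching events.

    Branching times (internal node depths) partition the crown-to-present
    span; tied node depths yield zero-length intervals, which is fine (hard
    polytomies resolved with zero-length branches contribute nothing).
    """
    if tree.n_tips < 3:
        raise TreeError("internode intervals need at least 3 tips")
    check_ultrametric(tree, "the gamma statistic")
    depths = tree.depths()
    internal_depths = sorted(depths[n.id] for n in tree.internal_nodes)
    if len(internal_depths) != tree.n_tips - 1:
        raise TreeError(
            "gamma needs a bifurcating tree (after polytomy resolution): "
            f"expected {tree.n_tips - 1} internal nodes, found {len(internal_depths)}"
        )
    age = crown_age(tree)
    bounds = internal_depths + [age]
    return np.diff(bounds)


def gamma_statistic(tree: Tree) -> GammaResult:
    """The constant-rates test statistic from the tree's internode intervals."""
    g = internode_intervals(tree)  # g_2 .. g_n
    n = tree.n_tips
    k = np.arange(2, n + 1)
    kg = k * g
    total_T = float(kg.sum())
    # inner sums for i = 2..n-1: cumulative sums of k*g_k up to i
    cumulative = np.cumsum(kg)[: n - 2]
    numerator = cumulative.mean() - total_T / 2.0
    denominator = total_T * math.sqrt(1.0 / (12.0 * (n - 2)))
    return GammaResult(
        gamma=float(numerator / denominator),
        n=n,
        internode_intervals=g,
        total_T=total_T,
    )
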