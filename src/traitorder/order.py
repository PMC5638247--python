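"""Kendall's tau between tip order and trait ranks, maximized over node rotations.

The statistic: write the tree in Newick notation, record each species' 1-based
left-to-right position, and correlate positions with trait ranks using
Kendall's tau.  Rotating an internal node (reversing its child order) permutes
the positions without changing the topology, so the interesting quantity is
the *maximum* tau over all 2^(n-1) rotation states.

The key structural fact that makes the maximum cheap: a pair of tips is
ordered by the orientation of its most recent common ancestor and by nothing
else (subtrees occupy contiguous blocks of positions under every rotation
state).  Concordance of each pair therefore depends on exactly one node's
orientation, per-node choices are independent, and choosing each node's best
orientation yields the exact global optimum regardless of visiting order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau as _scipy_kendalltau
from scipy.stats import rankdata

from .traits import TraitTable
from .tree import RotationState, Tree, TreeError

__all__ = [
    "TauMaxResult",
    "kendall_tau",
    "maximize_tau",
    "brute_force_tau",
    "is_perfectly_orderable",
    "TreeIndex",
]

BRUTE_FORCE_MAX_TIPS = 14


def kendall_tau(positions, ranks) -> float:
    """Kendall's tau-b between tip positions and trait ranks.

    With no ties this is the plain tau-a: (concordant - discordant) over
    n(n-1)/2 pairs.
    """
    positions = np.asarray(positions, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    if positions.ndim != 1 or ranks.ndim != 1:
        raise ValueError("positions and ranks must be 1-D sequences")
    if len(positions) != len(ranks):
        raise ValueError(f"length mismatch: {len(positions)} positions vs {len(ranks)} ranks")
    if len(positions) < 2:
        raise ValueError("need at least 2 observations for a rank correlation")
    return float(_scipy_kendalltau(positions, ranks).statistic)


class TreeIndex:
    """Flat view of a bifurcating tree for fast cross-pair counting.

    ``tips`` is the tip order of the input orientation; each internal node is
    reduced to the slice of tip positions it spans and the split point between
    its two child blocks.
    """

    __slots__ = ("tips", "node_ids", "lo", "mid", "hi", "n")

    def __init__(self, tree: Tree):
        tips: list[str] = []
        node_ids: list[int] = []
        los: list[int] = []
        mids: list[int] = []
        his: list[int] = []

        def visit(node) -> tuple[int, int]:
            if node.is_leaf:
                tips.append(node.label)
                return len(tips) - 1, len(tips)
            if len(node.children) != 2:
                raise TreeError(
                    f"node {node.id} has {len(node.children)} children; the rotation "
                    "algorithm needs a bifurcating tree -- see resolve_polytomies()"
                )
            lo, m = visit(node.children[0])
            m2, hi = visit(node.children[1])
            node_ids.append(node.id)
            los.append(lo)
            mids.append(m)
            his.append(hi)
            return lo, hi

        visit(tree.root)
        self.tips = tips
        self.n = len(tips)
        self.node_ids = np.array(node_ids)
        self.lo = np.array(los)
        self.mid = np.array(mids)
        self.hi = np.array(his)


def _tied_pairs(ranks: np.ndarray) -> int:
    """Number of tip pairs with exactly equal trait rank."""
    _, counts = np.unique(ranks, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def _node_pair_counts(ranks: np.ndarray, lo: int, mid: int, hi: int) -> tuple[int, int, int]:
    """(A, B, T): cross pairs with left rank <, >, == right rank at one node."""
    left = ranks[lo:mid]
    right = np.sort(ranks[mid:hi])
    below = np.searchsorted(right, left, side="left")
    upto = np.searchsorted(right, left, side="right")
    a = int((right.size - upto).sum())  # left < right
    t = int((upto - below).sum())
    b = left.size * right.size - a - t
    return a, b, t


@dataclass(frozen=True)
class TauMaxResult:
    """Outcome of rotation maximization.

    tau_max is tau-b at the best orientation; ``rotation`` holds the internal
    node ids whose child order was reversed relative to the input; ``n_discordant``
    counts tip pairs that remain discordant at the optimum.
    """

    tau_max: float
    rotation: RotationState
    ordered_tips: list[str]
    n_discordant: int
    n: int

    def to_dict(self) -> dict:
        return {
            "tau_max": self.tau_max,
            "n": self.n,
            "n_discordant": self.n_discordant,
            "ordered_tips": list(self.ordered_tips),
        }


def _warn_ties(traits: TraitTable, tips: list[str], values: np.ndarray) -> None:
    vals, counts = np.unique(values, return_counts=True)
    tied_values = vals[counts > 1]
    if tied_values.size:
        tied_species = [t for t, v in zip(tips, values) if v in tied_values]
        warnings.warn(
            "tied trait values among species "
            f"{tied_species}; using tie-corrected tau-b",
            stacklevel=3,
        )


def maximize_tau(tree: Tree, traits: TraitTable) -> TauMaxResult:
    """Exact maximum of Kendall's tau over all rotation states.

    Per internal node, keep or reverse the child order according to which
    choice makes more cross-subtree pairs concordant; ties keep the input
    orientation so reports are deterministic.
    """
    index = TreeIndex(tree)
    if index.n < 3:
        raise TreeError("maximize_tau needs at least 3 tips")
    values = traits.values_for(index.tips)
    _warn_ties(traits, index.tips, values)
    ranks = rankdata(values)

    c_minus_d = 0
    n_discordant = 0
    flips: list[int] = []
    for node_id, lo, mid, hi in zip(index.node_ids, index.lo, index.mid, index.hi):
        a, b, _ = _node_pair_counts(ranks, lo, mid, hi)
        if b > a:
            flips.append(int(node_id))
            a, b = b, a
        c_minus_d += a - b
        n_discordant += b

    n0 = index.n * (index.n - 1) // 2
    ties = _tied_pairs(ranks)
    denom = np.sqrt(float(n0) * float(n0 - ties))
    rotation = RotationState.of(flips)
    return TauMaxResult(
        tau_max=float(c_minus_d / denom),
        rotation=rotation,
        ordered_tips=tree.tip_order(rotation),
        n_discordant=n_discordant,
        n=index.n,
    )


def max_tau_batch(index: TreeIndex, ranks: np.ndarray) -> np.ndarray:
    """tau_max for many rank vectors on one fixed tree.

    ``ranks`` has shape (B, n) aligned to ``index.tips``; returns shape (B,).
    This is the hot path of the Monte-Carlo null: per node, concordant
    cross-pairs are counted for all replicates at once.
    """
    ranks = np.asarray(ranks, dtype=float)
    if ranks.ndim == 1:
        ranks = ranks[None, :]
    B, n = ranks.shape
    if n != index.n:
        raise ValueError("rank matrix width does not match tree tip count")
    c_minus_d = np.zeros(B)
    for lo, mid, hi in zip(index.lo, index.mid, index.hi):
        left = ranks[:, lo:mid, None]
        right = ranks[:, None, mid:hi]
        a = (left < right).sum(axis=(1, 2))
        t = (left == right).sum(axis=(1, 2))
        b = (mid - lo) * (hi - mid) - a - t
        c_minus_d += np.abs(a - b)
    n0 = n * (n - 1) // 2
    sorted_r = np.sort(ranks, axis=1)
    tie_runs = sorted_r[:, 1:] == sorted_r[:, :-1]
    # tied pairs per row: sum over runs of c*(c-1)/2, computed from adjacency
    ties = np.zeros(B)
    if tie_runs.any():
        for i in np.nonzero(tie_runs.any(axis=1))[0]:
            ties[i] = _tied_pairs(ranks[i])
    denom = np.sqrt(float(n0) * (n0 - ties))
    return c_minus_d / denom


def _tau_of_sequence(ranks_in_order: np.ndarray) -> float:
    """tau-b between positions 1..n and the rank sequence (O(n^2), oracle-grade)."""
    r = np.asarray(ranks_in_order, dtype=float)
    n = len(r)
    diff = r[None, :] - r[:, None]
    iu = np.triu_indices(n, k=1)
    d = diff[iu]
    c_minus_d = int(np.sign(d).sum())
    ties = int((d == 0).sum())
    n0 = n * (n - 1) // 2
    return c_minus_d / np.sqrt(float(n0) * float(n0 - ties))


def brute_force_tau(tree: Tree, traits: TraitTable) -> float:
    """Maximum tau by exhausting all 2^(n-1) rotation states (test oracle)."""
    index = TreeIndex(tree)
    if index.n > BRUTE_FORCE_MAX_TIPS:
        raise TreeError(
            f"brute force enumerates 2^(n-1) rotations; refusing n={index.n} "
            f"(max {BRUTE_FORCE_MAX_TIPS})"
        )
    rank_of = dict(zip(index.tips, rankdata(traits.values_for(index.tips))))
    internal_ids = [int(i) for i in index.node_ids]
    best = -np.inf
    for mask in itertools.product([False, True], repeat=len(internal_ids)):
        rotation = RotationState.of(i for i, f in zip(internal_ids, mask) if f)
        order = tree.tip_order(rotation)
        tau = _tau_of_sequence(np.array([rank_of[t] for t in order]))
        best = max(best, tau)
    return float(best)


def is_perfectly_orderable(tree: Tree, traits: TraitTable) -> bool:
    """Can the tree be rotated so tips appear in strict trait order?

    True iff at every internal node the two child subtrees' trait-rank sets
    are separable (all ranks of one strictly below all ranks of the other),
    which is equivalent to tau_max = 1 with no discordant pair, and to the
    existence of a crossing-free traitgram embedding.
    """
    index = TreeIndex(tree)
    values = traits.values_for(index.tips)
    ranks = rankdata(values)
    for lo, mid, hi in zip(index.lo, index.mid, index.hi):
        left = ranks[lo:mid]
        right = ranks[mid:hi]
        if not (left.max() < right.min() or right.max() < left.min()):
            return False
    return True
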