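"""Traitgrams: trait evolution projected on the time axis, and branch crossings.

A traitgram draws each branch as a straight segment from (parent time, parent
trait) to (child time, child trait).  Two segments that properly intersect
away from a shared tree node imply that the two lineages had equal trait
values at that instant -- the geometric event a character-displacement model
forbids.  The number of such crossings is the geometric counterpart of the
rotation-maximized tau: histories with many crossings have poorly ordered tip
values, and a zero-crossing embedding exists exactly when the tips are
perfectly orderable.

For observed data, internal states are reconstructed by maximum likelihood
under Brownian motion; note that ML reconstruction minimizes change and so
*undercounts* true historical crossings.  Simulation-based counts should use
true simulated node states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .order import TreeIndex, maximize_tau
from .traits import TraitTable
from .tree import Tree, TreeError

__all__ = [
    "Traitgram",
    "CrossingCount",
    "asr_bm_ml",
    "build_traitgram",
    "traitgram_from_history",
    "count_crossings",
    "min_crossings_embedding",
]

#: relative tolerance of the orientation predicates (coordinates are
#: normalized to the unit box first, so this is relative to the drawing)
ORIENT_EPS = 1e-12


@dataclass
class Traitgram:
    """Segments of a (time, trait) projection.

    Arrays are aligned: segment i runs (t0[i], v0[i]) -> (t1[i], v1[i]) and
    belongs to the branch above node ``branch[i]`` (a branch contributes
    several segments when it carries a grid-resolution simulated path).
    """

    t0: np.ndarray
    v0: np.ndarray
    t1: np.ndarray
    v1: np.ndarray
    branch: np.ndarray

    def __post_init__(self):
        for name in ("t0", "v0", "t1", "v1", "branch"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if not (len(self.t0) == len(self.v0) == len(self.t1) == len(self.v1) == len(self.branch)):
            raise ValueError("segment arrays must have equal length")
        if np.any(self.t1 < self.t0):
            raise ValueError("segments must run forward in time")

    @property
    def n_segments(self) -> int:
        return len(self.t0)


@dataclass(frozen=True)
class CrossingCount:
    """Number of proper segment intersections and the branch pairs involved."""

    total: int
    pairs: list[tuple[int, int]]


def build_traitgram(tree: Tree, node_values: dict[int, float]) -> Traitgram:
    """One segment per branch from per-node trait values (true or inferred)."""
    depths = tree.depths()
    t0, v0, t1, v1, branch = [], [], [], [], []
    for node in tree.nodes:
        if node is tree.root:
            continue
        try:
            pv = node_values[node.parent.id]
            cv = node_values[node.id]
        except KeyError as exc:
            raise TreeError(f"missing trait value for node id {exc.args[0]}") from None
        t0.append(depths[node.parent.id])
        v0.append(pv)
        t1.append(depths[node.id])
        v1.append(cv)
        branch.append(node.id)
    return Traitgram(np.array(t0), np.array(v0), np.array(t1), np.array(v1), np.array(branch))


def traitgram_from_history(history) -> Traitgram:
    """Polyline traitgram from a displacement simulation's grid-level paths."""
    t0, v0, t1, v1, branch = [], [], [], [], []
    for b, (ts, vs) in history.paths.items():
        if len(ts) < 2:
            continue
        t0.append(ts[:-1])
        v0.append(vs[:-1])
        t1.append(ts[1:])
        v1.append(vs[1:])
        branch.append(np.full(len(ts) - 1, b))
    return Traitgram(
        np.concatenate(t0),
        np.concatenate(v0),
        np.concatenate(t1),
        np.concatenate(v1),
        np.concatenate(branch),
    )


# -- ancestral state reconstruction -------------------------------------------


def asr_bm_ml(tree: Tree, tip_traits: TraitTable) -> dict[int, float]:
    """ML ancestral states under Brownian motion (two-pass message passing).

    Equivalent to the GLS solution built from the BM covariance matrix: the
    root estimate is the phylogenetic mean, and every internal estimate is the
    precision-weighted combination of the message from below (Felsenstein
    pruning) and the message from the rest of the tree.  Zero-length branches
    are floored at a tiny fraction of the crown depth so conflicting tips on a
    hard polytomy of zero-length branches average rather than blow up.
    """
    if not tree.has_branch_lengths():
        raise TreeError("ancestral reconstruction needs branch lengths")
    depths = tree.depths()
    scale = max(depths.values())
    floor = (scale if scale > 0 else 1.0) * 1e-12

    post = [n for n in reversed(tree.nodes)]  # children before parents
    up_mean: dict[int, float] = {}
    up_var: dict[int, float] = {}
    for node in post:
        if node.is_leaf:
            up_mean[node.id] = tip_traits[node.label]
            up_var[node.id] = 0.0
        else:
            prec = 0.0
            mean = 0.0
            for c in node.children:
                v = max(up_var[c.id] + c.length, floor)
                prec += 1.0 / v
                mean += up_mean[c.id] / v
            up_mean[node.id] = mean / prec
            up_var[node.id] = 1.0 / prec

    out: dict[int, float] = {}
    down_mean: dict[int, float] = {}
    down_var: dict[int, float] = {}
    for node in tree.nodes:  # preorder: parents before children
        if node is tree.root:
            out[node.id] = up_mean[node.id]
            continue
        parent = node.parent
        prec = 0.0
        mean = 0.0
        if parent.id in down_var:
            v = down_var[parent.id]
            prec += 1.0 / v
            mean += down_mean[parent.id] / v
        for sib in parent.children:
            if sib is node:
                continue
            v = max(up_var[sib.id] + sib.length, floor)
            prec += 1.0 / v
            mean += up_mean[sib.id] / v
        if prec == 0.0:
            raise TreeError("singular configuration in ancestral reconstruction")
        msg_mean = mean / prec
        msg_var = 1.0 / prec + node.length
        down_mean[node.id] = msg_mean
        down_var[node.id] = max(msg_var, floor)
        if node.is_leaf:
            out[node.id] = tip_traits[node.label]
        else:
            uv = max(up_var[node.id], floor / 2)
            dv = down_var[node.id]
            w = (1.0 / uv) + (1.0 / dv)
            out[node.id] = (up_mean[node.id] / uv + down_mean[node.id] / dv) / w
    return out


# -- crossing counts ----------------------------------------------------------


def count_crossings(tg: Traitgram, eps: float = ORIENT_EPS) -> CrossingCount:
    """Count proper pairwise segment intersections (brute force, vectorized).

    Coordinates are normalized to the unit box first, so the count is
    invariant to affine rescaling of time and trait axes.  Intersections at
    shared endpoints (parent-child junctions, sister junctions) are not proper
    and are excluded automatically by the strict orientation test.  Tangency
    (touching without a sign change) is a measure-zero event under diffusion
    models; it is warned about and not counted.  Collinear overlapping
    segments are counted once, with a warning.
    """
    n = tg.n_segments
    if n < 2:
        return CrossingCount(0, [])
    t_span = float(max(tg.t1.max() - tg.t0.min(), 1e-300))
    v_all = np.concatenate([tg.v0, tg.v1])
    v_span = float(max(v_all.max() - v_all.min(), 1e-300))
    at0 = (tg.t0 - tg.t0.min()) / t_span
    at1 = (tg.t1 - tg.t0.min()) / t_span
    av0 = (tg.v0 - v_all.min()) / v_span
    av1 = (tg.v1 - v_all.min()) / v_span

    total = 0
    pairs: list[tuple[int, int]] = []
    warned_touch = False
    block = 2048
    for start in range(0, n, block):
        stop = min(start + block, n)
        i = np.arange(start, stop)[:, None]
        j = np.arange(n)[None, :]
        cand = (j > i) & (tg.branch[i] != tg.branch[j])
        # time intervals must overlap with positive measure
        cand &= np.maximum(at0[i], at0[j]) < np.minimum(at1[i], at1[j])
        if not cand.any():
            continue
        ii, jj = np.nonzero(cand)
        ii = ii + start
        d1 = _orient(at0[ii], av0[ii], at1[ii], av1[ii], at0[jj], av0[jj])
        d2 = _orient(at0[ii], av0[ii], at1[ii], av1[ii], at1[jj], av1[jj])
        d3 = _orient(at0[jj], av0[jj], at1[jj], av1[jj], at0[ii], av0[ii])
        d4 = _orient(at0[jj], av0[jj], at1[jj], av1[jj], at1[ii], av1[ii])
        small = (np.abs(d1) <= eps) | (np.abs(d2) <= eps) | (np.abs(d3) <= eps) | (np.abs(d4) <= eps)
        proper = (d1 * d2 < 0) & (d3 * d4 < 0) & ~small
        for a, b in zip(ii[proper], jj[proper]):
            pairs.append((int(tg.branch[a]), int(tg.branch[b])))
        total += int(proper.sum())
        # degenerate contacts within the overlapping time window
        if small.any():
            all_zero = (
                (np.abs(d1) <= eps) & (np.abs(d2) <= eps)
                & (np.abs(d3) <= eps) & (np.abs(d4) <= eps)
            )
            collinear = all_zero
            if collinear.any():
                warnings.warn("collinear overlapping traitgram segments; counted once each")
                for a, b in zip(ii[collinear], jj[collinear]):
                    pairs.append((int(tg.branch[a]), int(tg.branch[b])))
                total += int(collinear.sum())
            touch = small & ~all_zero & (d1 * d2 <= 0) & (d3 * d4 <= 0)
            if touch.any() and not warned_touch:
                # endpoint contacts at shared nodes land here too; only warn
                # about genuinely interior tangencies (no shared endpoint)
                interior = touch & ~_shares_endpoint(at0, av0, at1, av1, ii, jj, eps)
                if interior.any():
                    warnings.warn("tangent traitgram segments touch without crossing; not counted")
                    warned_touch = True
    return CrossingCount(total, pairs)


def _orient(ax, ay, bx, by, px, py):
    return (bx - ax) * (py - ay) - (by - ay) * (px - ax)


def _shares_endpoint(t0, v0, t1, v1, ii, jj, eps):
    def same(pa, qa, pb, qb):
        return (np.abs(pa - pb) <= eps) & (np.abs(qa - qb) <= eps)

    return (
        same(t0[ii], v0[ii], t0[jj], v0[jj])
        | same(t0[ii], v0[ii], t1[jj], v1[jj])
        | same(t1[ii], v1[ii], t0[jj], v0[jj])
        | same(t1[ii], v1[ii], t1[jj], v1[jj])
    )


def count_crossings_naive(tg: Traitgram, eps: float = ORIENT_EPS) -> int:
    """Reference all-pairs loop used to validate the vectorized counter."""
    n = tg.n_segments
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            if tg.branch[i] == tg.branch[j]:
                continue
            if max(tg.t0[i], tg.t0[j]) >= min(tg.t1[i], tg.t1[j]):
                continue
            d1 = _orient(tg.t0[i], tg.v0[i], tg.t1[i], tg.v1[i], tg.t0[j], tg.v0[j])
            d2 = _orient(tg.t0[i], tg.v0[i], tg.t1[i], tg.v1[i], tg.t1[j], tg.v1[j])
            d3 = _orient(tg.t0[j], tg.v0[j], tg.t1[j], tg.v1[j], tg.t0[i], tg.v0[i])
            d4 = _orient(tg.t0[j], tg.v0[j], tg.t1[j], tg.v1[j], tg.t1[i], tg.v1[i])
            if d1 * d2 < 0 and d3 * d4 < 0:
                total += 1
    return total


# -- zero-crossing embedding --------------------------------------------------


def min_crossings_embedding(tree: Tree, tip_traits: TraitTable) -> bool:
    """Can ancestral values be chosen so the traitgram has zero crossings?

    Constructive test: orient the tree by tau maximization, then assign each
    internal node a value strictly inside the gap between its two child
    subtrees' trait ranges and count crossings of the resulting traitgram.
    If the tips are perfectly orderable this wedge construction is crossing
    free; if they are not, *every* embedding has at least one crossing, so the
    construction finding one is conclusive.  Must agree with
    :func:`traitorder.order.is_perfectly_orderable`.
    """
    index = TreeIndex(tree)
    if index.n < 3:
        return True  # a cherry is always embeddable
    result = maximize_tau(tree, tip_traits)
    oriented = tree.apply_rotation(result.rotation)
    oidx = TreeIndex(oriented)
    values = tip_traits.values_for(oidx.tips)

    node_values: dict[int, float] = {}
    for tip in oriented.tips:
        node_values[tip.id] = tip_traits[tip.label]
    feasible = True
    for node_id, lo, mid, hi in zip(oidx.node_ids, oidx.lo, oidx.mid, oidx.hi):
        left = values[lo:mid]
        right = values[mid:hi]
        gap_lo, gap_hi = left.max(), right.min()
        if gap_lo >= gap_hi:
            feasible = False
            break
        node_values[int(node_id)] = 0.5 * (gap_lo + gap_hi)
    if not feasible:
        return False
    if not oriented.has_branch_lengths():
        # topology-only tree: draw it with unit branch lengths
        oriented = oriented.copy()
        for node in oriented.nodes:
            if node is not oriented.root:
                node.length = 1.0
        _equalize_tip_depths(oriented)
    tg = build_traitgram(oriented, node_values)
    return count_crossings(tg).total == 0


def _equalize_tip_depths(tree: Tree) -> None:
    depths = tree.depths()
    age = max(depths.values())
    for tip in tree.tips:
        tip.length += age - depths[tip.id]
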