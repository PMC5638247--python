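"""Null and alternative simulators, and the Monte-Carlo order test.

Null model: trait values change randomly along the tree (Brownian motion).
Because the test statistic depends on ranks only and BM rescaling is monotone,
its null distribution is invariant to the diffusion rate -- only topology and
branching times matter.  The alternative is a character-displacement model in
which trait trajectories of coexisting lineages are discouraged from crossing
(parameter ``p_c``: probability a proposed crossing is permitted; 1 = plain BM,
0 = strict displacement, which forbids any two lineages from ever swapping
order and hence yields perfectly ordered tip values).

The observed statistic is the rotation-maximized tau, so the null replicates
are maximized too, and the one-sided Monte-Carlo p-value is
p = (s* + 1) / (s + 1) with s* the number of null draws strictly above the
observed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .order import TreeIndex, max_tau_batch, maximize_tau
from .traits import TraitTable
from .tree import Node, Tree, TreeError, check_ultrametric

__all__ = [
    "SimConfig",
    "DisplacementConfig",
    "OrderTestResult",
    "DisplacementHistory",
    "simulate_bm",
    "tip_table",
    "simulate_yule",
    "null_tau_distribution",
    "order_test",
    "simulate_displacement",
]

#: tolerance used when counting null draws strictly above the observed tau
_TAU_EPS = 1e-9


@dataclass
class SimConfig:
    """Null-simulation settings.

    sigma2 is the BM rate in trait-units^2 per unit branch length; the default
    1.0 is justified by rate invariance of the rank statistic.  ``s`` is the
    number of null replicates (default 1000, giving a p-value floor of 1/1001).
    """

    sigma2: float = 1.0
    root_state: float = 0.0
    seed: Optional[int] = None
    s: int = 1000

    def __post_init__(self):
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if self.s < 1:
            raise ValueError("need at least one null replicate")


@dataclass
class DisplacementConfig:
    """Character-displacement simulation settings.

    ``p_c`` is the probability that a proposed order swap (trajectory crossing)
    between two coexisting lineages is permitted.  ``dt`` is the time step of
    the discretized simulation; default crown_age/1000.
    """

    p_c: float = 0.0
    dt: Optional[float] = None
    sigma2: float = 1.0
    root_state: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.p_c <= 1.0:
            raise ValueError("p_c must lie in [0, 1]")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")


@dataclass(frozen=True)
class OrderTestResult:
    """Observed maximized tau against its Monte-Carlo null distribution."""

    tau_obs: float
    null_taus: np.ndarray
    s: int
    s_star: int
    p: float

    def to_dict(self) -> dict:
        return {"tau_obs": self.tau_obs, "s": self.s, "s_star": self.s_star, "p": self.p}


# -- Brownian motion ----------------------------------------------------------


def simulate_bm(
    tree: Tree,
    config: Optional[SimConfig] = None,
    *,
    rng: Optional[np.random.Generator] = None,
) -> dict[int, float]:
    """Brownian motion along every branch; returns node-id -> trait value.

    Each child value is its parent's value plus a Normal(0, sigma2 * branch
    length) increment; deterministic for a fixed seed.
    """
    config = config or SimConfig()
    if not tree.has_branch_lengths():
        raise TreeError("BM simulation needs branch lengths on every branch")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    values: dict[int, float] = {tree.root.id: config.root_state}
    for node in tree.nodes:
        if node is tree.root:
            continue
        sd = math.sqrt(config.sigma2 * node.length)
        values[node.id] = values[node.parent.id] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    return values


def tip_table(tree: Tree, node_values: dict[int, float]) -> TraitTable:
    """Extract tip values from a per-node simulation as a TraitTable."""
    return TraitTable({t.label: node_values[t.id] for t in tree.tips})


def _bm_tips_batch(
    tree: Tree, index: TreeIndex, n_rep: int, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_rep, n_tips) matrix of BM tip values aligned to index.tips."""
    values: dict[int, np.ndarray] = {tree.root.id: np.zeros(n_rep)}
    for node in tree.nodes:
        if node is tree.root:
            continue
        sd = math.sqrt(sigma2 * node.length)
        incr = rng.normal(0.0, sd, size=n_rep) if sd > 0 else 0.0
        values[node.id] = values[node.parent.id] + incr
    tip_by_label = {t.label: t.id for t in tree.tips}
    return np.column_stack([values[tip_by_label[lbl]] for lbl in index.tips])


# -- Yule trees ---------------------------------------------------------------


def simulate_yule(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    crown_age: Optional[float] = None,
) -> Tree:
    """Pure-birth ultrametric tree with ``n_tips`` tips.

    While k lineages exist the waiting time to the next birth is Exponential
    with rate k * birth_rate, starting from the crown split (2 lineages) and
    cutting the tree at the moment the would-be (n+1)-th lineage falls due.
    Every internode interval therefore follows the constant-rates law
    (g_k ~ Exp(k * birth_rate)), which keeps the gamma statistic centred at
    zero on simulated trees, and the crown age has expectation
    sum_{k=2}^{n} 1/(k * birth_rate).  Pass ``crown_age`` to rescale the tree
    to an exact depth instead.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)

    root = Node()
    # active lineages: (pending node, time its branch started)
    active: list[tuple[Node, float]] = []
    for _ in range(2):
        child = Node()
        root.children.append(child)
        active.append((child, 0.0))
    t = 0.0
    for k in range(2, n_tips):
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(len(active)))
        node, start = active.pop(idx)
        node.length = t - start
        for _ in range(2):
            child = Node()
            node.children.append(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for i, (node, start) in enumerate(active):
        node.length = t - start
    tree = _label_tips(root)
    if crown_age is not None:
        scale = crown_age / t
        for node in tree.nodes:
            if node.length is not None:
                node.length *= scale
    return tree


def _label_tips(root: Node) -> Tree:
    i = 0
    for node in Tree._preorder(root):
        if not node.children:
            i += 1
            node.label = f"t{i}"
    return Tree(root)


# -- order test ---------------------------------------------------------------


def null_tau_distribution(tree: Tree, config: Optional[SimConfig] = None) -> np.ndarray:
    """s draws of the rotation-maximized tau under BM on the given tree.

    The null replicates go through the same maximization as the observed
    statistic; anything else would bias the p-value anti-conservatively.
    """
    config = config or SimConfig()
    index = TreeIndex(tree)
    rng = np.random.default_rng(config.seed)
    tips = _bm_tips_batch(tree, index, config.s, config.sigma2, rng)
    ranks = rankdata(tips, axis=1)
    return max_tau_batch(index, ranks)


def order_test(
    tree: Tree, traits: TraitTable, config: Optional[SimConfig] = None
) -> OrderTestResult:
    """One-sided Monte-Carlo test of trait order against the BM null.

    s* counts null draws strictly greater than tau_obs (ties count as
    non-exceeding); p = (s* + 1)/(s + 1), so the smallest attainable p is
    1/(s + 1).
    """
    config = config or SimConfig()
    tau_obs = maximize_tau(tree, traits).tau_max
    null_taus = null_tau_distribution(tree, config)
    s_star = int((null_taus > tau_obs + _TAU_EPS).sum())
    p = (s_star + 1) / (config.s + 1)
    return OrderTestResult(
        tau_obs=tau_obs, null_taus=null_taus, s=config.s, s_star=s_star, p=p
    )


# -- character displacement ---------------------------------------------------


@dataclass
class DisplacementHistory:
    """Grid-resolution trajectories of a displacement simulation.

    ``paths`` maps each branch (identified by its child node id) to a pair of
    arrays (times, values) sampled at every simulation step during the
    branch's lifetime, endpoints included.
    """

    paths: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def _thin_crossings(
    x: np.ndarray, dx: np.ndarray, p_c: float, rng: np.random.Generator
) -> np.ndarray:
    """One time step: apply increments, thinning proposed order swaps.

    A disallowed swap exchanges the two increments, which keeps the pair in
    its original order (reflection) and leaves the marginal BM law intact.
    Pairs that start at exactly equal values (fresh sister lineages) may
    reorder freely: their relative order is not yet established, so this is
    not a crossing.
    """
    y = x + dx
    if p_c >= 1.0:
        return y
    if p_c <= 0.0:
        # no crossings: assign the sorted proposals back in the current order
        order = np.argsort(x, kind="stable")
        out = np.empty_like(y)
        out[order] = np.sort(y)
        return out

    idx = list(np.argsort(x, kind="stable"))
    yv = y.copy()
    allowed: dict[tuple[int, int], bool] = {}
    max_sweeps = 4 * len(idx) * len(idx) + 16
    for _ in range(max_sweeps):
        changed = False
        for a in range(len(idx) - 1):
            i, j = idx[a], idx[a + 1]
            if yv[i] <= yv[j]:
                continue
            if x[i] == x[j]:
                idx[a], idx[a + 1] = j, i
                changed = True
                continue
            key = (i, j) if i < j else (j, i)
            if key not in allowed:
                allowed[key] = bool(rng.random() < p_c)
            if allowed[key]:
                idx[a], idx[a + 1] = j, i  # crossing permitted
            else:
                yv[i], yv[j] = x[i] + (yv[j] - x[j]), x[j] + (yv[i] - x[i])
            changed = True
        if not changed:
            return yv
    # pathological multi-crossing chain: fall back to the order-preserving map
    order = np.argsort(x, kind="stable")
    out = np.empty_like(yv)
    out[order] = np.sort(yv)
    return out


def simulate_displacement(
    tree: Tree,
    config: Optional[DisplacementConfig] = None,
    *,
    return_history: bool = False,
):
    """Simulate trait evolution with crossing-thinned Brownian motion.

    Returns the tip :class:`~traitorder.traits.TraitTable`, or a
    ``(tips, node_values, history)`` triple when ``return_history`` is set.
    ``node_values`` maps every node id to its trait value at the node's time.
    """
    config = config or DisplacementConfig()
    check_ultrametric(tree, "the displacement simulator")
    if not tree.is_bifurcating:
        raise TreeError("displacement simulation needs a bifurcating tree")
    depths = tree.depths()
    age = max(depths.values())
    dt = config.dt if config.dt is not None else age / 1000.0
    rng = np.random.default_rng(config.seed)

    node_by_id = {n.id: n for n in tree.nodes}
    # event times: node depths, merged within float tolerance so e.g. all tips
    # share one terminal event despite rounding noise in summed branch lengths
    tol = age * 1e-9
    events: dict[float, list[int]] = {}
    event_times: list[float] = []
    for depth, node_id in sorted(
        (depths[n.id], n.id) for n in tree.nodes if n is not tree.root
    ):
        if event_times and depth - event_times[-1] <= tol:
            events[event_times[-1]].append(node_id)
        else:
            event_times.append(depth)
            events[depth] = [node_id]

    node_values: dict[int, float] = {tree.root.id: config.root_state}
    history = DisplacementHistory() if return_history else None

    # active branches, identified by child node id
    active: list[int] = [c.id for c in tree.root.children]
    values = np.full(len(active), config.root_state, dtype=float)
    if history is not None:
        rec: dict[int, tuple[list, list]] = {
            b: ([0.0], [config.root_state]) for b in active
        }

    t = 0.0
    for t_event in event_times:
        if t_event <= t:
            pass
        else:
            n_steps = max(1, int(math.ceil((t_event - t) / dt)))
            step = (t_event - t) / n_steps
            sd = math.sqrt(config.sigma2 * step)
            for k in range(n_steps):
                dx = rng.normal(0.0, sd, size=len(active)) if sd > 0 else np.zeros(len(active))
                values = _thin_crossings(values, dx, config.p_c, rng)
                t += step
                if history is not None:
                    for b, v in zip(active, values):
                        rec[b][0].append(t)
                        rec[b][1].append(v)
            t = t_event
        # branch endpoints reached: record node values, split or terminate;
        # ids are preorder, so sorting processes parents before zero-length children
        for node_id in sorted(events[t_event]):
            pos = active.index(node_id)
            v = values[pos]
            node_values[node_id] = float(v)
            node = node_by_id[node_id]
            if node.is_leaf:
                active.pop(pos)
                values = np.delete(values, pos)
            else:
                kids = [c.id for c in node.children]
                active = active[:pos] + kids + active[pos + 1 :]
                values = np.concatenate([values[:pos], [v, v], values[pos + 1 :]])
                if history is not None:
                    for b in kids:
                        rec[b] = ([t], [float(v)])

    tips = TraitTable({tip.label: node_values[tip.id] for tip in tree.tips})
    if history is not None:
        history.paths = {
            b: (np.array(ts), np.array(vs)) for b, (ts, vs) in rec.items()
        }
        return tips, node_values, history
    return tips
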