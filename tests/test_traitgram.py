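"""Traitgram construction, ancestral reconstruction, and crossing counts."""

import numpy as np
import pytest

from traitorder import (
    DisplacementConfig,
    SimConfig,
    TraitTable,
    Traitgram,
    asr_bm_ml,
    build_traitgram,
    count_crossings,
    is_perfectly_orderable,
    maximize_tau,
    min_crossings_embedding,
    parse_newick,
    simulate_bm,
    simulate_displacement,
    simulate_yule,
    tip_table,
    traitgram_from_history,
)
from traitorder.traitgram import count_crossings_naive
from conftest import random_instance


def _gls_ancestral_oracle(tree, traits):
    """Dense GLS solution from the BM covariance matrix (independent oracle)."""
    depths = tree.depths()
    tips = tree.tips
    n = len(tips)

    def mrca_depth(a, b):
        ancestors = set()
        x = a
        while x is not None:
            ancestors.add(x.id)
            x = x.parent
        x = b
        while x.id not in ancestors:
            x = x.parent
        return depths[x.id]

    C = np.array(
        [[depths[a.id] if a is b else mrca_depth(a, b) for b in tips] for a in tips]
    )
    x = np.array([traits[t.label] for t in tips])
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    root = one @ Ci @ x / (one @ Ci @ one)
    out = {}
    for node in tree.nodes:
        if node.is_leaf:
            continue
        c = np.array([mrca_depth(node, b) for b in tips])
        out[node.id] = root + c @ Ci @ (x - root)
    return out


class TestASR:
    def test_symmetric_cherry(self):
        tree = parse_newick("(A:1,B:1);")
        values = asr_bm_ml(tree, TraitTable({"A": 0.0, "B": 2.0}))
        assert values[tree.root.id] == pytest.approx(1.0)

    def test_equal_weight_star(self):
        tree = parse_newick("(A:1,B:1,C:1);")
        values = asr_bm_ml(tree, TraitTable({"A": 0.0, "B": 0.0, "C": 3.0}))
        assert values[tree.root.id] == pytest.approx(1.0)

    def test_matches_dense_gls(self, rng):
        for _ in range(10):
            tree, traits = random_instance(rng, 6)
            mine = asr_bm_ml(tree, traits)
            oracle = _gls_ancestral_oracle(tree, traits)
            for node_id, expected in oracle.items():
                assert mine[node_id] == pytest.approx(expected, abs=1e-9)


class TestBuildTraitgram:
    def test_two_tip_segments_share_root(self):
        tree = parse_newick("(A:1,B:1);")
        tg = build_traitgram(tree, {tree.root.id: 0.5, **{t.id: float(t.label == "A") for t in tree.tips}})
        assert tg.n_segments == 2
        assert np.all(tg.t0 == 0.0) and np.all(tg.v0 == 0.5)

    def test_branch_count_is_2n_minus_2(self, quartet_dated):
        tree, _ = quartet_dated
        node_values = {n.id: 0.0 for n in tree.nodes}
        assert build_traitgram(tree, node_values).n_segments == 2 * tree.n_tips - 2

    def test_endpoints_respect_node_times(self, rng):
        tree = simulate_yule(9, rng=rng)
        node_values = simulate_bm(tree, SimConfig(seed=2))
        tg = build_traitgram(tree, node_values)
        depths = tree.depths()
        by_branch = dict(zip(tg.branch.tolist(), zip(tg.t0, tg.t1)))
        for node in tree.nodes:
            if node is tree.root:
                continue
            t0, t1 = by_branch[node.id]
            assert t0 == pytest.approx(depths[node.parent.id])
            assert t1 == pytest.approx(depths[node.id])

    def test_missing_node_value_errors(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(Exception, match="missing"):
            build_traitgram(tree, {tree.root.id: 0.0})


class TestCountCrossings:
    def test_two_tip_tree_has_none(self):
        tree = parse_newick("(A:1,B:1);")
        tg = build_traitgram(tree, {tree.root.id: 0.0, tree.tips[0].id: 1.0, tree.tips[1].id: -1.0})
        assert count_crossings(tg).total == 0

    def test_hand_built_cousin_crossing(self):
        # two cousin branches swap trait order between their shared time window
        tg = Traitgram(
            t0=[0.0, 0.0], v0=[0.0, 1.0], t1=[2.0, 2.0], v1=[1.0, 0.0], branch=[1, 2]
        )
        result = count_crossings(tg)
        assert result.total == 1
        assert result.pairs == [(1, 2)]

    def test_quartet_reconstruction_has_at_least_one(self, quartet_dated):
        # the four-warbler example cannot be drawn without an intersection
        tree, traits = quartet_dated
        tg = build_traitgram(tree, asr_bm_ml(tree, traits))
        assert count_crossings(tg).total >= 1

    def test_shared_endpoints_do_not_count(self):
        # sisters diverging from one point, one crossing pair elsewhere
        tg = Traitgram(
            t0=[0.0, 0.0], v0=[0.0, 0.0], t1=[1.0, 1.0], v1=[1.0, -1.0], branch=[1, 2]
        )
        assert count_crossings(tg).total == 0

    def test_collinear_overlap_counted_once_with_warning(self):
        tg = Traitgram(
            t0=[0.0, 1.0], v0=[0.0, 1.0], t1=[2.0, 3.0], v1=[2.0, 3.0], branch=[1, 2]
        )
        with pytest.warns(UserWarning, match="collinear"):
            assert count_crossings(tg).total == 1

    def test_tangency_not_counted(self):
        # segment 2 touches segment 1 at an interior point without sign change
        tg = Traitgram(
            t0=[0.0, 0.0], v0=[0.0, 1.0], t1=[2.0, 2.0], v1=[0.0, 1.0], branch=[1, 2, ]
        )
        tg2 = Traitgram(
            t0=[0.0, 0.5], v0=[0.0, 1.0], t1=[2.0, 1.5], v1=[0.0, 0.0], branch=[1, 2]
        )
        assert count_crossings(tg).total == 0
        with pytest.warns(UserWarning, match="tangent"):
            assert count_crossings(tg2).total == 0

    def test_matches_naive_all_pairs(self, rng):
        for _ in range(30):
            tree = simulate_yule(int(rng.integers(5, 30)), rng=rng)
            tg = build_traitgram(tree, simulate_bm(tree, rng=rng))
            assert count_crossings(tg).total == count_crossings_naive(tg)

    def test_affine_invariance(self, rng):
        tree = simulate_yule(20, rng=rng)
        node_values = simulate_bm(tree, rng=rng)
        tg = build_traitgram(tree, node_values)
        ref = count_crossings(tg).total
        for a, b, c, d in [(3.0, 5.0, -2.0, 1.0), (0.1, -4.0, 10.0, 0.0)]:
            scaled = Traitgram(
                t0=a * tg.t0 + b if a > 0 else a * tg.t1 + b,
                v0=c * tg.v0 + d,
                t1=a * tg.t1 + b if a > 0 else a * tg.t0 + b,
                v1=c * tg.v1 + d,
                branch=tg.branch,
            )
            assert count_crossings(scaled).total == ref

    def test_strict_displacement_history_has_no_crossings(self, rng):
        tree = simulate_yule(10, rng=rng)
        _, _, history = simulate_displacement(
            tree,
            DisplacementConfig(p_c=0.0, seed=3, dt=None),
            return_history=True,
        )
        assert count_crossings(traitgram_from_history(history)).total == 0

    def test_negative_association_with_tau(self):
        # histories with many crossings have poorly ordered tips
        from scipy.stats import kendalltau

        tree = simulate_yule(25, seed=3)
        rng = np.random.default_rng(4)
        taus, crossings = [], []
        for _ in range(300):
            node_values = simulate_bm(tree, rng=rng)
            taus.append(maximize_tau(tree, tip_table(tree, node_values)).tau_max)
            crossings.append(count_crossings(build_traitgram(tree, node_values)).total)
        assert kendalltau(taus, crossings).statistic < 0


class TestZeroCrossingEmbedding:
    def test_quartet_infeasible(self, quartet):
        assert min_crossings_embedding(*quartet) is False

    def test_three_taxon_feasible(self, three_taxon):
        assert min_crossings_embedding(*three_taxon) is True

    def test_cherry_feasible(self):
        tree = parse_newick("(A:1,B:1);")
        assert min_crossings_embedding(tree, TraitTable({"A": 1.0, "B": 2.0})) is True

    def test_equivalent_to_perfect_orderability(self, rng):
        agree = 0
        for _ in range(150):
            tree, traits = random_instance(rng, rng.integers(4, 10))
            assert min_crossings_embedding(tree, traits) == is_perfectly_orderable(tree, traits)
            agree += 1
        assert agree == 150
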