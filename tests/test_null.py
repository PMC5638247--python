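"""Brownian/Yule/displacement simulators and the Monte-Carlo order test."""

import numpy as np
import pytest
from scipy.stats import ks_2samp, kstest

from traitorder import (
    DisplacementConfig,
    SimConfig,
    TreeError,
    crown_age,
    is_perfectly_orderable,
    is_ultrametric,
    maximize_tau,
    null_tau_distribution,
    order_test,
    parse_newick,
    simulate_bm,
    simulate_displacement,
    simulate_yule,
    tip_table,
    write_newick,
)


class TestSimulateBM:
    def test_contrast_variance(self):
        tree = parse_newick("(A:1,B:1);")
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(4000):
            v = tip_table(tree, simulate_bm(tree, rng=rng))
            diffs.append(v["A"] - v["B"])
        assert np.var(diffs) == pytest.approx(2.0, rel=0.1)

    def test_zero_rate_limit(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        values = simulate_bm(tree, SimConfig(sigma2=0.0, root_state=7.0, seed=1))
        assert all(v == 7.0 for v in values.values())

    def test_tip_covariance_matches_shared_paths(self):
        tree = parse_newick("((A:1,B:1):2,(C:2,D:2):1);")
        expected = np.array(
            [[3.0, 2.0, 0.0, 0.0],
             [2.0, 3.0, 0.0, 0.0],
             [0.0, 0.0, 3.0, 1.0],
             [0.0, 0.0, 1.0, 3.0]]
        )
        rng = np.random.default_rng(5)
        sims = np.array(
            [list(tip_table(tree, simulate_bm(tree, rng=rng)).values_for("ABCD"))
             for _ in range(6000)]
        )
        assert np.allclose(np.cov(sims.T), expected, atol=0.25)

    def test_seed_determinism(self, rng):
        tree = simulate_yule(8, rng=rng)
        a = simulate_bm(tree, SimConfig(seed=42))
        b = simulate_bm(tree, SimConfig(seed=42))
        assert a == b

    def test_needs_branch_lengths(self, quartet):
        tree, _ = quartet
        with pytest.raises(TreeError):
            simulate_bm(tree, SimConfig(seed=0))


class TestSimulateYule:
    def test_two_tips_is_ultrametric_cherry(self):
        tree = simulate_yule(2, seed=0)
        assert tree.n_tips == 2
        assert is_ultrametric(tree)

    def test_all_outputs_ultrametric_bifurcating(self, rng):
        for _ in range(20):
            tree = simulate_yule(int(rng.integers(2, 40)), rng=rng)
            assert is_ultrametric(tree)
            assert tree.is_bifurcating

    def test_crown_age_expectation(self):
        # k lineages wait Exp(k * birth_rate): E[crown age] is the partial
        # harmonic sum from the crown (2 lineages) to the cut after the n-th
        rng = np.random.default_rng(11)
        ages = [crown_age(simulate_yule(10, rng=rng)) for _ in range(2000)]
        expected = sum(1 / k for k in range(2, 11))
        assert np.mean(ages) == pytest.approx(expected, rel=0.05)

    def test_seed_reproducibility(self):
        assert write_newick(simulate_yule(12, seed=9)) == write_newick(simulate_yule(12, seed=9))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_yule(1)
        with pytest.raises(ValueError):
            simulate_yule(5, birth_rate=0.0)


class TestOrderTest:
    def test_p_value_formula(self, rng):
        tree, traits = _bm_dataset(rng, 10)
        result = order_test(tree, traits, SimConfig(seed=3, s=200))
        recomputed = (int((result.null_taus > result.tau_obs + 1e-9).sum()) + 1) / 201
        assert result.p == pytest.approx(recomputed)
        assert result.s == 200
        assert 1 / 201 <= result.p <= 1.0

    def test_perfectly_ordered_data_hits_floor(self, rng):
        tree = simulate_yule(20, rng=rng)
        traits = simulate_displacement(tree, DisplacementConfig(p_c=0.0, seed=4))
        result = order_test(tree, traits, SimConfig(seed=5, s=100))
        assert result.tau_obs == pytest.approx(1.0)
        assert result.s_star == 0
        assert result.p == pytest.approx(1 / 101)

    def test_null_draws_bounded(self, rng):
        tree = simulate_yule(12, rng=rng)
        draws = null_tau_distribution(tree, SimConfig(seed=1, s=300))
        assert len(draws) == 300
        assert np.all(draws >= -1) and np.all(draws <= 1)

    def test_rate_invariance(self):
        tree = simulate_yule(12, seed=77)
        slow = null_tau_distribution(tree, SimConfig(sigma2=1.0, seed=1, s=800))
        fast = null_tau_distribution(tree, SimConfig(sigma2=10.0, seed=2, s=800))
        assert ks_2samp(slow, fast).pvalue > 0.01

    def test_topology_shifts_null(self):
        balanced = parse_newick(_balanced_newick(16))
        pectinate = parse_newick(_pectinate_newick(16))
        a = null_tau_distribution(balanced, SimConfig(seed=1, s=1500))
        b = null_tau_distribution(pectinate, SimConfig(seed=2, s=1500))
        assert ks_2samp(a, b).pvalue < 0.01


class TestSimulateDisplacement:
    def test_pc_one_collapses_to_bm(self):
        # on a cherry the tip contrast must be Normal(0, sqrt(2))
        tree = parse_newick("(A:1,B:1);")
        rng_seeds = np.random.default_rng(0).integers(2**31, size=800)
        diffs = [
            (lambda v: v["A"] - v["B"])(
                simulate_displacement(tree, DisplacementConfig(p_c=1.0, seed=int(s)))
            )
            for s in rng_seeds
        ]
        assert kstest(diffs, "norm", args=(0, np.sqrt(2))).pvalue > 0.01

    def test_pc_zero_perfectly_orders_every_replicate(self, rng):
        for _ in range(8):
            tree = simulate_yule(int(rng.integers(5, 15)), rng=rng)
            traits = simulate_displacement(
                tree, DisplacementConfig(p_c=0.0, seed=int(rng.integers(2**31)))
            )
            assert is_perfectly_orderable(tree, traits)
            assert maximize_tau(tree, traits).tau_max == pytest.approx(1.0)

    def test_median_tau_non_increasing_in_pc(self):
        tree = simulate_yule(25, seed=13)
        medians = []
        for pc in (0.0, 0.5, 1.0):
            rng = np.random.default_rng(99)
            taus = [
                maximize_tau(
                    tree,
                    simulate_displacement(
                        tree, DisplacementConfig(p_c=pc, seed=int(rng.integers(2**31)))
                    ),
                ).tau_max
                for _ in range(25)
            ]
            medians.append(np.median(taus))
        assert medians[0] == pytest.approx(1.0)
        assert medians[0] >= medians[1] >= medians[2] - 0.05

    def test_requires_ultrametric(self):
        tree = parse_newick("(A:1,B:2);")
        with pytest.raises(TreeError):
            simulate_displacement(tree, DisplacementConfig(seed=0))

    def test_seed_determinism(self, rng):
        tree = simulate_yule(10, rng=rng)
        a = simulate_displacement(tree, DisplacementConfig(p_c=0.3, seed=8))
        b = simulate_displacement(tree, DisplacementConfig(p_c=0.3, seed=8))
        assert all(a[s] == b[s] for s in a.species)


def _bm_dataset(rng, n):
    tree = simulate_yule(n, rng=rng)
    return tree, tip_table(tree, simulate_bm(tree, rng=rng))


def _balanced_newick(n):
    def build(k):
        if k == 1:
            build.i += 1
            return f"t{build.i}:0"
        half = k // 2
        return f"({build(half)}:1,{build(k - half)}:1)"

    build.i = 0
    text = build(n) + ";"
    # pad tip branches so the tree is ultrametric
    from traitorder import parse_newick as pn

    tree = pn(text)
    depths = tree.depths()
    age = max(depths.values())
    for tip in tree.tips:
        tip.length += age - depths[tip.id]
    return write_newick(tree)


def _pectinate_newick(n):
    s = "(t1:1,t2:1)"
    for i in range(3, n + 1):
        s = f"({s}:1,t{i}:{i - 1})"
    return s + ";"
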