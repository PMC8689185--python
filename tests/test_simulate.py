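import numpy as np
import pytest
from scipy import stats

from treedab.simulate import (
    GroundTruth,
    SimulationSpec,
    benchmark_grid,
    choose_effect_nodes,
    random_multifurcating_tree,
    simulate_dataset,
)


class TestRandomTree:
    @pytest.mark.parametrize("p", [10, 30, 50, 100])
    def test_benchmark_sizes_have_exact_depth_five(self, p):
        tree = random_multifurcating_tree(p, depth=5, seed=0)
        assert tree.n_leaves == p
        assert tree.depth == 5

    def test_multifurcation_present(self):
        tree = random_multifurcating_tree(12, depth=5, seed=2)
        assert any(len(n.children) > 2 for n in tree.internal_nodes)

    def test_seeded_reproducibility(self):
        t1 = random_multifurcating_tree(20, depth=4, seed=9)
        t2 = random_multifurcating_tree(20, depth=4, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_too_small_p_raises(self):
        with pytest.raises(ValueError):
            random_multifurcating_tree(4, depth=5, seed=0)

    def test_no_singular_nodes_generated(self):
        tree = random_multifurcating_tree(25, depth=5, seed=1)
        assert all(len(n.children) >= 2 for n in tree.internal_nodes)


class TestChooseEffectNodes:
    def test_three_nodes_one_internal(self, sim_tree):
        truth = choose_effect_nodes(sim_tree, seed=1)
        nodes = truth.affected_nodes[0]
        assert len(nodes) == 3
        leaf_names = set(sim_tree.leaf_names)
        assert sum(nm not in leaf_names for nm in nodes) == 1  # one internal
        internal = next(nm for nm in nodes if nm not in leaf_names)
        node = sim_tree._find(internal)
        assert all(c.is_leaf for c in node.children)  # directly above leaves

    @pytest.mark.parametrize("seed", range(8))
    def test_reference_feature_never_affected(self, sim_tree, seed):
        truth = choose_effect_nodes(sim_tree, seed=seed)
        assert sim_tree.leaf_names[-1] not in truth.affected_leaves[0]
        assert truth.labels[-1] == 0

    def test_subtrees_disjoint(self, sim_tree):
        truth = choose_effect_nodes(sim_tree, seed=3)
        cover = [sim_tree.subtree_leaves(nm) for nm in truth.affected_nodes[0]]
        flat = [lf for c in cover for lf in c]
        assert len(flat) == len(set(flat))

    def test_seeded_reproducibility(self, sim_tree):
        a = choose_effect_nodes(sim_tree, seed=5).affected_nodes
        b = choose_effect_nodes(sim_tree, seed=5).affected_nodes
        assert a == b


class TestSimulateDataset:
    def test_rows_sum_to_sequencing_depth(self, sim_tree, sim_truth):
        sim = simulate_dataset(
            SimulationSpec(p=10, n0=5, effect_size=0.5, seed=0), sim_truth, sim_tree
        )
        assert sim.Y.shape == (10, 10)
        np.testing.assert_array_equal(sim.Y.sum(axis=1), 10000)

    def test_overdispersion_rescaling_total(self):
        # concentration total is (1 - psi)/psi = 499 at the default psi
        spec = SimulationSpec(p=10, psi=0.002)
        assert (1 - spec.psi) / spec.psi == pytest.approx(499.0)

    def test_null_effect_groups_indistinguishable(self, sim_tree, sim_truth):
        """At effect 0 the two groups share one generative law: mean
        proportions of the nominally affected leaves do not differ."""
        diffs = []
        for rep in range(40):
            sim = simulate_dataset(
                SimulationSpec(p=10, n0=10, effect_size=0.0, seed=500 + rep),
                sim_truth,
                sim_tree,
            )
            props = sim.Y / sim.Y.sum(axis=1, keepdims=True)
            aff = sim.truth.labels.astype(bool)
            diffs.append(
                props[sim.X[:, 0] == 1][:, aff].mean()
                - props[sim.X[:, 0] == 0][:, aff].mean()
            )
        _, pval = stats.ttest_1samp(diffs, 0.0)
        assert pval > 0.01

    def test_group_separation_grows_with_effect(self, sim_tree, sim_truth):
        mean_gap = {}
        for beta in (0.0, 0.9):
            gaps = []
            for rep in range(25):
                sim = simulate_dataset(
                    SimulationSpec(p=10, n0=10, effect_size=beta, seed=900 + rep),
                    sim_truth,
                    sim_tree,
                )
                props = sim.Y / sim.Y.sum(axis=1, keepdims=True)
                aff = sim.truth.labels.astype(bool)
                gaps.append(
                    props[sim.X[:, 0] == 1][:, aff].mean()
                    - props[sim.X[:, 0] == 0][:, aff].mean()
                )
            mean_gap[beta] = np.mean(gaps)
        assert mean_gap[0.9] > mean_gap[0.0] + 0.01

    def test_seeded_reproducibility(self, sim_tree, sim_truth):
        spec = SimulationSpec(p=10, n0=5, effect_size=0.3, seed=123)
        a = simulate_dataset(spec, sim_truth, sim_tree)
        b = simulate_dataset(spec, sim_truth, sim_tree)
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(a.X, b.X)

    def test_second_covariate_variant(self, sim_tree, sim_truth):
        node = sim_tree.internal_nodes[0].name
        spec = SimulationSpec(
            p=10, n0=6, effect_size=0.5, seed=4, second_covariate=(3.0, node)
        )
        sim = simulate_dataset(spec, sim_truth, sim_tree)
        assert sim.X.shape == (12, 2)
        assert np.all((sim.X[:, 1] >= 0) & (sim.X[:, 1] <= 1))
        assert sim.truth.affected_nodes[1] == [node]
        assert set(sim.truth.affected_leaves[1]) == set(sim_tree.subtree_leaves(node))

    def test_root_level_variant_expressible(self, sim_tree):
        # an explicit near-root node can be the ground truth
        big = max(
            sim_tree.internal_nodes[:-1],
            key=lambda n: len(sim_tree.subtree_leaves(n.name)),
        )
        truth = GroundTruth.from_nodes(sim_tree, {0: [big.name]})
        assert truth.labels.sum() == len(sim_tree.subtree_leaves(big.name))


class TestBenchmarkGrid:
    def test_small_grid_cardinality_and_ids(self):
        out = list(
            benchmark_grid(
                p_values=(10, 12),
                n0_values=(5,),
                effect_sizes=(0.3, 0.9),
                replicates=3,
                seed=0,
            )
        )
        assert len(out) == 2 * 1 * 2 * 3
        ids = [sim.id for _, _, sim in out]
        assert len(set(ids)) == len(ids)
        assert "p10_n5_b0.3_r0" in ids

    def test_one_tree_per_p_reused(self):
        out = list(
            benchmark_grid(
                p_values=(10,), n0_values=(5, 8), effect_sizes=(0.5,), replicates=2, seed=1
            )
        )
        newicks = {tree.to_newick() for tree, _, _ in out}
        assert len(newicks) == 1

    def test_master_seed_reproduces_bit_exactly(self):
        kw = dict(p_values=(10,), n0_values=(5,), effect_sizes=(0.3,), replicates=2, seed=7)
        a = [sim.Y for _, _, sim in benchmark_grid(**kw)]
        b = [sim.Y for _, _, sim in benchmark_grid(**kw)]
        for ya, yb in zip(a, b):
            np.testing.assert_array_equal(ya, yb)
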