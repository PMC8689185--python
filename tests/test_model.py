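import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

import treedab as td
from treedab.data import ReferenceChoice, preprocess
from treedab.inference import initialize_state
from treedab.model import (
    ModelConfig,
    TreeDirMultModel,
    dirmult_logpmf,
    expand_effects,
    node_penalties,
)


@pytest.fixture()
def small_model(strong_effect_sim, sim_tree):
    ds = strong_effect_sim.to_dataset()
    return TreeDirMultModel(ds, sim_tree, ModelConfig(reference=ReferenceChoice(index=9)))


class TestNodePenalties:
    def test_phi_zero_gives_base_rate_everywhere(self):
        lam = node_penalties([1, 2, 5, 10], p=10, phi=0.0, lambda1=5.0)
        np.testing.assert_allclose(lam, 5.0)

    def test_root_values_at_strong_bias(self):
        assert node_penalties([10], 10, 10.0, 5.0)[0] == pytest.approx(
            10 / (1 + np.exp(-5)), rel=1e-6
        )  # ~9.9331
        assert node_penalties([10], 10, -10.0, 5.0)[0] == pytest.approx(
            10 / (1 + np.exp(5)), rel=1e-4
        )  # ~0.06693

    @pytest.mark.parametrize("phi,expect", [(3.0, 1), (-3.0, -1), (0.0, 0)])
    def test_monotonicity_in_subtree_size(self, phi, expect):
        lam = node_penalties(np.arange(1, 21), p=20, phi=phi, lambda1=5.0)
        diffs = np.sign(np.diff(lam))
        assert np.all(diffs == expect)

    def test_range(self):
        lam = node_penalties(np.arange(1, 51), 50, 7.0, 5.0)
        assert np.all((lam > 0) & (lam < 10.0))


class TestExpandEffects:
    def test_zero_propagates_zero(self, six_leaf_tree):
        A = six_leaf_tree.ancestor_matrix().A
        assert np.all(expand_effects(np.zeros((2, A.shape[1])), A) == 0)

    def test_internal_effect_reaches_child_leaves_only(self, six_leaf_tree):
        am = six_leaf_tree.ancestor_matrix()
        bh = np.zeros((1, am.n_nodes))
        bh[0, am.column_names.index("N3")] = 1.7
        beta = expand_effects(bh, am.A)
        np.testing.assert_allclose(beta[0], [0, 0, 0, 0, 1.7, 1.7])

    def test_leaf_block_is_identity(self, six_leaf_tree):
        am = six_leaf_tree.ancestor_matrix()
        bh = np.zeros((1, am.n_nodes))
        bh[0, :6] = np.arange(6)
        np.testing.assert_allclose(expand_effects(bh, am.A)[0], np.arange(6))


class TestDirMultLogpmf:
    def test_two_category_uniform_case(self):
        # y=(1,1), a=(1,1): Dirichlet-Multinomial with uniform Dirichlet over
        # 2 categories puts probability 1/3 on each composition of N=2
        assert dirmult_logpmf([1, 1], [1, 1]) == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_single_category_is_certain(self):
        assert dirmult_logpmf([7], [2.3]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            p = rng.integers(2, 5)
            y = rng.integers(0, 6, size=p)
            a = rng.uniform(0.2, 5.0, size=p)
            expected = stats.dirichlet_multinomial.logpmf(y, alpha=a, n=int(y.sum()))
            assert dirmult_logpmf(y, a) == pytest.approx(expected, abs=1e-10)

    def test_large_concentration_approaches_multinomial(self):
        y = np.array([3, 1, 1])
        pi = np.array([0.5, 0.3, 0.2])
        lp = dirmult_logpmf(y, 1e6 * pi)
        lp_mult = stats.multinomial.logpmf(y, n=5, p=pi)
        assert abs(lp - lp_mult) < 1e-3

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            dirmult_logpmf([1, 1], [1.0, 0.0])


class TestJointLogDensity:
    def test_finite_on_random_state(self, small_model):
        state = initialize_state(small_model, 0)
        assert np.isfinite(small_model.joint_log_density(state))

    def test_term_by_term_oracle(self, small_model):
        """Each additive term matches an independent scipy evaluation."""
        m = small_model
        state = initialize_state(m, 1)
        state.sigma = np.exp(np.random.default_rng(2).normal(size=state.sigma.shape) * 0.3)
        state.theta = 0.37
        terms = m.log_density_terms(state)

        beta = state.beta_hat_free() @ m.A_free.T
        a = np.exp(state.alpha[None, :] + m.X @ beta)
        lik = sum(dirmult_logpmf(m.Y[i], a[i]) for i in range(m.Y.shape[0]))
        assert terms["likelihood"] == pytest.approx(lik, abs=1e-8)

        assert terms["alpha_prior"] == pytest.approx(
            stats.norm.logpdf(state.alpha, scale=np.sqrt(10)).sum(), abs=1e-8
        )
        assert terms["b_prior"] == pytest.approx(
            stats.norm.logpdf(state.b).sum(), abs=1e-8
        )
        sp = stats.expon.logpdf(state.sigma[0], scale=1 / m.rate0).sum()
        sp += stats.expon.logpdf(state.sigma[1], scale=1 / m.rate1[None, :]).sum()
        assert terms["sigma_prior"] == pytest.approx(sp, abs=1e-8)
        assert terms["theta_prior"] == pytest.approx(
            stats.beta.logpdf(state.theta, 1.0, m.theta_beta_b), abs=1e-8
        )

    def test_gradient_matches_finite_differences(self, small_model):
        m = small_model
        z = m.pack(initialize_state(m, 3))
        lp, grad = m.log_density_and_grad(z)
        assert lp == pytest.approx(m.log_density(z), abs=1e-8)
        rng = np.random.default_rng(0)
        idx = rng.choice(len(z), size=25, replace=False)
        eps = 1e-6
        for i in idx:
            e = np.zeros_like(z)
            e[i] = eps
            num = (m.log_density(z + e) - m.log_density(z - e)) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-3)

    def test_compositional_invariance_of_expected_proportions(self, small_model):
        """Adding a constant to all log-concentrations leaves proportions unchanged."""
        m = small_model
        state = initialize_state(m, 4)
        beta = state.beta_hat_free() @ m.A_free.T
        loga = state.alpha[None, :] + m.X @ beta
        probs = np.exp(loga) / np.exp(loga).sum(axis=1, keepdims=True)
        loga_shifted = loga + 3.7
        probs2 = np.exp(loga_shifted) / np.exp(loga_shifted).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(probs, probs2, atol=1e-12)

    def test_masked_columns_are_structural_zeros(self, small_model):
        m = small_model
        state = initialize_state(m, 5)
        full = m.beta_hat_full(state)
        assert np.all(full[:, m.masked_idx] == 0.0)
        # the masked set is the reference leaf and its ancestors up to the root
        assert 9 in m.masked_idx  # reference leaf column
        assert m.v - 1 in m.masked_idx  # root column (last)
        # propagation agrees whether masked entries are zeros or omitted
        via_full = expand_effects(full, m.A)
        via_free = state.beta_hat_free() @ m.A_free.T
        np.testing.assert_allclose(via_full, via_free, atol=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="lambda0"):
            ModelConfig(lambda0=5.0, lambda1=50.0)

    def test_feature_mismatch_rejected(self, sim_tree, strong_effect_sim):
        ds = strong_effect_sim.to_dataset()
        ds.feature_names = list(reversed(ds.feature_names))
        with pytest.raises(ValueError, match="leaves"):
            TreeDirMultModel(ds, sim_tree, ModelConfig(reference=ReferenceChoice(index=9)))
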