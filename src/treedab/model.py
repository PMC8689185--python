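"""Tree-aggregated Dirichlet-Multinomial regression model.

The observation model for sample ``i`` with covariate row ``x_i`` is

    Y_i ~ DirMult(N_i, a(x_i)),      log a(x_i) = alpha + x_i beta,

where ``alpha`` (length ``p``) is the base log-composition and ``beta``
(shape ``d x p``) are leaf-level covariate effects.  Effects are not sampled
per leaf but per tree node: a node-effect matrix ``beta_hat`` (``d x v``) is
propagated to the leaves through the ancestor matrix, ``beta = beta_hat @
A.T``, so one credible entry on an internal node moves its whole subtree.

Sparsity comes from a spike-and-slab lasso prior on each ``beta_hat``
entry: a mixture, weighted by a shared ``theta``, of two components that are
each an Exponential-scale times a standard normal — a "spike" with a large
rate ``lambda0`` (default 50) that crushes negligible effects and a "slab"
with a small rate (base ``lambda1``, default 5) that leaves real effects
lightly penalised.  The slab rate is scaled per node by a sigmoid in the
subtree leaf fraction with gain ``phi``: ``phi < 0`` favours aggregated
effects near the root, ``phi > 0`` favours detailed leaf-level effects,
``phi = 0`` treats all nodes alike.

One reference feature is constrained to be unaffected by all covariates:
its column and all of its ancestors' columns (the root included) are masked
out of ``beta_hat`` entirely — those parameters are never sampled.

Everything here is pure math on in-memory arrays; the gradient of the joint
log density (needed by Hamiltonian Monte Carlo) is derived analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, digamma, expit

from .data import CompositionalDataset, ReferenceChoice
from .trees import Hierarchy

_ALPHA_VAR = 10.0  # prior variance of each alpha_j


@dataclass
class ModelConfig:
    """Hyperparameters and reference masking for the regression model.

    ``lambda0 > lambda1 > 0`` is required: the spike must penalise harder
    than the slab.  ``reference`` is a :class:`ReferenceChoice` (leaf index
    into the feature axis); ``masked_names`` is filled in when the config is
    bound to a tree.
    """

    lambda0: float = 50.0
    lambda1: float = 5.0
    phi: float = 0.0
    reference: ReferenceChoice | None = None
    masked_names: list = field(default_factory=list)

    def __post_init__(self):
        if not (self.lambda0 > self.lambda1 > 0):
            raise ValueError("need lambda0 > lambda1 > 0")


@dataclass
class ParameterState:
    """Latent variables of the model (free-node parameterisation).

    ``b`` and ``sigma`` have shape ``(2, d, v_free)``; index 0 is the spike
    component, index 1 the slab.  ``beta_hat`` on free nodes is
    ``theta * sigma[1] * b[1] + (1 - theta) * sigma[0] * b[0]``; masked nodes
    are structurally zero.
    """

    alpha: np.ndarray
    b: np.ndarray
    sigma: np.ndarray
    theta: float

    def beta_hat_free(self) -> np.ndarray:
        return self.theta * self.sigma[1] * self.b[1] + (1.0 - self.theta) * (
            self.sigma[0] * self.b[0]
        )

    def validate(self):
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must lie strictly inside (0, 1)")


def node_penalties(leaf_counts, p: int, phi: float, lambda1: float) -> np.ndarray:
    """Node-adaptive slab rates: ``2*lambda1 * sigmoid(phi * (L_k/p - 0.5))``.

    Identical across covariates; values lie in ``(0, 2*lambda1)``.  At
    ``phi = 0`` every node receives the base rate ``lambda1``.
    """
    L = np.asarray(leaf_counts, dtype=float)
    return 2.0 * lambda1 * expit(phi * (L / p - 0.5))


def expand_effects(beta_hat: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Propagate node effects to the leaves: ``beta = beta_hat @ A.T``.

    A leaf's effect is the sum of the effects on itself and on all of its
    ancestors.
    """
    beta_hat = np.atleast_2d(np.asarray(beta_hat, dtype=float))
    return beta_hat @ np.asarray(A, dtype=float).T


def dirmult_logpmf(y, a) -> float:
    """Dirichlet-Multinomial log-pmf of count vector ``y`` at concentration ``a``.

    Computed via log-gamma for numerical stability:

        log C(N; y) + lgam(A) - lgam(N + A) + sum_j [lgam(y_j + a_j) - lgam(a_j)]

    with ``N = sum(y)`` and ``A = sum(a)``.  Accepts non-integer ``y`` (e.g.
    pseudo-counted data); the combinatorial term then uses gamma functions.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("concentration parameters must be strictly positive")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    N = y.sum(axis=-1)
    A = a.sum(axis=-1)
    out = (
        gammaln(N + 1.0)
        - gammaln(y + 1.0).sum(axis=-1)
        + gammaln(A)
        - gammaln(N + A)
        + (gammaln(y + a) - gammaln(a)).sum(axis=-1)
    )
    return float(out) if out.ndim == 0 else out


class TreeDirMultModel:
    """Joint log density (and gradient) of the model on a given dataset.

    Binds a preprocessed dataset, a normalised hierarchy, and a
    :class:`ModelConfig`; resolves the reference mask; and exposes the joint
    log density both per parameter block (for diagnostics) and as a single
    differentiable function of a flat unconstrained vector, using ``log
    sigma`` and ``logit theta`` reparameterisations with the corresponding
    Jacobian terms.
    """

    def __init__(
        self,
        dataset: CompositionalDataset,
        tree: Hierarchy,
        config: ModelConfig,
    ):
        if tree.leaf_names != dataset.feature_names:
            raise ValueError(
                "tree leaves and dataset features disagree (order matters); "
                "align the dataset with CompositionalDataset.reorder_features"
            )
        if config.reference is None:
            raise ValueError("ModelConfig.reference must be set before model build")
        self.dataset = dataset
        self.tree = tree
        self.config = config

        am = tree.ancestor_matrix()
        self.A = am.A.astype(float)
        self.node_names = am.column_names
        self.leaf_counts = am.leaf_counts
        p = tree.n_leaves
        self.p = p
        self.v = am.n_nodes
        self.d = dataset.n_covariates

        ref_idx = config.reference.index
        ref_name = tree.leaf_names[ref_idx]
        masked_names = [ref_name] + tree.ancestor_names(ref_name)
        name_to_col = {nm: k for k, nm in enumerate(self.node_names)}
        self.masked_idx = np.array(sorted(name_to_col[nm] for nm in masked_names))
        self.free_idx = np.array(
            [k for k in range(self.v) if k not in set(self.masked_idx)]
        )
        config.masked_names = masked_names
        self.v_free = len(self.free_idx)
        self.A_free = self.A[:, self.free_idx]

        lam_all = node_penalties(self.leaf_counts, p, config.phi, config.lambda1)
        self.lambda1_k = lam_all[self.free_idx]  # slab rate per free node
        self.rate1 = self.lambda1_k**2 / 2.0  # Exponential rates
        self.rate0 = config.lambda0**2 / 2.0
        # Mixture-weight prior theta ~ Beta(1, |v \ vhat|).  Scaling the
        # second parameter with the number of free nodes is what gives the
        # spike-and-slab lasso its automatic multiplicity control: with more
        # candidate nodes the prior expects a smaller slab fraction, keeping
        # the practical-significance threshold delta_k positive and the
        # selection sparse.
        self.theta_beta_b = float(self.v_free)

        self.Y = dataset.Y
        self.X = dataset.X
        self.N = self.Y.sum(axis=1)
        self._y_const = float(
            np.sum(gammaln(self.N + 1.0)) - np.sum(gammaln(self.Y + 1.0))
        )

    # -- parameter packing ------------------------------------------------

    @property
    def dim(self) -> int:
        return self.p + 4 * self.d * self.v_free + 1

    def pack(self, state: ParameterState) -> np.ndarray:
        z = np.concatenate(
            [
                state.alpha,
                state.b.ravel(),
                np.log(state.sigma).ravel(),
                [np.log(state.theta) - np.log1p(-state.theta)],
            ]
        )
        return z

    def unpack(self, z: np.ndarray) -> ParameterState:
        p, d, vf = self.p, self.d, self.v_free
        k = d * vf
        alpha = z[:p]
        b = z[p : p + 2 * k].reshape(2, d, vf)
        sigma = np.exp(z[p + 2 * k : p + 4 * k].reshape(2, d, vf))
        theta = float(expit(z[-1]))
        return ParameterState(alpha=alpha, b=b, sigma=sigma, theta=theta)

    def beta_hat_full(self, state: ParameterState) -> np.ndarray:
        """Full ``d x v`` node-effect matrix with masked columns at exactly 0."""
        out = np.zeros((self.d, self.v))
        out[:, self.free_idx] = state.beta_hat_free()
        return out

    # -- log density ------------------------------------------------------

    def log_density_terms(self, state: ParameterState) -> dict:
        """The five additive terms of the joint log density, by name."""
        bh = state.beta_hat_free()
        beta = bh @ self.A_free.T  # d x p
        loga = state.alpha[None, :] + self.X @ beta
        if not np.all(np.isfinite(loga)) or loga.max() > 250.0 or loga.min() < -250.0:
            lik = -np.inf
        else:
            a = np.exp(loga)
            Arow = a.sum(axis=1)
            lik = self._y_const + float(
                np.sum(gammaln(Arow) - gammaln(self.N + Arow))
                + np.sum(gammaln(self.Y + a) - gammaln(a))
            )
        terms = {
            "likelihood": lik,
            "alpha_prior": float(
                -0.5 * np.sum(state.alpha**2) / _ALPHA_VAR
                - 0.5 * self.p * np.log(2 * np.pi * _ALPHA_VAR)
            ),
            "b_prior": float(
                -0.5 * np.sum(state.b**2) - 0.5 * state.b.size * np.log(2 * np.pi)
            ),
            "sigma_prior": float(
                np.sum(np.log(self.rate0) - self.rate0 * state.sigma[0])
                + np.sum(np.log(self.rate1)[None, :] - self.rate1[None, :] * state.sigma[1])
            ),
            "theta_prior": float(
                np.log(self.theta_beta_b)
                + (self.theta_beta_b - 1.0) * np.log1p(-state.theta)
            ),
        }
        return terms

    def joint_log_density(self, state: ParameterState) -> float:
        """Sum of likelihood and all prior terms (constrained space, no Jacobians)."""
        state.validate()
        terms = self.log_density_terms(state)
        total = sum(terms.values())
        if not np.isfinite(total):
            bad = [k for k, t in terms.items() if not np.isfinite(t)]
            import logging

            logging.getLogger(__name__).warning(
                "non-finite joint log density; offending terms: %s", bad
            )
        return total

    def log_density(self, z: np.ndarray) -> float:
        """Unconstrained-space target: joint log density + Jacobian terms."""
        p, d, vf = self.p, self.d, self.v_free
        k = d * vf
        if np.any(np.abs(z[p + 2 * k :]) > 50.0):
            return -np.inf
        state = self.unpack(z)
        s = z[p + 2 * k : p + 4 * k]
        u = z[-1]
        # log|dsigma/ds| = s per entry; log|dtheta/du| = log theta + log(1-theta)
        jac = float(np.sum(s)) - np.logaddexp(0.0, -u) - np.logaddexp(0.0, u)
        return sum(self.log_density_terms(state).values()) + jac

    def log_density_and_grad(self, z: np.ndarray):
        """Value and analytic gradient of :meth:`log_density`."""
        p, d, vf = self.p, self.d, self.v_free
        k = d * vf
        # Reject states outside a numerically safe box (leapfrog divergences):
        # |log sigma| or |logit theta| beyond ~50 would overflow downstream.
        if np.any(np.abs(z[p + 2 * k :]) > 50.0):
            return -np.inf, np.zeros_like(z)
        alpha = z[:p]
        b = z[p : p + 2 * k].reshape(2, d, vf)
        s = z[p + 2 * k : p + 4 * k].reshape(2, d, vf)
        sigma = np.exp(s)
        u = z[-1]
        theta = expit(u)

        bh = theta * sigma[1] * b[1] + (1.0 - theta) * sigma[0] * b[0]
        beta = bh @ self.A_free.T
        loga = alpha[None, :] + self.X @ beta
        # exp and row sums must stay well inside float range
        if not np.all(np.isfinite(loga)) or loga.max() > 250.0 or loga.min() < -250.0:
            return -np.inf, np.zeros_like(z)
        a = np.exp(loga)

        Arow = a.sum(axis=1)
        Y, N = self.Y, self.N
        lik = self._y_const + float(
            np.sum(gammaln(Arow) - gammaln(N + Arow))
            + np.sum(gammaln(Y + a) - gammaln(a))
        )
        # d lik / d a_ij, then chain through a = exp(log a)
        g = (
            digamma(Arow)[:, None]
            - digamma(N + Arow)[:, None]
            + digamma(Y + a)
            - digamma(a)
        )
        G = g * a  # n x p: d lik / d log a

        grad_alpha = G.sum(axis=0) - alpha / _ALPHA_VAR
        C = (self.X.T @ G) @ self.A_free  # d x vf: d lik / d beta_hat

        grad_b1 = C * (theta * sigma[1]) - b[1]
        grad_b0 = C * ((1.0 - theta) * sigma[0]) - b[0]
        # d/d sigma, chained to s = log sigma (+1 from the Jacobian term)
        grad_s1 = (C * (theta * b[1]) - self.rate1[None, :]) * sigma[1] + 1.0
        grad_s0 = (C * ((1.0 - theta) * b[0]) - self.rate0) * sigma[0] + 1.0

        dtheta = float(
            np.sum(C * (sigma[1] * b[1] - sigma[0] * b[0]))
            - (self.theta_beta_b - 1.0) / (1.0 - theta)
        )
        grad_u = theta * (1.0 - theta) * dtheta + (1.0 - 2.0 * theta)

        logp = (
            lik
            - 0.5 * float(np.sum(alpha**2)) / _ALPHA_VAR
            - 0.5 * p * np.log(2 * np.pi * _ALPHA_VAR)
            - 0.5 * float(np.sum(b**2))
            - 0.5 * b.size * np.log(2 * np.pi)
            + float(np.sum(np.log(self.rate0) - self.rate0 * sigma[0]))
            + float(np.sum(np.log(self.rate1)[None, :] - self.rate1[None, :] * sigma[1]))
            + np.log(self.theta_beta_b)
            + (self.theta_beta_b - 1.0) * np.log1p(-theta)
            + float(np.sum(s))
            - np.logaddexp(0.0, -u)
            - np.logaddexp(0.0, u)
        )
        grad = np.concatenate(
            [
                grad_alpha,
                np.stack([grad_b0, grad_b1]).ravel(),
                np.stack([grad_s0, grad_s1]).ravel(),
                [grad_u],
            ]
        )
        return logp, grad


def joint_log_density(
    state: ParameterState,
    dataset: CompositionalDataset,
    tree: Hierarchy,
    config: ModelConfig,
) -> float:
    """Joint log density of a parameter state under the full model."""
    return TreeDirMultModel(dataset, tree, config).joint_log_density(state)
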