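"""Sparse credible effects and the differential-abundance set.

Posterior medians of the node effects are compared against a per-node
threshold of practical significance, the effect magnitude at which the
posterior odds of slab versus spike membership cross even:

    p*(0)   = theta* lambda1_k / (theta* lambda1_k + (1 - theta*) lambda0)
    delta_k = log(1 / p*(0) - 1) / (lambda0 - lambda1_k)

with ``theta*`` the posterior median of the mixture weight.  Node effects
with ``|median| > delta_k`` are kept (strict inequality), everything else is
set to exactly zero.  The credible matrix propagated through the ancestor
matrix yields the set of differentially abundant (covariate, feature) pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import Trace
from .model import TreeDirMultModel, expand_effects, node_penalties


def practical_significance_threshold(theta_star, lambda0, lambda1_k):
    """Per-node credibility threshold ``delta_k`` (vectorised over nodes)."""
    theta_star = float(theta_star)
    if not (0.0 < theta_star < 1.0):
        raise ValueError("theta* must lie strictly inside (0, 1)")
    lam1 = np.asarray(lambda1_k, dtype=float)
    if np.any(lam1 <= 0) or np.any(lambda0 <= lam1):
        raise ValueError("need lambda0 > lambda1_k > 0")
    p0 = theta_star * lam1 / (theta_star * lam1 + (1.0 - theta_star) * lambda0)
    delta = np.log(1.0 / p0 - 1.0) / (lambda0 - lam1)
    return float(delta) if np.ndim(lambda1_k) == 0 else delta


def credible_effects(trace: Trace, delta) -> np.ndarray:
    """Threshold posterior median node effects at ``delta`` per node.

    Returns the ``d x v`` credible matrix: entries are either 0 or the
    posterior median.  Equality with the threshold counts as not credible.
    """
    med = trace.beta_hat_median()
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (med.shape[1],))
    keep = np.abs(med) > delta[None, :]
    return np.where(keep, med, 0.0)


def differential_features(beta_credible: np.ndarray, A: np.ndarray) -> set:
    """Set of (covariate index, feature index) pairs with nonzero leaf effect."""
    leaf = expand_effects(beta_credible, A)
    ls, js = np.nonzero(leaf)
    return set(zip(ls.tolist(), js.tolist()))


def expected_counts(alpha, beta, x_row, total) -> np.ndarray:
    """Dirichlet-Multinomial expectation: ``total * softmax(alpha + x beta)``.

    ``beta`` is leaf-level (``d x p``); the output sums to ``total``.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    alpha = np.asarray(alpha, dtype=float)
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    x_row = np.atleast_1d(np.asarray(x_row, dtype=float))
    loga = alpha + x_row @ beta
    loga = loga - loga.max()
    w = np.exp(loga)
    return total * w / w.sum()


@dataclass
class EffectResult:
    """Full selection output for one fitted model.

    ``beta_credible`` keeps only node effects whose posterior median exceeds
    the node's practical-significance threshold; ``leaf_effects`` is its
    propagation to the leaves; ``differential_set`` the support of the
    latter.  Effect sizes are comparable within this run only, not across
    runs (the compositional scale is anchored by the run's reference).
    """

    beta_hat_median: np.ndarray  # d x v
    theta_median: float
    delta: np.ndarray  # per node (v,)
    beta_credible: np.ndarray  # d x v
    leaf_effects: np.ndarray  # d x p
    differential_set: set
    node_names: list = field(default_factory=list)
    feature_names: list = field(default_factory=list)
    covariate_names: list = field(default_factory=list)
    leaf_counts: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def node_table(self) -> pd.DataFrame:
        """One row per (covariate, node): median effect, threshold, credibility."""
        p = len(self.feature_names)
        rows = []
        for l, cov in enumerate(self.covariate_names):
            for k, node in enumerate(self.node_names):
                rows.append(
                    {
                        "covariate": cov,
                        "node": node,
                        "node_type": "leaf" if k < p else "internal",
                        "subtree_leaves": (
                            int(self.leaf_counts[k]) if self.leaf_counts is not None else None
                        ),
                        "median_effect": self.beta_hat_median[l, k],
                        "delta": self.delta[k],
                        "credible": bool(self.beta_credible[l, k] != 0.0),
                        "credible_effect": self.beta_credible[l, k],
                    }
                )
        return pd.DataFrame(rows)

    def leaf_table(self) -> pd.DataFrame:
        """One row per (covariate, feature): propagated credible effect."""
        rows = []
        for l, cov in enumerate(self.covariate_names):
            for j, feat in enumerate(self.feature_names):
                rows.append(
                    {
                        "covariate": cov,
                        "feature": feat,
                        "leaf_effect": self.leaf_effects[l, j],
                        "differential": (l, j) in self.differential_set,
                    }
                )
        return pd.DataFrame(rows)

    def differential_json(self) -> str:
        pairs = sorted(
            [self.covariate_names[l], self.feature_names[j]]
            for (l, j) in self.differential_set
        )
        return json.dumps(
            {
                "differential_features": pairs,
                "theta_median": self.theta_median,
                "note": "effect sizes are not comparable across runs",
            },
            indent=2,
        )


def select_effects(trace: Trace, model: TreeDirMultModel) -> EffectResult:
    """Turn a posterior trace into sparse credible effects and the set D."""
    theta_star = trace.theta_median()
    lam_full = node_penalties(
        model.leaf_counts, model.p, model.config.phi, model.config.lambda1
    )
    delta = practical_significance_threshold(theta_star, model.config.lambda0, lam_full)
    beta_cred = credible_effects(trace, delta)
    beta_cred[:, model.masked_idx] = 0.0  # structural zeros stay zero
    leaf = expand_effects(beta_cred, model.A)
    D = differential_features(beta_cred, model.A)
    return EffectResult(
        beta_hat_median=trace.beta_hat_median(),
        theta_median=theta_star,
        delta=delta,
        beta_credible=beta_cred,
        leaf_effects=leaf,
        differential_set=D,
        node_names=model.node_names,
        feature_names=model.dataset.feature_names,
        covariate_names=model.dataset.covariate_names,
        leaf_counts=model.leaf_counts,
        metadata={
            "lambda0": model.config.lambda0,
            "lambda1": model.config.lambda1,
            "phi": model.config.phi,
            "reference": model.node_names[model.config.reference.index],
            "note": "effect sizes are not comparable across runs",
        },
    )
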