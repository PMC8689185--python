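"""scikit-learn style front end for the tree-aggregated regression model.

``TreeCompositionalRegressor`` follows the estimator contract: all
hyperparameters are constructor arguments, ``fit(X, Y)`` learns fitted
attributes with trailing underscores, ``predict(X)`` returns expected count
compositions, and ``get_params``/``set_params``/``clone`` work for pipeline
and model-selection use (e.g. cross-validating the aggregation bias ``phi``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import ReferenceChoice, preprocess, select_reference
from .evaluate import msle, predict_counts
from .inference import SamplerConfig, sample_posterior
from .model import ModelConfig, TreeDirMultModel
from .selection import select_effects
from .trees import Hierarchy, parse_newick


class TreeCompositionalRegressor(BaseEstimator):
    """Bayesian tree-aggregated Dirichlet-Multinomial regression.

    Parameters
    ----------
    tree : Hierarchy or newick str
        Feature hierarchy; leaves must match the count-table columns.
    lambda0, lambda1 : float
        Spike and base slab rates of the spike-and-slab lasso prior
        (``lambda0 > lambda1 > 0``).
    phi : float
        Aggregation bias: negative favours effects near the root, positive
        favours leaf-level effects, 0 is neutral.
    reference : "auto", str or int
        Reference feature (assumed unaffected by all covariates).  "auto"
        selects the least-dispersed feature present in at least
        ``presence_threshold`` of samples.
    num_samples, burn_in, leapfrog_steps, algorithm, target_accept, seed
        Sampler settings; defaults are a 20,000-draw HMC chain with 5,000
        burn-in and 10 leapfrog steps.

    Attributes
    ----------
    trace_ : Trace
        Post-burn-in posterior draws.
    result_ : EffectResult
        Credible node effects, thresholds and the differential set.
    alpha_star_ : ndarray of shape (p,)
        Posterior mean base log-composition (used for prediction).
    beta_leaf_ : ndarray of shape (d, p)
        Credible leaf-propagated effects.
    reference_index_ : int
        Column index of the reference feature.
    """

    def __init__(
        self,
        tree=None,
        lambda0: float = 50.0,
        lambda1: float = 5.0,
        phi: float = 0.0,
        reference="auto",
        presence_threshold: float = 0.95,
        num_samples: int = 20000,
        burn_in: int = 5000,
        leapfrog_steps: int = 10,
        algorithm: str = "hmc",
        target_accept: float = 0.75,
        seed: int | None = None,
    ):
        self.tree = tree
        self.lambda0 = lambda0
        self.lambda1 = lambda1
        self.phi = phi
        self.reference = reference
        self.presence_threshold = presence_threshold
        self.num_samples = num_samples
        self.burn_in = burn_in
        self.leapfrog_steps = leapfrog_steps
        self.algorithm = algorithm
        self.target_accept = target_accept
        self.seed = seed

    # -- helpers ----------------------------------------------------------

    def _resolve_tree(self) -> Hierarchy:
        if isinstance(self.tree, Hierarchy):
            return self.tree.normalize()
        if isinstance(self.tree, str):
            return parse_newick(self.tree).normalize()
        raise ValueError("tree must be a Hierarchy or a newick string")

    def _resolve_reference(self, Y_raw: np.ndarray, feature_names) -> ReferenceChoice:
        if isinstance(self.reference, str) and self.reference != "auto":
            if self.reference not in feature_names:
                raise ValueError(f"reference feature {self.reference!r} not found")
            idx = feature_names.index(self.reference)
            return ReferenceChoice(index=idx, name=self.reference)
        if isinstance(self.reference, (int, np.integer)):
            return ReferenceChoice(
                index=int(self.reference), name=feature_names[int(self.reference)]
            )
        return select_reference(
            Y_raw, self.presence_threshold, feature_names=feature_names
        )

    # -- estimator contract ----------------------------------------------

    def fit(self, X, Y):
        """Fit the model: X are covariates (n x d), Y raw counts (n x p).

        ``X=None`` fits an intercept-only model (d = 0).  DataFrame inputs
        contribute their column names; count columns are aligned to the
        tree's leaf order by name when names are available.
        """
        tree = self._resolve_tree()

        feature_names = None
        if isinstance(Y, pd.DataFrame):
            feature_names = list(Y.columns.astype(str))
        Y_raw = np.asarray(Y, dtype=float)
        n = Y_raw.shape[0]
        if X is None:
            X = np.zeros((n, 0))

        ds = preprocess(Y, X, feature_names=feature_names)
        if feature_names is not None:
            ds = ds.reorder_features(tree.leaf_names)
            order = [feature_names.index(nm) for nm in tree.leaf_names]
            Y_raw = Y_raw[:, order]
        elif ds.n_features != tree.n_leaves:
            raise ValueError("count table width does not match the tree's leaf count")
        else:
            ds.feature_names = tree.leaf_names

        ref = self._resolve_reference(Y_raw, ds.feature_names)
        model_config = ModelConfig(
            lambda0=self.lambda0,
            lambda1=self.lambda1,
            phi=self.phi,
            reference=ref,
        )
        sampler_config = SamplerConfig(
            num_samples=self.num_samples,
            burn_in=self.burn_in,
            leapfrog_steps=self.leapfrog_steps,
            algorithm=self.algorithm,
            target_accept=self.target_accept,
            seed=self.seed,
        )
        self.trace_ = sample_posterior(ds, tree, model_config, sampler_config)
        self.model_ = TreeDirMultModel(ds, tree, model_config)
        self.result_ = select_effects(self.trace_, self.model_)
        self.alpha_star_ = self.trace_.alpha.mean(axis=0)
        self.beta_leaf_ = self.result_.leaf_effects
        self.differential_set_ = self.result_.differential_set
        self.reference_index_ = ref.index
        self.tree_ = tree
        self.dataset_ = ds
        self.feature_names_ = ds.feature_names
        self.mean_total_ = float(ds.row_totals.mean())
        self.n_features_in_ = ds.n_covariates
        return self

    def predict(self, X) -> np.ndarray:
        """Expected counts per sample at the mean training sequencing depth."""
        if not hasattr(self, "trace_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float) if X is not None else np.zeros((1, 0))
        if X.ndim == 1:
            X = X[:, None]
        return np.vstack(
            [
                predict_counts(self.alpha_star_, self.beta_leaf_, row, self.mean_total_)
                for row in X
            ]
        )

    def score(self, X, Y) -> float:
        """Negative mean squared logarithmic error of predicted counts."""
        Y = np.asarray(Y, dtype=float)
        pred = self.predict(X)
        return -float(np.mean([msle(Y[i], pred[i]) for i in range(len(Y))]))

    # -- convenience ------------------------------------------------------

    def effects(self) -> pd.DataFrame:
        """Node-level effect table of the fitted model."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        return self.result_.node_table()

    def differential_features(self) -> list:
        """Names of (covariate, feature) pairs in the differential set."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        r = self.result_
        return sorted(
            (r.covariate_names[l], r.feature_names[j]) for (l, j) in r.differential_set
        )
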