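"""Count/covariate ingestion, preprocessing, and reference-feature selection.

Count tables are samples x features, non-negative integers.  Preprocessing
replaces zero counts with a 0.5 pseudo-count (the per-sample totals used by
the likelihood are recorded from the raw counts first) and puts covariates on
a common scale: non-binary columns are min-max scaled to [0, 1], binary 0/1
columns pass through.

Because the data are compositional, the model needs a reference feature that
is assumed unchanged by every covariate.  When none is known a priori, the
reference is chosen automatically as the feature with minimal dispersion of
its relative abundance among features present in at least a given share of
samples (default 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CompositionalDataset:
    """Preprocessed count + covariate data.

    Attributes
    ----------
    Y : ndarray of shape (n, p)
        Counts after pseudo-counting: strictly positive, zeros hold 0.5.
    X : ndarray of shape (n, d)
        Covariates after scaling to a common range.
    row_totals : ndarray of shape (n,)
        Per-sample totals of the *raw* counts (the Dirichlet-Multinomial
        size parameters).
    """

    Y: np.ndarray
    X: np.ndarray
    row_totals: np.ndarray
    sample_ids: list = field(default_factory=list)
    feature_names: list = field(default_factory=list)
    covariate_names: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_features(self) -> int:
        return self.Y.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def reorder_features(self, order: list) -> "CompositionalDataset":
        """Return a copy with feature columns permuted to ``order`` (names)."""
        missing = set(order) - set(self.feature_names)
        extra = set(self.feature_names) - set(order)
        if missing or extra:
            raise ValueError(
                "feature name mismatch; "
                f"missing from data: {sorted(missing)}; not in target: {sorted(extra)}"
            )
        idx = [self.feature_names.index(nm) for nm in order]
        return CompositionalDataset(
            Y=self.Y[:, idx],
            X=self.X,
            row_totals=self.row_totals,
            sample_ids=list(self.sample_ids),
            feature_names=list(order),
            covariate_names=list(self.covariate_names),
        )


@dataclass
class ReferenceChoice:
    """Automatically (or manually) selected reference feature.

    ``index`` is a leaf/column index into the feature axis.  For automatic
    selection, candidates are features present (raw count > 0) in at least
    ``presence_threshold`` of samples; among those the one with minimal
    dispersion wins, ties broken by lowest column index.
    """

    index: int
    presence_threshold: float = 0.95
    dispersion_scores: np.ndarray | None = None
    name: str | None = None


def _is_binary(col: np.ndarray) -> bool:
    return set(np.unique(col)).issubset({0.0, 1.0})


def preprocess(
    Y,
    X,
    sample_ids=None,
    feature_names=None,
    covariate_names=None,
) -> CompositionalDataset:
    """Validate and preprocess raw counts and covariates.

    Accepts DataFrames (names taken from index/columns) or arrays.  Raw
    counts must be non-negative integers; covariates numeric with no missing
    values (drop incomplete samples upstream).  Constant covariate columns
    are rejected because min-max scaling is undefined for them.
    """
    if isinstance(Y, pd.DataFrame):
        sample_ids = sample_ids or list(Y.index.astype(str))
        feature_names = feature_names or list(Y.columns.astype(str))
        Y = Y.to_numpy()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-dimensional (samples x features)")
    if np.any(Y < 0) or not np.allclose(Y, np.round(Y)):
        raise ValueError("raw counts must be non-negative integers")

    if isinstance(X, pd.DataFrame):
        covariate_names = covariate_names or list(X.columns.astype(str))
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("Y and X disagree on the number of samples")
    if np.any(~np.isfinite(X)):
        raise ValueError("covariates contain missing/non-finite values")

    n, p = Y.shape
    d = X.shape[1]
    sample_ids = list(sample_ids) if sample_ids else [f"S{i}" for i in range(n)]
    feature_names = (
        list(feature_names) if feature_names else [f"F{j}" for j in range(p)]
    )
    covariate_names = (
        list(covariate_names) if covariate_names else [f"x{l}" for l in range(d)]
    )

    row_totals = Y.sum(axis=1)
    Yp = Y.copy()
    Yp[Yp == 0] = 0.5

    Xs = X.astype(float).copy()
    for l in range(d):
        col = Xs[:, l]
        if _is_binary(col):
            continue
        lo, hi = col.min(), col.max()
        if hi == lo:
            raise ValueError(
                f"covariate {covariate_names[l]!r} is constant; min-max scaling undefined"
            )
        Xs[:, l] = (col - lo) / (hi - lo)

    return CompositionalDataset(
        Y=Yp,
        X=Xs,
        row_totals=row_totals,
        sample_ids=sample_ids,
        feature_names=feature_names,
        covariate_names=covariate_names,
    )


def select_reference(
    Y,
    presence_threshold: float = 0.95,
    feature_names=None,
) -> ReferenceChoice:
    """Pick the least-dispersed sufficiently-present feature as reference.

    Presence is computed on raw zeros (before pseudo-counting).  Dispersion
    is the variance across samples of the feature's relative abundance
    (count / raw row total), which makes the score independent of sequencing
    depth.
    """
    if isinstance(Y, pd.DataFrame):
        feature_names = feature_names or list(Y.columns.astype(str))
        Y = Y.to_numpy()
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    totals = Y.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("samples with zero total count")
    props = Y / totals[:, None]
    disp = props.var(axis=0)
    presence = (Y > 0).mean(axis=0)
    candidates = presence >= presence_threshold
    if not candidates.any():
        raise ValueError(
            f"no feature is present in at least {presence_threshold:.0%} of samples; "
            "lower the presence threshold or set the reference manually"
        )
    masked = np.where(candidates, disp, np.inf)
    idx = int(np.argmin(masked))  # argmin takes the first minimum -> lowest index tie-break
    return ReferenceChoice(
        index=idx,
        presence_threshold=presence_threshold,
        dispersion_scores=disp,
        name=feature_names[idx] if feature_names else None,
    )


def load_counts(path) -> pd.DataFrame:
    """Read a samples x features count table (CSV/TSV, first column = sample id)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def load_covariates(path) -> pd.DataFrame:
    """Read a samples x covariates table (CSV/TSV, first column = sample id)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def from_anndata(adata, covariate_keys: list) -> tuple:
    """Extract (counts DataFrame, covariates DataFrame) from an AnnData object.

    The AnnData is expected to hold per-sample counts of cell types (or other
    features) in ``X`` with samples as obs and features as var, the usual
    layout after aggregating a single-cell experiment by sample.
    """
    Y = pd.DataFrame(
        np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
    )
    X = adata.obs[list(covariate_keys)].copy()
    return Y, X
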