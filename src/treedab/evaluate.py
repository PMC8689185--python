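"""Detection scoring and out-of-sample count prediction.

Detection is scored at the leaf level, per covariate, after propagating any
node-level result to the leaves: MCC by the standard contingency formula
(0 when the denominator vanishes), FDR = FP / (TP + FP) with 0/0 read as 0,
and Hamming distance as the number of disagreeing features.  Predictive
performance of a fitted model is the mean squared logarithmic error between
held-out counts and softmax-normalised predictions scaled to the mean
training sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold


@dataclass
class DetectionScore:
    tp: int
    fp: int
    fn: int
    tn: int
    mcc: float
    fdr: float
    hamming: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def detection_metrics(truth_labels, detected) -> DetectionScore:
    """Score a binary detection vector against ground-truth labels."""
    t = np.asarray(truth_labels).astype(bool)
    d = np.asarray(detected).astype(bool)
    if t.shape != d.shape:
        raise ValueError("truth and detection vectors must have equal length")
    tp = int(np.sum(t & d))
    fp = int(np.sum(~t & d))
    fn = int(np.sum(t & ~d))
    tn = int(np.sum(~t & ~d))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    fdr = 0.0 if (tp + fp) == 0 else fp / (tp + fp)
    hamming = fp + fn
    return DetectionScore(tp=tp, fp=fp, fn=fn, tn=tn, mcc=float(mcc), fdr=float(fdr), hamming=hamming)


def predict_counts(alpha_star, beta_star_leaf, x_row, mean_training_total) -> np.ndarray:
    """Predicted counts: softmax(alpha* + x beta*) times the mean training total."""
    if mean_training_total <= 0:
        raise ValueError("mean_training_total must be positive")
    alpha_star = np.asarray(alpha_star, dtype=float)
    beta = np.atleast_2d(np.asarray(beta_star_leaf, dtype=float))
    x_row = np.atleast_1d(np.asarray(x_row, dtype=float))
    loga = alpha_star + x_row @ beta
    loga = loga - loga.max()
    w = np.exp(loga)
    return mean_training_total * w / w.sum()


def msle(actual, predicted) -> float:
    """Mean squared logarithmic error: mean((log1p(a) - log1p(p))^2)."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if np.any(a < 0) or np.any(p < 0):
        raise ValueError("msle requires non-negative inputs")
    return float(np.mean((np.log1p(a) - np.log1p(p)) ** 2))


def kfold_indices(n: int, n_splits: int = 5, seed: int = 0):
    """Seed-reproducible K-fold (train_idx, test_idx) pairs."""
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def cross_validate_msle(Y_raw, X, fit_fn, n_splits: int = 5, seed: int = 0):
    """K-fold predictive evaluation of a fit procedure.

    ``fit_fn(Y_train, X_train) -> (alpha_star, beta_star_leaf)`` is called
    on training folds only; predictions for each held-out sample use its own
    covariate row and the mean training total.  Returns a list of per-fold
    dicts with the fold MSLE and the training-index checksum (for leakage
    audits).
    """
    Y_raw = np.asarray(Y_raw, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    results = []
    for fold, (tr, te) in enumerate(kfold_indices(len(Y_raw), n_splits, seed)):
        alpha_star, beta_star = fit_fn(Y_raw[tr], X[tr])
        mean_total = float(Y_raw[tr].sum(axis=1).mean())
        errs = [
            msle(Y_raw[i], predict_counts(alpha_star, beta_star, X[i], mean_total))
            for i in te
        ]
        results.append(
            {
                "fold": fold,
                "msle": float(np.mean(errs)),
                "train_checksum": int(np.sum(tr) + np.prod(tr % 97 + 1) % 10**9),
                "train_indices": tr,
            }
        )
    return results
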