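"""Linear discriminant analysis with an explicit, auditable contract.

The classifier is the shared-covariance Gaussian rule: class means,
pooled within-class covariance (optionally ridge-stabilized), and the
linear discriminant ``x' S^-1 mu_k - 0.5 mu_k' S^-1 mu_k + log pi_k``.
Ties break deterministically toward the first class in sorted label
order.  Fold construction for cross-validation lives here too, because
the fold unit (trial vs. window block) decides whether overlapping
windows can leak between train and test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default ridge: this fraction of the mean pooled-covariance diagonal
AUTO_RIDGE = 1e-6


@dataclass(frozen=True)
class LdaModel:
    class_labels: np.ndarray      # sorted, defines tie-break order
    means: np.ndarray             # K x d
    pooled_cov: np.ndarray        # d x d, after ridge
    priors: np.ndarray            # K, sums to 1
    ridge: float                  # the ridge value actually added


def resolve_ridge(cov: np.ndarray, ridge) -> float:
    """Turn the ridge spec into an absolute value.

    ``"auto"`` scales with the mean diagonal so the stabilization is
    invariant to the (arbitrary) amplitude units; a number is used as-is.
    """
    if isinstance(ridge, str):
        if ridge != "auto":
            raise ValueError(f"unknown ridge mode {ridge!r}")
        return AUTO_RIDGE * float(np.mean(np.diag(cov)))
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    return float(ridge)


def ridged(cov: np.ndarray, ridge) -> np.ndarray:
    lam = resolve_ridge(cov, ridge)
    return cov + lam * np.eye(cov.shape[0])


def fit_lda(X: np.ndarray, y, ridge="auto", priors: str = "empirical") -> LdaModel:
    """Fit class means, pooled covariance and priors.

    ``pooled_cov = sum_k (n_k - 1) S_k / (n - K)`` plus the ridge.  With
    ``ridge=0`` a non-positive-definite pooled covariance raises rather
    than silently falling back.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be n x d with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < 2):
        small = labels[counts < 2]
        raise ValueError(f"class {small[0]!r} has fewer than 2 samples")
    n, d = X.shape
    K = len(labels)

    means = np.empty((K, d))
    scatter = np.zeros((d, d))
    for k, lab in enumerate(labels):
        Xk = X[y == lab]
        means[k] = Xk.mean(axis=0)
        dev = Xk - means[k]
        scatter += dev.T @ dev
    cov = scatter / (n - K)

    lam = resolve_ridge(cov, ridge)
    cov = cov + lam * np.eye(d)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; set ridge > 0") from None

    if priors == "empirical":
        pi = counts / n
    elif priors == "uniform":
        pi = np.full(K, 1.0 / K)
    else:
        raise ValueError(f"unknown priors mode {priors!r}")
    return LdaModel(class_labels=labels, means=means, pooled_cov=cov,
                    priors=pi, ridge=lam)


def decision_scores(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """Per-class discriminant values (n x K)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"X has {X.shape[1]} features, model expects "
            f"{model.means.shape[1]}")
    W = np.linalg.solve(model.pooled_cov, model.means.T)   # d x K
    bias = -0.5 * np.sum(model.means.T * W, axis=0) + np.log(model.priors)
    return X @ W + bias


def predict_lda(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """Argmax of the discriminant; ties go to the first label in order."""
    scores = decision_scores(model, X)
    return model.class_labels[np.argmax(scores, axis=1)]


def model_to_dict(model: LdaModel) -> dict:
    """JSON-serializable snapshot for audit."""
    return {
        "class_labels": [l.item() if hasattr(l, "item") else l
                         for l in model.class_labels],
        "means": model.means.tolist(),
        "pooled_cov": model.pooled_cov.tolist(),
        "priors": model.priors.tolist(),
        "ridge": model.ridge,
    }


def make_folds(labels, n_folds: int = 4, mode: str = "by_trial",
               seed=None) -> np.ndarray:
    """Assign every window row to a cross-validation fold.

    ``by_trial`` puts all windows of repetition r into the same fold, so
    overlapping windows of one trial can never straddle the train/test
    split.  ``by_window_block`` splits each recording's window sequence
    into ``n_folds`` contiguous, balanced blocks (needed when trial
    identity is itself the prediction target).  ``shuffled`` assigns
    windows to folds at random — deliberately leaky for overlapping
    windows; kept to demonstrate the inflation it causes.
    """
    labels = pd.DataFrame(labels)
    if "trial" not in labels.columns:
        raise ValueError("labels must carry a 'trial' column")
    n = len(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    fold = np.empty(n, dtype=int)

    if mode == "by_trial":
        trials = np.sort(labels["trial"].unique())
        if len(trials) < n_folds:
            raise ValueError(
                f"{len(trials)} trials cannot fill {n_folds} by-trial folds")
        if len(trials) % n_folds:
            raise ValueError(
                f"{len(trials)} trials do not divide into {n_folds} folds")
        rank = {t: i % n_folds for i, t in enumerate(trials)}
        fold[:] = labels["trial"].map(rank).to_numpy()
    elif mode == "by_window_block":
        group_cols = [c for c in
                      ("subject", "factor_kind", "factor_level", "motion",
                       "trial") if c in labels.columns]
        for _, idx in labels.groupby(group_cols, sort=False).indices.items():
            idx = np.sort(idx)
            if len(idx) < n_folds:
                raise ValueError(
                    f"recording with {len(idx)} windows cannot fill "
                    f"{n_folds} blocks")
            for f, block in enumerate(np.array_split(idx, n_folds)):
                fold[block] = f
    elif mode == "shuffled":
        rng = np.random.default_rng(seed)
        fold[:] = rng.permutation(np.arange(n) % n_folds)
    else:
        raise ValueError(f"unknown fold mode {mode!r}")
    return fold
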