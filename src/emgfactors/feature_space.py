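"""Mahalanobis consistency and separability of the EMG feature space.

Two scalar indices summarize how recording conditions deform the feature
space:

* the repeatability index (RI) — the average squared Mahalanobis
  distance between trial means, each target trial measuring distances in
  its own covariance metric; lower means more consistent repetitions;
* the modified separability index (mSI) — for each motion class, half
  the squared Mahalanobis distance to its *nearest* other class under
  the averaged covariance of the compared pair; higher means more
  separable motions.

Protocols: the baseline RI is computed across the four repetitions of a
motion inside one condition level and averaged over levels; the
between-factor RI redraws one trial per level so that condition changes,
not repetition noise, drive the distances.  The baseline mSI is computed
across motions within a level; the between-factor mSI pools all levels
of the factor.  Both indices are invariant under invertible affine maps
of the feature space (with the ridge disabled), which makes them
comparable across feature scalings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .features import feature_column_names
from .lda import ridged
from .selection import factor_view, kind_levels

__all__ = [
    "TrialStats", "ClassStats", "repeatability_index",
    "modified_separability_index", "baseline_ri", "between_factor_ri",
    "msi_protocol", "pca_project", "trial_stats", "class_stats",
]


@dataclass(frozen=True)
class TrialStats:
    """Mean and covariance of one trial's feature windows."""
    mu: np.ndarray
    cov: np.ndarray
    n_windows: int
    label: tuple = ()


#: same payload, different role: one class (motion) instead of one trial
ClassStats = TrialStats


def _stats_of(X: np.ndarray, label=()) -> TrialStats:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 feature rows for a covariance")
    return TrialStats(mu=X.mean(axis=0),
                      cov=np.cov(X, rowvar=False, ddof=1),
                      n_windows=X.shape[0], label=tuple(np.atleast_1d(label)))


def _check_dims(stats: list) -> int:
    d = stats[0].mu.shape[0]
    for s in stats:
        if s.mu.shape[0] != d or s.cov.shape != (d, d):
            raise ValueError("inconsistent feature dimensions")
    return d


def _half_mahal(delta: np.ndarray, cov: np.ndarray) -> float:
    """0.5 * delta' cov^-1 delta via Cholesky (raises if singular)."""
    try:
        L = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular covariance; enable the ridge") from None
    z = linalg.solve_triangular(L, delta, lower=True)
    return 0.5 * float(z @ z)


def repeatability_index(trials: list, ridge="auto",
                        include_self: bool = True) -> float:
    """RI over K trials:

    ``(1/K) sum_i (1/K) sum_j 0.5 (mu_i - mu_j)' S_i^-1 (mu_i - mu_j)``.

    The literal form keeps the zero ``i == j`` terms in the inner
    average; ``include_self=False`` divides by ``K - 1`` instead, which
    rescales the index by ``K / (K - 1)``.
    """
    K = len(trials)
    if K < 2:
        raise ValueError("need at least 2 trials")
    _check_dims(trials)
    inner_n = K if include_self else K - 1
    total = 0.0
    for ti in trials:
        Si = ridged(ti.cov, ridge)
        total += sum(_half_mahal(ti.mu - tj.mu, Si) for tj in trials) / inner_n
    return total / K


def modified_separability_index(classes: list, ridge="auto",
                                cov_mode: str = "pairwise") -> float:
    """mSI over M classes:

    ``(1/M) sum_i min_{j != i} 0.5 (mu_i - mu_j)' S^-1 (mu_i - mu_j)``

    with ``S`` the average covariance of the compared classes —
    ``(S_i + S_j) / 2`` recomputed per pair (``cov_mode="pairwise"``) or
    the grand mean over all classes (``cov_mode="global"``).
    """
    M = len(classes)
    if M < 2:
        raise ValueError("need at least 2 classes")
    _check_dims(classes)
    if cov_mode not in ("pairwise", "global"):
        raise ValueError(f"unknown cov_mode {cov_mode!r}")
    if cov_mode == "global":
        S_global = ridged(np.mean([c.cov for c in classes], axis=0), ridge)
    total = 0.0
    for i, ci in enumerate(classes):
        best = np.inf
        for j, cj in enumerate(classes):
            if j == i:
                continue
            S = (ridged((ci.cov + cj.cov) / 2.0, ridge)
                 if cov_mode == "pairwise" else S_global)
            best = min(best, _half_mahal(ci.mu - cj.mu, S))
        total += best
    return total / M


# ---------------------------------------------------------------------------
# protocols on labeled feature tables


def trial_stats(df: pd.DataFrame) -> dict:
    """TrialStats per (factor_level, motion, trial) of one subject's table."""
    cols = feature_column_names(df)
    out = {}
    for key, grp in df.groupby(["factor_level", "motion", "trial"],
                               sort=True):
        out[key] = _stats_of(grp[cols].to_numpy(), label=key)
    return out


def class_stats(df: pd.DataFrame, by: str = "motion") -> dict:
    cols = feature_column_names(df)
    return {key: _stats_of(grp[cols].to_numpy(), label=(key,))
            for key, grp in df.groupby(by, sort=True)}


def _require_full_trials(df: pd.DataFrame, level: str, motion: str):
    trials = sorted(df["trial"].unique())
    cell = df[(df["factor_level"] == level) & (df["motion"] == motion)]
    have = sorted(cell["trial"].unique())
    if have != trials:
        raise ValueError(
            f"level {level} motion {motion} is missing repetitions "
            f"(have {have}, expected {trials})")


def baseline_ri(features: pd.DataFrame, factor_kind: str, ridge="auto",
                include_self: bool = True) -> pd.Series:
    """Per-motion RI across the repetitions inside each level, averaged
    over the factor's levels."""
    view = factor_view(features, factor_kind)
    levels = kind_levels(view, factor_kind)
    motions = sorted(view["motion"].unique())
    stats = trial_stats(view)
    out = {}
    for motion in motions:
        per_level = []
        for level in levels:
            _require_full_trials(view, level, motion)
            trials = [stats[k] for k in sorted(stats)
                      if k[0] == level and k[1] == motion]
            per_level.append(repeatability_index(trials, ridge=ridge,
                                                 include_self=include_self))
        out[motion] = float(np.mean(per_level))
    return pd.Series(out, name=f"baseline_ri_{factor_kind}")


def between_factor_ri(features: pd.DataFrame, factor_kind: str, seed: int = 0,
                      n_draws: int = 1, ridge="auto",
                      include_self: bool = True) -> pd.Series:
    """Per-motion RI across levels: one randomly drawn trial per level.

    Positions compare P1..P4; shifts compare S1..S4 (four trials either
    way, mirroring the four-repetition baseline).  Averaged over
    ``n_draws`` seeded draws.
    """
    view = factor_view(features, factor_kind)
    levels = [l for l in kind_levels(view, factor_kind) if l != "S0"]
    if len(levels) < 2:
        raise ValueError("need at least 2 levels")
    motions = sorted(view["motion"].unique())
    stats = trial_stats(view)
    rng = np.random.default_rng(seed)
    out = {m: [] for m in motions}
    for _ in range(n_draws):
        for motion in motions:
            picked = []
            for level in levels:
                trials = [stats[k] for k in sorted(stats)
                          if k[0] == level and k[1] == motion]
                if not trials:
                    raise ValueError(
                        f"no trials for level {level} motion {motion}")
                picked.append(trials[rng.integers(len(trials))])
            out[motion].append(repeatability_index(
                picked, ridge=ridge, include_self=include_self))
    return pd.Series({m: float(np.mean(v)) for m, v in out.items()},
                     name=f"between_ri_{factor_kind}")


def msi_protocol(features: pd.DataFrame, factor_kind: str, ridge="auto",
                 cov_mode: str = "pairwise") -> dict:
    """Baseline vs. between-factor motion separability.

    baseline: mSI over the motion classes inside each level, averaged
    over levels; between: mSI over motion classes pooling every level of
    the factor.  A factor that deforms the feature space inflates the
    pooled within-class covariance and drags the between value below the
    baseline.
    """
    view = factor_view(features, factor_kind)
    levels = kind_levels(view, factor_kind)
    per_level = []
    for level in levels:
        sub = view[view["factor_level"] == level]
        classes = list(class_stats(sub).values())
        if len(classes) < 2:
            raise ValueError(f"level {level} has fewer than 2 motions")
        per_level.append(modified_separability_index(
            classes, ridge=ridge, cov_mode=cov_mode))
    pooled = list(class_stats(view).values())
    between = modified_separability_index(pooled, ridge=ridge,
                                          cov_mode=cov_mode)
    return {"baseline": float(np.mean(per_level)), "between": float(between)}


def pca_project(features, n_components: int = 2):
    """Standardized PCA scores for visualization.

    Columns are z-scored first (amplitudes and counts are incommensurate);
    zero-variance columns are dropped with a warning.  Returns
    ``(scores, explained_variance_ratio)``.
    """
    import warnings

    from sklearn.decomposition import PCA

    if isinstance(features, pd.DataFrame):
        cols = feature_column_names(features) or list(features.columns)
        X = features[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if X.shape[0] <= n_components:
        raise ValueError("need more rows than components")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"dropping {np.count_nonzero(~keep)} zero-variance "
                      "column(s) before PCA", stacklevel=2)
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=min(n_components, X.shape[1]), svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
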