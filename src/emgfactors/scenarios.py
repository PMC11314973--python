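"""Classification experiments on the labeled feature table.

Four families of experiments probe how limb position and electrode shift
restructure the feature space:

* WFC — within-factor motion classification: 4-fold cross-validation of
  the 7 motions inside one condition level (folds are whole repetitions,
  so overlapping windows never leak across the split);
* BFC — between-factor motion classification: train on the baseline
  condition (P1/S0), test on each changed level, no cross-validation;
* factor-as-class (Types 1-5) — the condition levels themselves are the
  prediction target, showing that each level forms a statistically
  separable cluster;
* trial-as-class — repetitions as the target, the negative control:
  with exchangeable repetitions the accuracy must sit at chance.

Accuracies are reported in percent, mean +- SD across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import feature_column_names
from .lda import fit_lda, make_folds, predict_lda
from .selection import baseline_level, combined_view, factor_view, kind_levels

FACTOR_TYPES = (1, 2, 3, 4, 5)


@dataclass
class ScenarioResult:
    """Per-scenario accuracy summary and pooled confusion counts."""

    scenario: dict
    accuracies: np.ndarray            # per subject, percent
    confusion: pd.DataFrame           # pooled over subjects and folds

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        if len(self.accuracies) < 2:
            return 0.0
        return float(np.std(self.accuracies, ddof=1))

    @property
    def n_test(self) -> int:
        return int(self.confusion.to_numpy().sum())

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "accuracies": [float(a) for a in self.accuracies],
            "mean": self.mean,
            "sd": self.sd,
            "n_test": self.n_test,
            "confusion": {
                "labels": [str(l) for l in self.confusion.index],
                "counts": self.confusion.to_numpy().tolist(),
            },
        }


def _empty_confusion(labels) -> pd.DataFrame:
    labels = [str(l) for l in labels]
    return pd.DataFrame(np.zeros((len(labels), len(labels)), dtype=int),
                        index=labels, columns=labels)


def _accumulate(confusion: pd.DataFrame, y_true, y_pred):
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        confusion.loc[str(t), str(p)] += 1


def _accuracy(confusion: pd.DataFrame) -> float:
    total = confusion.to_numpy().sum()
    return 100.0 * np.trace(confusion.to_numpy()) / total


def _check_classes(y, what: str):
    if len(pd.unique(y)) < 2:
        raise ValueError(f"fewer than 2 {what} classes after selection")


def _cv_confusion(df: pd.DataFrame, target: str, n_folds: int,
                  fold_mode: str, ridge="auto", seed=None) -> pd.DataFrame:
    """Cross-validated confusion matrix for one subject's selection."""
    cols = feature_column_names(df)
    X = df[cols].to_numpy()
    y = df[target].to_numpy()
    _check_classes(y, target)
    folds = make_folds(df, n_folds=n_folds, mode=fold_mode, seed=seed)
    confusion = _empty_confusion(np.unique(y))
    for f in range(n_folds):
        train, test = folds != f, folds == f
        model = fit_lda(X[train], y[train], ridge=ridge)
        _accumulate(confusion, y[test], predict_lda(model, X[test]))
    return confusion


def _per_subject(features: pd.DataFrame, fn) -> ScenarioResult:
    """Run ``fn(subject_df) -> confusion`` per subject and pool."""
    accs, pooled = [], None
    for _, sub in features.groupby("subject", sort=True):
        confusion = fn(sub)
        accs.append(_accuracy(confusion))
        pooled = confusion if pooled is None else pooled.add(confusion,
                                                             fill_value=0)
    return accs, pooled.astype(int)


def run_wfc(features: pd.DataFrame, factor_kind: str, factor_level: str,
            n_folds: int = 4, fold_mode: str = "by_trial",
            ridge="auto") -> ScenarioResult:
    """Motion classification inside one condition level (4-fold CV)."""
    view = factor_view(features, factor_kind)
    sel = view[view["factor_level"] == factor_level]
    if sel.empty:
        raise ValueError(f"no data for level {factor_level!r}")
    accs, confusion = _per_subject(
        sel, lambda sub: _cv_confusion(sub, "motion", n_folds, fold_mode,
                                       ridge=ridge))
    return ScenarioResult(
        scenario={"name": "WFC", "factor_kind": factor_kind,
                  "factor_level": factor_level, "fold_mode": fold_mode},
        accuracies=np.asarray(accs), confusion=confusion)


def run_bfc(features: pd.DataFrame, factor_kind: str, test_levels=None,
            ridge="auto") -> dict:
    """Train on the baseline level, evaluate on each changed level.

    No cross-validation: the whole baseline is the training set, mirroring
    plain classifier transfer.  Returns ``{level: ScenarioResult}``.
    """
    view = factor_view(features, factor_kind)
    base = baseline_level(factor_kind)
    if test_levels is None:
        test_levels = [l for l in kind_levels(view, factor_kind) if l != base]
    if len(test_levels) == 0:
        raise ValueError("no test levels")
    if base in test_levels:
        raise ValueError("test levels overlap the training baseline")
    cols = feature_column_names(view)
    out = {}
    for level in test_levels:
        if view[view["factor_level"] == level].empty:
            raise ValueError(f"no data for level {level!r}")

        def one(sub, level=level):
            train = sub[sub["factor_level"] == base]
            test = sub[sub["factor_level"] == level]
            _check_classes(train["motion"], "motion")
            model = fit_lda(train[cols].to_numpy(),
                            train["motion"].to_numpy(), ridge=ridge)
            confusion = _empty_confusion(np.unique(train["motion"]))
            _accumulate(confusion, test["motion"],
                        predict_lda(model, test[cols].to_numpy()))
            return confusion

        accs, confusion = _per_subject(view, one)
        out[level] = ScenarioResult(
            scenario={"name": "BFC", "factor_kind": factor_kind,
                      "train_level": base, "test_level": level},
            accuracies=np.asarray(accs), confusion=confusion)
    return out


def _type_view(features: pd.DataFrame, ftype: int,
               baseline_as_position: bool = True) -> pd.DataFrame:
    """Rows and target column for one factor-classification type."""
    if ftype in (1, 5):
        view = combined_view(features)
        view["target"] = view["factor_level"]
    elif ftype == 2:
        view = combined_view(features)
        if not baseline_as_position:
            view = view[view["factor_level"] != "P1"]
        view["target"] = view["factor_kind"]
    elif ftype == 3:
        view = factor_view(features, "position")
        view["target"] = view["factor_level"]
    elif ftype == 4:
        view = factor_view(features, "shift")
        view["target"] = view["factor_level"]
    else:
        raise ValueError(f"factor classification type must be in "
                         f"{FACTOR_TYPES}, got {ftype}")
    return view


def run_factor_classification(features: pd.DataFrame, ftype: int,
                              motion=None, n_folds: int = 4,
                              fold_mode: str = "by_trial", ridge="auto",
                              baseline_as_position: bool = True
                              ) -> ScenarioResult:
    """Condition levels as the prediction target (4-fold CV).

    Type 1: 8 levels (P1..P4, S1..S4; P1 doubles as S0), single motion.
    Type 2: binary position vs. shift, single motion (the shared baseline
    is grouped with the positions unless ``baseline_as_position=False``).
    Type 3: P1..P4, all motions.  Type 4: S0..S4, all motions.
    Type 5: 8 levels, all motions.
    """
    if ftype in (1, 2):
        if motion is None:
            raise ValueError(f"type {ftype} requires a single motion")
    elif motion is not None:
        raise ValueError(f"type {ftype} pools all motions; drop motion=")
    view = _type_view(features, ftype,
                      baseline_as_position=baseline_as_position)
    if motion is not None:
        view = view[view["motion"] == motion]
        if view.empty:
            raise ValueError(f"no data for motion {motion!r}")
    accs, confusion = _per_subject(
        view, lambda sub: _cv_confusion(sub, "target", n_folds, fold_mode,
                                        ridge=ridge))
    return ScenarioResult(
        scenario={"name": f"TYPE{ftype}", "motion": motion,
                  "fold_mode": fold_mode},
        accuracies=np.asarray(accs), confusion=confusion)


def run_trial_classification(features: pd.DataFrame, factor_kind: str,
                             factor_level: str, n_folds: int = 4,
                             fold_mode: str = "by_window_block",
                             ridge="auto", seed=None) -> ScenarioResult:
    """Repetition identity as the target inside one condition level.

    Folds are contiguous window blocks within each trial (the trial *is*
    the label, so by-trial folding is impossible); random window folds
    (``fold_mode="shuffled"``) are deliberately leaky for overlapping
    windows and kept only to demonstrate the inflation.  Per-motion runs
    are averaged into one accuracy per subject.
    """
    if fold_mode == "by_trial":
        raise ValueError("trial identity is the target; fold by window "
                         "blocks, not by trial")
    view = factor_view(features, factor_kind)
    sel = view[view["factor_level"] == factor_level]
    if sel.empty:
        raise ValueError(f"no data for level {factor_level!r}")
    if sel["trial"].nunique() < 2:
        raise ValueError("need at least 2 repetitions")

    def one(sub):
        pooled = None
        for _, per_motion in sub.groupby("motion", sort=True):
            confusion = _cv_confusion(per_motion, "trial", n_folds,
                                      fold_mode, ridge=ridge, seed=seed)
            pooled = confusion if pooled is None else pooled + confusion
        return pooled

    accs, confusion = _per_subject(sel, one)
    return ScenarioResult(
        scenario={"name": "TRIAL", "factor_kind": factor_kind,
                  "factor_level": factor_level, "fold_mode": fold_mode},
        accuracies=np.asarray(accs), confusion=confusion)
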