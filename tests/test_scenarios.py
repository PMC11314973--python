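"""Classification scenarios: motion transfer, factor-as-class, trial
negative control, confusion-matrix invariants and determinism."""

import numpy as np
import pandas as pd
import pytest

from emgfactors.pipeline import compute_features
from emgfactors.scenarios import (run_bfc, run_factor_classification,
                                  run_trial_classification, run_wfc)

from conftest import small_config


def _shuffle_labels(df, column, seed=0):
    out = df.copy()
    out[column] = np.random.default_rng(seed).permutation(
        out[column].to_numpy())
    return out


class TestWfc:
    def test_motions_separate_within_a_level(self, small_features):
        res = run_wfc(small_features, "position", "P1")
        assert res.mean > 90.0

    def test_shuffled_motion_labels_score_at_chance(self, small_features):
        shuffled = _shuffle_labels(small_features, "motion", seed=1)
        res = run_wfc(shuffled, "position", "P1")
        k = small_features["motion"].nunique()
        chance = 100.0 / k
        tol = 300.0 * np.sqrt(chance / 100 * (1 - chance / 100) / res.n_test)
        assert abs(res.mean - chance) <= tol

    def test_single_motion_rejected(self, small_features):
        sel = small_features[small_features["motion"] == "CH"]
        with pytest.raises(ValueError, match="fewer than 2"):
            run_wfc(sel, "position", "P1")

    def test_missing_level_rejected(self, small_features):
        with pytest.raises(ValueError, match="no data"):
            run_wfc(small_features, "position", "P9")


class TestBfc:
    def test_baseline_transfer_per_level(self, small_features):
        out = run_bfc(small_features, "shift")
        assert set(out) == {"S1", "S2", "S3", "S4"}
        for res in out.values():
            assert 0.0 <= res.mean <= 100.0
            assert res.scenario["train_level"] == "S0"

    def test_empty_test_levels_rejected(self, small_features):
        with pytest.raises(ValueError, match="no test levels"):
            run_bfc(small_features, "position", test_levels=[])

    def test_overlap_with_baseline_rejected(self, small_features):
        with pytest.raises(ValueError, match="overlap"):
            run_bfc(small_features, "position", test_levels=["P1", "P2"])


class TestFactorClassification:
    def test_type1_levels_form_separable_clusters(self, small_features):
        res = run_factor_classification(small_features, 1, motion="CH")
        assert res.confusion.shape == (8, 8)
        assert res.mean > 80.0

    def test_type5_not_better_than_type1(self, small_features):
        t1 = np.mean([run_factor_classification(
            small_features, 1, motion=m).mean
            for m in ("CH", "OH", "RT")])
        t5 = run_factor_classification(small_features, 5)
        assert t5.mean <= t1

    def test_type2_is_binary_with_baseline_grouped(self, small_features):
        res = run_factor_classification(small_features, 2, motion="CH")
        assert sorted(res.confusion.index) == ["position", "shift"]
        # the shared baseline counts toward the position super-class
        n_pos_windows = res.confusion.loc["position"].sum()
        n_shift_windows = res.confusion.loc["shift"].sum()
        assert n_pos_windows == n_shift_windows  # 4 levels each

    def test_type2_can_exclude_the_shared_baseline(self, small_features):
        res = run_factor_classification(small_features, 2, motion="CH",
                                        baseline_as_position=False)
        n_pos = res.confusion.loc["position"].sum()
        n_shift = res.confusion.loc["shift"].sum()
        assert n_pos == 3 * n_shift // 4  # 3 position levels vs 4 shifts

    def test_motion_argument_contract(self, small_features):
        with pytest.raises(ValueError, match="requires a single motion"):
            run_factor_classification(small_features, 1)
        with pytest.raises(ValueError, match="pools all motions"):
            run_factor_classification(small_features, 3, motion="CH")
        with pytest.raises(ValueError, match="type"):
            run_factor_classification(small_features, 9)


class TestTrialClassification:
    def test_exchangeable_repetitions_score_at_chance(self, small_features):
        res = run_trial_classification(small_features, "position", "P1")
        chance = 25.0
        tol = 300.0 * np.sqrt(0.25 * 0.75 / res.n_test)
        assert abs(res.mean - chance) <= tol

    def test_distinct_trial_gains_are_classifiable(self):
        # a strong per-trial gain drift makes repetitions identifiable:
        # the positive control for the negative control above
        cfg = small_config(seed=2, trial_jitter_sd=0.6)
        feats = compute_features(cfg, ["sub01"])
        res = run_trial_classification(feats, "position", "P1")
        assert res.mean > 40.0

    def test_fewer_than_two_trials_rejected(self, small_features):
        sel = small_features[small_features["trial"] == 1]
        with pytest.raises(ValueError, match="2 repetitions"):
            run_trial_classification(sel, "position", "P1")

    def test_by_trial_folding_rejected(self, small_features):
        with pytest.raises(ValueError, match="target"):
            run_trial_classification(small_features, "position", "P1",
                                     fold_mode="by_trial")


class TestResultInvariants:
    def test_confusion_rows_sum_to_test_counts(self, small_features):
        res = run_wfc(small_features, "position", "P2")
        counts = small_features[
            (small_features.factor_kind == "position")
            & (small_features.factor_level == "P2")
        ].groupby("motion").size()
        for motion, n in counts.items():
            assert res.confusion.loc[motion].sum() == n

    def test_accuracy_equals_trace_over_total(self, small_features):
        res = run_factor_classification(small_features, 3)
        c = res.confusion.to_numpy()
        # single subject: the mean is the pooled accuracy
        assert res.mean == pytest.approx(100.0 * np.trace(c) / c.sum(),
                                         abs=1e-12)

    def test_results_are_reproducible(self, small_features):
        a = run_factor_classification(small_features, 4)
        b = run_factor_classification(small_features, 4)
        pd.testing.assert_frame_equal(a.confusion, b.confusion)
        assert a.to_dict() == b.to_dict()
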