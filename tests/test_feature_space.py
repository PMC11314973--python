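"""Repeatability and separability indices against brute-force oracles,
analytic spot values, Mahalanobis invariance and the table protocols."""

import numpy as np
import pandas as pd
import pytest

from emgfactors.feature_space import (ClassStats, TrialStats, baseline_ri,
                                      between_factor_ri,
                                      modified_separability_index,
                                      msi_protocol, pca_project,
                                      repeatability_index)
from emgfactors.features import feature_columns
from emgfactors.pipeline import compute_features

from conftest import small_config

# --- independent oracles ---------------------------------------------------


def ri_oracle(mus, covs):
    K = len(mus)
    total = 0.0
    for i in range(K):
        inv = np.linalg.inv(covs[i])
        for j in range(K):
            d = mus[i] - mus[j]
            total += 0.5 * d @ inv @ d / K
    return total / K


def msi_oracle(mus, covs):
    M = len(mus)
    total = 0.0
    for i in range(M):
        dists = []
        for j in range(M):
            if j == i:
                continue
            d = mus[i] - mus[j]
            S = (covs[i] + covs[j]) / 2.0
            dists.append(0.5 * d @ np.linalg.inv(S) @ d)
        total += min(dists)
    return total / M


def random_stats(rng, k, d, cls=TrialStats):
    out = []
    for _ in range(k):
        A = rng.standard_normal((d, d + 5))
        out.append(cls(mu=rng.standard_normal(d) * 3,
                       cov=A @ A.T / (d + 5), n_windows=d + 5))
    return out


# --- analytic spot values --------------------------------------------------


def test_ri_is_zero_for_coincident_means():
    trials = [TrialStats(mu=np.array([1.0, 2.0]), cov=np.eye(2), n_windows=5)
              for _ in range(4)]
    assert repeatability_index(trials, ridge=0.0) == 0.0


def test_ri_hand_computed_two_trial_case():
    # K=2, d=1, means 0 and 2, unit variances: each outer term averages
    # {0, 2}/2 = 1, so RI = 1
    trials = [TrialStats(mu=np.array([0.0]), cov=np.eye(1), n_windows=5),
              TrialStats(mu=np.array([2.0]), cov=np.eye(1), n_windows=5)]
    assert repeatability_index(trials, ridge=0.0) == pytest.approx(1.0)
    # excluding the i == j self term rescales by K/(K-1)
    assert repeatability_index(trials, ridge=0.0, include_self=False) \
        == pytest.approx(2.0)


def test_msi_is_zero_for_coincident_centroids():
    classes = [ClassStats(mu=np.zeros(3), cov=np.eye(3), n_windows=9)
               for _ in range(2)]
    assert modified_separability_index(classes, ridge=0.0) == 0.0


def test_msi_hand_computed_two_class_case():
    # centroids (0,0) and (2,0), identity covariances: each class sees
    # 0.5 * 4 = 2 to its only neighbour
    classes = [ClassStats(mu=np.array([0.0, 0.0]), cov=np.eye(2), n_windows=9),
               ClassStats(mu=np.array([2.0, 0.0]), cov=np.eye(2), n_windows=9)]
    assert modified_separability_index(classes, ridge=0.0) \
        == pytest.approx(2.0)


def test_degenerate_inputs_rejected():
    one = [TrialStats(mu=np.zeros(2), cov=np.eye(2), n_windows=5)]
    with pytest.raises(ValueError):
        repeatability_index(one)
    with pytest.raises(ValueError):
        modified_separability_index(one)
    singular = [TrialStats(mu=np.zeros(2), cov=np.zeros((2, 2)), n_windows=5),
                TrialStats(mu=np.ones(2), cov=np.zeros((2, 2)), n_windows=5)]
    with pytest.raises(np.linalg.LinAlgError):
        repeatability_index(singular, ridge=0.0)


# --- oracle equivalence and invariance -------------------------------------


def test_indices_match_bruteforce_oracles(rng):
    for _ in range(50):
        k = rng.integers(2, 7)
        d = rng.integers(1, 11)
        stats = random_stats(rng, k, d)
        mus = [s.mu for s in stats]
        covs = [s.cov for s in stats]
        assert repeatability_index(stats, ridge=0.0) \
            == pytest.approx(ri_oracle(mus, covs), rel=1e-10)
        assert modified_separability_index(stats, ridge=0.0) \
            == pytest.approx(msi_oracle(mus, covs), rel=1e-10)


def test_global_covariance_variant(rng):
    stats = random_stats(rng, 5, 4)
    S = np.mean([s.cov for s in stats], axis=0)
    Sinv = np.linalg.inv(S)
    expected = np.mean([
        min(0.5 * (si.mu - sj.mu) @ Sinv @ (si.mu - sj.mu)
            for j, sj in enumerate(stats) if j != i)
        for i, si in enumerate(stats)])
    got = modified_separability_index(stats, ridge=0.0, cov_mode="global")
    assert got == pytest.approx(expected, rel=1e-10)


def test_indices_invariant_under_affine_maps(rng):
    stats = random_stats(rng, 4, 5)
    ri0 = repeatability_index(stats, ridge=0.0)
    msi0 = modified_separability_index(stats, ridge=0.0)
    for _ in range(5):
        A = rng.standard_normal((5, 5)) + np.eye(5)
        b = rng.standard_normal(5)
        mapped = [TrialStats(mu=A @ s.mu + b, cov=A @ s.cov @ A.T,
                             n_windows=s.n_windows) for s in stats]
        assert repeatability_index(mapped, ridge=0.0) \
            == pytest.approx(ri0, rel=1e-6)
        assert modified_separability_index(mapped, ridge=0.0) \
            == pytest.approx(msi0, rel=1e-6)


# --- protocols on feature tables -------------------------------------------


def _toy_table(trial_shift=0.0, n_levels=2, rng=None):
    """Tiny hand-built feature table: 2 motions, n_levels levels, 3 trials,
    6 windows each, 2 channels' MAV-like columns."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for level in [f"P{i+1}" for i in range(n_levels)]:
        for motion, base in (("CH", 0.0), ("OH", 5.0)):
            for trial in range(1, 4):
                centre = base + trial_shift * trial
                for _ in range(6):
                    v = rng.normal(centre, 0.5, 2)
                    rows.append({"subject": "s1", "factor_kind": "position",
                                 "factor_level": level, "motion": motion,
                                 "trial": trial,
                                 "MAV_ch1": v[0], "MAV_ch2": v[1]})
    return pd.DataFrame(rows)


def test_baseline_ri_zero_for_identical_repetitions():
    df = _toy_table()
    # overwrite each trial with the same window block -> identical trials
    block = df[(df.factor_level == "P1") & (df.motion == "CH")
               & (df.trial == 1)][["MAV_ch1", "MAV_ch2"]].to_numpy()
    for level in df.factor_level.unique():
        for motion in df.motion.unique():
            for trial in (1, 2, 3):
                m = ((df.factor_level == level) & (df.motion == motion)
                     & (df.trial == trial))
                df.loc[m, ["MAV_ch1", "MAV_ch2"]] = block
    assert np.allclose(baseline_ri(df, "position"), 0.0)


def test_baseline_ri_increases_with_trial_jitter():
    """More trial-to-trial gain drift -> less repeatable trial means."""
    jitter_grid = (0.0, 0.15, 0.45)
    means = []
    for jitter in jitter_grid:
        vals = []
        for seed in range(5):
            cfg = small_config(seed=seed, trial_jitter_sd=jitter,
                               position_gain_sd=(0.0,),
                               shift_mixing=(0.0,),
                               shift_attenuation=(1.0,))
            feats = compute_features(cfg, ["sub01"])
            vals.append(float(baseline_ri(feats, "position").mean()))
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_missing_repetition_rejected():
    df = _toy_table()
    df = df[~((df.factor_level == "P2") & (df.motion == "OH")
              & (df.trial == 3))]
    with pytest.raises(ValueError, match="missing repetitions"):
        baseline_ri(df, "position")


def test_between_ri_deterministic_given_seed():
    df = _toy_table(trial_shift=0.4)
    a = between_factor_ri(df, "position", seed=42, n_draws=2)
    b = between_factor_ri(df, "position", seed=42, n_draws=2)
    pd.testing.assert_series_equal(a, b)


def test_msi_single_level_between_equals_baseline():
    df = _toy_table(n_levels=1)
    out = msi_protocol(df, "position")
    assert out["between"] == pytest.approx(out["baseline"])


# --- PCA -------------------------------------------------------------------


class TestPca:
    def test_rank_one_data_explained_by_first_component(self, rng):
        t = rng.standard_normal(100)
        X = np.outer(t, [1.0, -2.0, 0.5])
        _, ratios = pca_project(X, n_components=2)
        assert ratios[0] == pytest.approx(1.0, abs=1e-10)

    def test_ratios_sorted_descending(self, rng):
        X = rng.standard_normal((200, 6)) * np.array([5, 4, 3, 2, 1, 0.5])
        scores, ratios = pca_project(X, n_components=4)
        assert scores.shape == (200, 4)
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1 + 1e-12

    def test_zero_variance_column_dropped_with_warning(self, rng):
        X = np.hstack([rng.standard_normal((50, 3)), np.ones((50, 1))])
        with pytest.warns(UserWarning, match="zero-variance"):
            scores, _ = pca_project(X, n_components=2)
        assert scores.shape == (50, 2)

    def test_needs_more_rows_than_components(self, rng):
        with pytest.raises(ValueError):
            pca_project(rng.standard_normal((2, 5)), n_components=2)
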