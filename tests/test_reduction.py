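"""Radiomic feature reduction: NZV, correlation pruning, supervised screen."""

import numpy as np
import pandas as pd
import pytest

from radgex._stats import spearman_corr_matrix, spearman_pair, spearman_vector
from radgex.reduction import (correlation_prune, feature_columns,
                              near_zero_variance_filter, reduce_unsupervised,
                              univariate_screen)
from radgex.prediction import screen_training


def _table(cols: dict, n=None) -> pd.DataFrame:
    df = pd.DataFrame(cols)
    df.insert(0, "subcompartment", "ET")
    df.insert(0, "patient_id", [f"P{i}" for i in range(len(df))])
    return df


class TestNearZeroVariance:
    def test_constant_dropped_distinct_kept(self):
        df = _table({"const": [1.0] * 50, "distinct": np.arange(50.0)})
        out, dropped = near_zero_variance_filter(df)
        assert dropped == ["const"]
        assert "distinct" in out.columns

    def test_frequency_ratio_rule(self):
        # 48 zeros, 2 ones in 50 rows: ratio 24 > 19 and 4% unique < 10% -> dropped
        df = _table({"nzv": np.r_[np.zeros(48), np.ones(2)],
                     "binary_balanced": np.r_[np.zeros(25), np.ones(25)]})
        out, dropped = near_zero_variance_filter(df)
        assert dropped == ["nzv"]
        assert "binary_balanced" in out.columns  # ratio 1, kept despite low uniqueness


class TestCorrelationPrune:
    def test_duplicate_column_one_survives(self):
        x = np.random.default_rng(0).normal(size=30)
        df = _table({"f1": x, "f2": x.copy(), "g": np.random.default_rng(1).normal(size=30)})
        out, dropped = correlation_prune(df)
        feats = feature_columns(out)
        assert ("f1" in feats) != ("f2" in feats)
        assert "g" in feats

    def test_three_mutually_perfect_columns_one_survives(self):
        x = np.random.default_rng(2).normal(size=30)
        df = _table({"a": x, "b": 2 * x + 1, "c": -x})
        out, _ = correlation_prune(df)
        assert len(feature_columns(out)) == 1

    def test_uncorrelated_table_unchanged(self):
        rng = np.random.default_rng(3)
        df = _table({f"f{i}": rng.normal(size=200) for i in range(5)})
        out, dropped = correlation_prune(df, rho_cut=0.5)
        assert dropped == []

    def test_survivors_below_cutoff_and_deterministic(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(40, 3))
        cols = {}
        for i in range(9):
            cols[f"f{i}"] = base[:, i % 3] + rng.normal(0, 0.15, 40)
        df = _table(cols)
        out1, d1 = correlation_prune(df, rho_cut=0.9)
        out2, d2 = correlation_prune(df, rho_cut=0.9)
        assert d1 == d2
        C = np.abs(spearman_corr_matrix(out1[feature_columns(out1)].to_numpy()))
        np.fill_diagonal(C, 0)
        assert C.max() <= 0.9 + 1e-12


class TestUnsupervisedStages:
    def test_stage_counts_monotone_and_outcome_blind(self):
        rng = np.random.default_rng(5)
        n = 50
        cols = {f"f{i}": rng.normal(size=n) for i in range(10)}
        cols["dup"] = cols["f0"].copy()
        cols["const"] = np.zeros(n)
        df = _table(cols)
        out, report = reduce_unsupervised(df)
        assert report["n_initial"] >= report["n_after_nzv"] >= report["n_after_corr"]
        assert report["n_after_nzv"] == 11 and report["n_after_corr"] == 10


class TestUnivariateScreen:
    def _cohort(self, rng, n=28, m=30, rho_feature=None):
        feats = {f"rad_{j:04d}": rng.normal(size=n) for j in range(m)}
        df = _table(feats)
        y = rng.normal(size=n)
        if rho_feature is not None:
            df[rho_feature] = y + rng.normal(0, 0.2, n)  # population rho ~ 0.98
        scores = df[["patient_id", "subcompartment"]].copy()
        scores["S"] = y
        return df, scores

    def test_planted_feature_selected_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df, scores = self._cohort(rng, rho_feature="rad_0003")
            res = univariate_screen(df, scores, "S", mode="per_subcompartment")
            if res.selected and res.selected[0] == "rad_0003":
                hits += 1
        assert hits >= 19  # >= 95% of seeds

    def test_null_cohort_mostly_empty_selection(self):
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            df, scores = self._cohort(rng)
            sizes.append(len(univariate_screen(df, scores, "S").selected))
        assert np.median(sizes) == 0

    def test_cap_respected(self):
        rng = np.random.default_rng(7)
        df, scores = self._cohort(rng)
        for j in range(8):  # plant many correlated features
            df[f"rad_{j:04d}"] = scores["S"] + rng.normal(0, 0.1, 28)
        res = univariate_screen(df, scores, "S", cap=5)
        assert len(res.selected) == 5

    def test_stage12_invariant_to_outcome_permutation(self):
        """NZV and correlation pruning never see the pathway score."""
        rng = np.random.default_rng(8)
        df, scores = self._cohort(rng)
        out1, rep1 = reduce_unsupervised(df)
        scores2 = scores.copy()
        scores2["S"] = scores2["S"].sample(frac=1, random_state=0).to_numpy()
        out2, rep2 = reduce_unsupervised(df)
        pd.testing.assert_frame_equal(out1, out2)

    def test_patient_level_mode_matches_fast_path(self):
        """The in-fold screen equals the module-level patient_level screen."""
        rng = np.random.default_rng(9)
        df, scores = self._cohort(rng, rho_feature="rad_0005")
        feats = feature_columns(df)
        res = univariate_screen(df, scores, "S", mode="patient_level")
        idx = screen_training(scores["S"].to_numpy(), df[feats].to_numpy(), feats)
        assert res.selected == [feats[i] for i in idx]

    def test_infold_leakage_canary(self):
        """Flipping the held-out patient's score never changes that fold's selection."""
        rng = np.random.default_rng(10)
        df, scores = self._cohort(rng, rho_feature="rad_0002")
        feats = feature_columns(df)
        y = scores["S"].to_numpy().copy()
        X = df[feats].to_numpy()
        train = np.ones(28, dtype=bool)
        train[4] = False
        sel1 = screen_training(y[train], X[train], feats)
        y2 = y.copy()
        y2[4] = -y2[4] + 100.0
        sel2 = screen_training(y2[train], X[train], feats)
        assert sel1 == sel2


class TestSpearmanUtilities:
    def test_exact_small_n_matches_brute_force_enumeration(self):
        from itertools import permutations
        from scipy import stats
        rng = np.random.default_rng(11)
        for n in (5, 7):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, p = spearman_pair(x, y)
            assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)
            # brute-force null: rho over all alignments of the y ranks
            null = [stats.spearmanr(x, np.array(y)[list(perm)]).statistic
                    for perm in permutations(range(n))]
            expected = np.mean(np.abs(null) >= abs(rho) - 1e-12)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_vectorized_matches_scipy_large_n(self):
        from scipy import stats
        rng = np.random.default_rng(12)
        y = rng.normal(size=40)
        X = rng.normal(size=(40, 6))
        rho, p = spearman_vector(y, X)
        for j in range(6):
            ref = stats.spearmanr(y, X[:, j])
            assert rho[j] == pytest.approx(ref.statistic, abs=1e-12)
            assert p[j] == pytest.approx(ref.pvalue, rel=1e-6)
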