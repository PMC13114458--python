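"""Elastic net and nested LOPO-CV: oracles, leakage canaries, determinism."""

import numpy as np
import pandas as pd
import pytest

from conftest import null_patient_table
from radgex._enet import enet_path, lambda_grid, lambda_max
from radgex.prediction import (ElasticNetConfig, bootstrap_ci, elastic_net_fit,
                               legacy_prescreened_cv, nested_lopo, patient_level_table)

FAST_EN = ElasticNetConfig(alpha_grid=(0.5, 1.0), n_lambda=25, inner_folds=3)


def _orthonormal_design(rng, n=40, p=5):
    A = rng.normal(size=(n, p))
    Q, _ = np.linalg.qr(A - A.mean(0))
    return Q * np.sqrt(n)  # X'X / n = I


class TestCoordinateDescent:
    def test_orthonormal_matches_soft_threshold_closed_form(self):
        rng = np.random.default_rng(0)
        X = _orthonormal_design(rng)
        y = rng.normal(size=40)
        y -= y.mean()
        xty = X.T @ y / 40
        for l1_ratio in (1.0, 0.6, 0.3):
            lams = lambda_grid(lambda_max(X, y, l1_ratio), 30, 1e-3)
            coefs = enet_path(X, y, lams, l1_ratio, tol=1e-12, max_iter=20000)
            for li, lam in enumerate(lams):
                closed = (np.sign(xty) * np.maximum(np.abs(xty) - lam * l1_ratio, 0.0)
                          / (1.0 + lam * (1.0 - l1_ratio)))
                np.testing.assert_allclose(coefs[li], closed, atol=1e-8)

    def test_matches_sklearn_on_general_design(self):
        from sklearn.linear_model import ElasticNet
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 8))
        y = X[:, 0] * 2 - X[:, 3] + rng.normal(size=50) * 0.5
        Xc, yc = X - X.mean(0), y - y.mean()
        for lam in (0.1, 0.01):
            for a in (1.0, 0.5):
                ours = enet_path(Xc, yc, np.array([lam]), a, tol=1e-12, max_iter=10**5)[0]
                ref = ElasticNet(alpha=lam, l1_ratio=a, fit_intercept=False,
                                 tol=1e-12, max_iter=10**6).fit(Xc, yc).coef_
                np.testing.assert_allclose(ours, ref, atol=1e-6)

    def test_top_of_path_is_all_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        X -= X.mean(0)
        y = rng.normal(size=30)
        y -= y.mean()
        lam0 = lambda_max(X, y, 0.5)
        assert np.allclose(enet_path(X, y, np.array([lam0]), 0.5), 0.0)
        assert not np.allclose(enet_path(X, y, np.array([lam0 * 0.5]), 0.5), 0.0)


class TestElasticNetFit:
    def test_recovers_true_support_with_low_noise(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 20))
            y = 2.0 * X[:, 3] - 1.5 * X[:, 7] + rng.normal(0, 0.2, 100)
            fit = elastic_net_fit(X, y, ElasticNetConfig())
            nz = set(np.nonzero(fit.coef)[0])
            if {3, 7} <= nz:
                hits += 1
        assert hits >= 9

    def test_degenerate_response_gives_intercept_only(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        fit = elastic_net_fit(X, np.full(10, 2.5), FAST_EN)
        assert np.allclose(fit.coef, 0.0) and fit.intercept == pytest.approx(2.5)

    def test_collinear_features_are_well_posed(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        X = np.column_stack([x, x, x + rng.normal(0, 1e-8, 30)])
        y = x + rng.normal(0, 0.3, 30)
        fit = elastic_net_fit(X, y, ElasticNetConfig(alpha_grid=(0.1, 0.5), n_lambda=20))
        assert np.isfinite(fit.coef).all()


class TestPatientLevelTable:
    def _obs(self):
        return pd.DataFrame({
            "patient_id": ["P1", "P1", "P2"],
            "subcompartment": ["ET", "NET", "ET"],
            "composition": [("CT",), ("CTpan",), ("CT",)],
            "S": [1.0, 3.0, 5.0],
        })

    def _features(self):
        return pd.DataFrame({
            "patient_id": ["P1", "P1", "P2"],
            "subcompartment": ["ET", "NET", "ET"],
            "rad_0001": [2.0, 4.0, 7.0],
        })

    def test_mean_over_available_subcompartments(self):
        out = patient_level_table(self._obs(), self._features())
        assert out.loc[out["patient_id"] == "P1", "S"].iloc[0] == pytest.approx(2.0)
        assert out.loc[out["patient_id"] == "P1", "rad_0001"].iloc[0] == pytest.approx(3.0)
        assert out.loc[out["patient_id"] == "P2", "S"].iloc[0] == pytest.approx(5.0)

    def test_median_variant_equals_mean_for_two_rows(self):
        mean = patient_level_table(self._obs(), self._features(), "mean")
        med = patient_level_table(self._obs(), self._features(), "median")
        pd.testing.assert_frame_equal(mean, med)


class TestNestedLopo:
    def _signal_table(self, rng, n=24, m=15):
        tab = null_patient_table(rng, n, m)
        tab["pathway"] = tab["rad_000"] * 1.0 + rng.normal(0, 0.4, n)
        return tab

    def test_mean_predictor_gives_r2_zero(self):
        # if every prediction equals the overall mean, R2cv is exactly 0
        rng = np.random.default_rng(5)
        y = rng.normal(size=10)
        from radgex.prediction import _pooled_metrics
        r2, mae, rho = _pooled_metrics(y, np.full(10, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_determinism_across_runs(self):
        rng = np.random.default_rng(6)
        tab = self._signal_table(rng)
        r1 = nested_lopo(tab, "pathway", FAST_EN)
        r2 = nested_lopo(tab, "pathway", FAST_EN)
        assert r1.r2_cv == r2.r2_cv
        assert [f.alpha for f in r1.fold_records] == [f.alpha for f in r2.fold_records]
        np.testing.assert_array_equal(r1.y_hat, r2.y_hat)

    def test_r2cv_metric_invariant_to_joint_affine_transform(self):
        from radgex.prediction import _pooled_metrics
        rng = np.random.default_rng(7)
        y = rng.normal(size=20)
        y_hat = y * 0.7 + rng.normal(0, 0.3, 20)
        r1, _, rho1 = _pooled_metrics(y, y_hat)
        r2, _, rho2 = _pooled_metrics(3.0 * y + 10.0, 3.0 * y_hat + 10.0)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_pipeline_invariant_to_response_scale_when_standardized(self):
        # with the standardized analysis scale, an affine change of the raw
        # pathway score leaves every fold and metric identical
        rng = np.random.default_rng(7)
        tab = self._signal_table(rng)
        r1 = nested_lopo(tab, "pathway", FAST_EN)
        tab2 = tab.copy()
        tab2["pathway"] = tab2["pathway"] * 3.0 + 10.0
        r2 = nested_lopo(tab2, "pathway", FAST_EN)
        assert r1.r2_cv == pytest.approx(r2.r2_cv, abs=1e-9)
        np.testing.assert_allclose(r1.y_hat, r2.y_hat, atol=1e-9)

    def test_leakage_canary_nested_vs_legacy(self):
        """Perturbing the held-out score never changes that fold in nested mode."""
        rng = np.random.default_rng(8)
        tab = self._signal_table(rng)
        i = 3
        res1 = nested_lopo(tab, "pathway", FAST_EN, standardize_response=False)
        tab2 = tab.copy()
        tab2.loc[i, "pathway"] = tab2.loc[i, "pathway"] + 50.0
        res2 = nested_lopo(tab2, "pathway", FAST_EN, standardize_response=False)
        assert res1.fold_records[i].selected == res2.fold_records[i].selected
        assert res1.fold_records[i].prediction == pytest.approx(
            res2.fold_records[i].prediction, abs=1e-9)
        # legacy mode screens on all patients, so the same perturbation CAN leak
        leg1 = legacy_prescreened_cv(tab, "pathway", FAST_EN)
        leg2 = legacy_prescreened_cv(tab2, "pathway", FAST_EN)
        assert (leg1.fold_records[i].selected != leg2.fold_records[i].selected
                or leg1.fold_records[i].prediction != leg2.fold_records[i].prediction)

    def test_no_signal_pathway_reports_status(self):
        rng = np.random.default_rng(9)
        tab = null_patient_table(rng, n=12, m=5)
        res = nested_lopo(tab, "pathway", FAST_EN)
        assert res.status == "no_signal"
        assert res.r2_cv <= 0.0


class TestBootstrapCi:
    def test_perfect_predictions_give_unit_interval(self):
        y = np.arange(10.0)
        lo, hi = bootstrap_ci(y, y.copy(), B=300, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_seeded_and_self_consistent(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=25)
        y_hat = y * 0.6 + rng.normal(0, 0.5, 25)
        a = bootstrap_ci(y, y_hat, B=500, seed=1)
        b = bootstrap_ci(y, y_hat, B=500, seed=1)
        assert a == b
        big = bootstrap_ci(y, y_hat, B=5000, seed=2)
        assert a[0] == pytest.approx(big[0], abs=0.1)
        assert a[1] == pytest.approx(big[1], abs=0.1)

    def test_rejects_tiny_inputs(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.arange(4.0), np.arange(4.0), B=300)
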