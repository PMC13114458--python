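"""Mixed-model association: variance components, LRT, R² decomposition."""

import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import null_lmm_frame, unbalanced_design
from radgex._lmm_core import fit_random_intercept_ml
from radgex.lmm import (COVARIATE_MODELS, covariate_ladder, fit_lmm_pair,
                        prepare_lmm_table, run_lmm_campaign, zscore)
from radgex.reduction import ScreenResult


class TestZscore:
    def test_global(self):
        np.testing.assert_allclose(zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_within_group(self):
        z = zscore([1.0, 3.0, 1.0, 3.0], groups=["a", "a", "b", "b"])
        np.testing.assert_allclose(z, [-0.7071067811865475, 0.7071067811865475] * 2)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            zscore([1.0, 1.0, 1.0])


class TestVarianceComponents:
    def test_balanced_anova_closed_form(self):
        """ML variance components equal the closed-form one-way decomposition."""
        rng = np.random.default_rng(7)
        m, k = 40, 2
        b = rng.normal(0, 1.0, m)
        y = np.repeat(b, k) + rng.normal(0, 0.8, m * k)
        fit = fit_random_intercept_ml(y, np.ones((m * k, 1)), np.repeat(np.arange(m), k))
        ybar_i = y.reshape(m, k).mean(1)
        msw = ((y.reshape(m, k) - ybar_i[:, None]) ** 2).sum() / (m * (k - 1))
        between = k * ((ybar_i - y.mean()) ** 2).sum()
        sig_b = (between / m - msw) / k
        assert fit.var_intercept == pytest.approx(sig_b, abs=1e-6)
        assert fit.var_resid == pytest.approx(msw, abs=1e-6)

    def test_agrees_with_statsmodels_ml(self):
        from statsmodels.regression.mixed_linear_model import MixedLM
        rng = np.random.default_rng(8)
        n = 60
        groups = np.repeat(np.arange(20), 3)
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ [0.5, 1.0, -0.3] + np.repeat(rng.normal(0, 0.8, 20), 3) + rng.normal(0, 0.6, n)
        ours = fit_random_intercept_ml(y, X, groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm = MixedLM(y, X, groups=groups).fit(reml=False)
        assert ours.llf == pytest.approx(sm.llf, abs=1e-6)
        np.testing.assert_allclose(ours.fe_params, sm.fe_params, atol=1e-5)

    def test_boundary_zero_between_variance(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=60)  # no patient structure at all
        fit = fit_random_intercept_ml(y, np.ones((60, 1)), np.repeat(np.arange(20), 3))
        assert fit.var_intercept == pytest.approx(0.0, abs=1e-6)


class TestFitLmmPair:
    def test_icc_recovers_known_variance_ratio(self):
        """var(intercept)=1, var(resid)=1 at n=200 patients -> ICC ~ 0.5."""
        rng = np.random.default_rng(10)
        m = 200
        df = unbalanced_design(m, m, m)  # 3 rows per patient, balanced
        pats = df["patient_id"].unique()
        b = {p: rng.normal(0, 1.0) for p in pats}
        df["z_pathway"] = df["patient_id"].map(b) + rng.normal(0, 1.0, len(df))
        df["z_rad_0"] = rng.normal(size=len(df))
        res = fit_lmm_pair(df, ["z_rad_0"])
        assert res.icc == pytest.approx(0.5, abs=0.1)

    def test_exact_response_gives_saturated_fit(self):
        rng = np.random.default_rng(11)
        df = unbalanced_design()
        for j in range(3):
            df[f"z_rad_{j}"] = rng.normal(size=len(df))
        df["z_pathway"] = df["z_rad_0"]
        res = fit_lmm_pair(df, [f"z_rad_{j}" for j in range(3)])
        assert res.r2m_full > 0.999
        assert res.chi2 > 100
        assert res.lrt_p < 1e-10

    def test_r2_invariant_to_response_shift_and_r2c_dominates(self):
        rng = np.random.default_rng(12)
        df = null_lmm_frame(rng, k=2)
        r1 = fit_lmm_pair(df, ["z_rad_0", "z_rad_1"])
        df2 = df.copy()
        df2["z_pathway"] = df2["z_pathway"] + 5.0
        r2 = fit_lmm_pair(df2, ["z_rad_0", "z_rad_1"])
        assert r1.r2m_full == pytest.approx(r2.r2m_full, abs=1e-6)
        assert r1.r2c == pytest.approx(r2.r2c, abs=1e-6)
        assert r1.r2c >= r1.r2m_full - 1e-9
        assert 0.0 <= r1.icc <= 1.0
        assert r1.chi2 >= 0.0

    def test_null_chi2_matches_reference_distribution_loosely(self):
        """Null chi2 values follow their asymptotic shape by rank correlation."""
        from scipy import stats
        rng = np.random.default_rng(13)
        chis = np.array([fit_lmm_pair(null_lmm_frame(rng, k=2),
                                      ["z_rad_0", "z_rad_1"]).chi2 for _ in range(120)])
        qq_theory = stats.chi2.ppf((np.arange(120) + 0.5) / 120, df=2)
        r = np.corrcoef(np.sort(chis), qq_theory)[0, 1]
        assert r > 0.95

    def test_f_adjusted_reference_is_less_anticonservative(self):
        rng = np.random.default_rng(14)
        p_chi, p_f = [], []
        for _ in range(120):
            df = null_lmm_frame(rng, k=5)
            terms = [f"z_rad_{j}" for j in range(5)]
            p_chi.append(fit_lmm_pair(df, terms).lrt_p)
            p_f.append(fit_lmm_pair(df, terms, lrt_reference="f_adjusted").lrt_p)
        assert np.mean(np.array(p_f) < 0.05) < np.mean(np.array(p_chi) < 0.05)


class TestCampaign:
    def _screens(self, selected):
        return {name: ScreenResult(name, "per_subcompartment", pd.DataFrame(), sel)
                for name, sel in selected.items()}

    def test_empty_selections_get_p_one_and_padded_fdr(self):
        rng = np.random.default_rng(15)
        df = unbalanced_design()
        feats = df.copy()
        feats["rad_0001"] = rng.normal(size=len(df))
        obs = df.copy()
        obs["SET_A"] = feats["rad_0001"] + rng.normal(0, 0.3, len(df))  # real signal
        obs["SET_B"] = rng.normal(size=len(df))
        obs["composition"] = [("CT",)] * len(df)
        screens = self._screens({"SET_A": ["rad_0001"], "SET_B": []})
        out = run_lmm_campaign(obs, feats, screens, n_total_pathways=24)
        row_b = out[out["set_name"] == "SET_B"].iloc[0]
        assert row_b["lrt_p"] == 1.0 and row_b["k"] == 0
        row_a = out[out["set_name"] == "SET_A"].iloc[0]
        # padded BH: adjusted = p * 24 / 1 for the single tested pathway
        assert row_a["fdr"] == pytest.approx(min(1.0, row_a["lrt_p"] * 24), rel=1e-9)

    def test_all_empty_gives_all_fdr_one(self):
        df = unbalanced_design()
        obs = df.copy()
        obs["SET_A"] = 0.0
        obs["composition"] = [("CT",)] * len(df)
        out = run_lmm_campaign(obs, df.copy(), self._screens({"SET_A": []}), 24)
        assert (out["fdr"] == 1.0).all()


class TestCovariateLadder:
    def test_irrelevant_covariates_leave_lrt_stable(self):
        rng = np.random.default_rng(16)
        df = null_lmm_frame(rng, k=2)
        df["z_pathway"] = df["z_rad_0"] * 0.8 + df["z_pathway"]
        pats = df["patient_id"].unique()
        cov = pd.DataFrame({"patient_id": pats,
                            "age": rng.normal(58, 8, len(pats)),
                            "mgmt_status": rng.integers(0, 2, len(pats)),
                            "subtype": rng.choice(["CL", "MES", "PN"], len(pats))})
        df = df.merge(cov, on="patient_id")
        out = covariate_ladder(df, ["z_rad_0", "z_rad_1"])
        assert set(out) == set(COVARIATE_MODELS)
        ps = [out[k].lrt_p for k in "ABCD"]
        assert all(p < 0.01 for p in ps)  # signal survives every rung

    def test_subtype_effect_raises_marginal_r2(self):
        rng = np.random.default_rng(17)
        df = null_lmm_frame(rng, k=1)
        pats = df["patient_id"].unique()
        subtype = {p: rng.choice(["CL", "MES", "PN"]) for p in pats}
        shift = {"CL": -1.0, "MES": 1.0, "PN": 0.0}
        df["z_pathway"] += df["patient_id"].map(lambda p: shift[subtype[p]])
        cov = pd.DataFrame({"patient_id": pats, "age": rng.normal(58, 8, len(pats)),
                            "mgmt_status": rng.integers(0, 2, len(pats)),
                            "subtype": [subtype[p] for p in pats]})
        df = df.merge(cov, on="patient_id")
        out = covariate_ladder(df, ["z_rad_0"])
        assert out["D"].r2m_full > out["C"].r2m_full + 0.05
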