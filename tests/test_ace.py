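"""FIML engine: covariance algebra, likelihood, fitting, CIs, comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twinace as ta
from twinace.ace import (BivariateACEParams, FitResult, UnivariateACEParams,
                         expected_cov_bivariate, expected_cov_univariate,
                         fiml_neg2ll)


def _params(a2, c2, e2, mu=0.0):
    return UnivariateACEParams(a=math.sqrt(a2), c=math.sqrt(c2),
                               e=math.sqrt(e2), mu=mu)


class TestExpectedCov:
    def test_perfect_genetic_determination(self):
        p = UnivariateACEParams(a=1, c=0, e=0)
        assert np.allclose(expected_cov_univariate(p, "MZ"), [[1, 1], [1, 1]])

    def test_full_ace_paranoia_implies_mz_icc(self):
        # standardized (.45, .07, .48) implies MZ correlation .52
        p = _params(0.45, 0.07, 0.48)
        sigma = expected_cov_univariate(p, "MZ")
        assert sigma[0, 1] / sigma[0, 0] == pytest.approx(0.52, abs=1e-12)

    def test_dz_offdiagonal_identity(self):
        p = UnivariateACEParams(a=0.7, c=0.3, e=0.55)
        mz = expected_cov_univariate(p, "MZ")
        dz = expected_cov_univariate(p, "DZ")
        assert dz[0, 1] == pytest.approx(mz[0, 1] - p.a ** 2 / 2, abs=1e-12)

    def test_bivariate_block_diagonal_when_uncorrelated(self):
        p = BivariateACEParams(a_x=0.6, c_x=0.4, e_x=0.5,
                               a_y=0.7, c_y=0.2, e_y=0.6)
        sigma = expected_cov_bivariate(p, "MZ")
        assert sigma[0, 1] == 0 and sigma[0, 3] == 0 and sigma[1, 2] == 0

    def test_bivariate_implied_phenotypic_correlation(self):
        p = BivariateACEParams(
            a_x=math.sqrt(0.35), c_x=math.sqrt(0.26), e_x=math.sqrt(0.39),
            a_y=math.sqrt(0.52), c_y=0.0, e_y=math.sqrt(0.48),
            r_a=0.55, r_c=0.0, r_e=0.04)
        sigma = expected_cov_bivariate(p, "MZ")
        expect = math.sqrt(0.35 * 0.52) * 0.55 + math.sqrt(0.39 * 0.48) * 0.04
        assert sigma[0, 1] == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.252, abs=5e-4)

    def test_mz_minus_dz_ctct_identity(self):
        p = BivariateACEParams(a_x=0.5, c_x=0.45, e_x=0.6,
                               a_y=0.65, c_y=0.3, e_y=0.5,
                               r_a=0.4, r_c=0.3, r_e=0.2)
        mz = expected_cov_bivariate(p, "MZ")
        dz = expected_cov_bivariate(p, "DZ")
        assert mz[0, 3] - dz[0, 3] == pytest.approx(
            0.5 * p.a_x * p.a_y * p.r_a, abs=1e-12)


class TestFimlNeg2ll:
    def test_single_observed_value_univariate_density(self):
        y = 1.7
        pairs = pd.DataFrame({"family_id": ["F0"], "zygosity": ["MZ"],
                              "sex_1": [0], "sex_2": [0], "age": [16.0],
                              "y_1": [y], "y_2": [np.nan]})
        eye = {"MZ": np.eye(2), "DZ": np.eye(2)}
        zero = {"MZ": np.zeros(2), "DZ": np.zeros(2)}
        val = fiml_neg2ll(pairs, "y", zero, eye)
        assert val == pytest.approx(math.log(2 * math.pi) + y ** 2, abs=1e-10)

    def test_complete_data_matches_sufficient_statistic_form(self, bullying_residualized):
        p = _params(0.35, 0.26, 0.39)
        means = {z: np.zeros(2) for z in ("MZ", "DZ")}
        covs = {z: expected_cov_univariate(p, z) for z in ("MZ", "DZ")}
        val = fiml_neg2ll(bullying_residualized, "bullying", means, covs)
        # closed-form complete-data oracle per zygosity group
        oracle = 0.0
        for zyg in ("MZ", "DZ"):
            sub = bullying_residualized[bullying_residualized["zygosity"] == zyg]
            Y = sub[["bullying_1", "bullying_2"]].to_numpy()
            n = len(Y)
            m = Y.mean(axis=0)
            S = np.cov(Y.T, ddof=0)
            sig = covs[zyg]
            inv = np.linalg.inv(sig)
            oracle += n * (math.log(np.linalg.det(sig)) + np.trace(inv @ S)
                           + (m - means[zyg]) @ inv @ (m - means[zyg])
                           + 2 * math.log(2 * math.pi))
        assert val == pytest.approx(oracle, abs=1e-6)

    def test_missingness_only_changes_that_pairs_contribution(self):
        spec = ta.UnivariateGenSpec(a2=0.4, c2=0.2, e2=0.4, n_mz=30, n_dz=30, seed=8)
        pairs = ta.simulate_univariate(spec)
        p = _params(0.4, 0.2, 0.4)
        means = {z: np.zeros(2) for z in ("MZ", "DZ")}
        covs = {z: expected_cov_univariate(p, z) for z in ("MZ", "DZ")}
        base = fiml_neg2ll(pairs, "trait", means, covs)
        dropped = pairs.copy()
        y1, y2 = dropped.loc[0, "trait_1"], dropped.loc[0, "trait_2"]
        dropped.loc[0, "trait_2"] = np.nan
        after = fiml_neg2ll(dropped, "trait", means, covs)
        # difference equals this pair's bivariate minus univariate contribution
        sig = covs["MZ"]
        pair_full = (2 * math.log(2 * math.pi) + math.log(np.linalg.det(sig))
                     + np.array([y1, y2]) @ np.linalg.inv(sig) @ np.array([y1, y2]))
        pair_one = math.log(2 * math.pi) + math.log(sig[0, 0]) + y1 ** 2 / sig[0, 0]
        assert base - after == pytest.approx(pair_full - pair_one, abs=1e-8)

    def test_singular_covariance_rejected(self):
        pairs = pd.DataFrame({"family_id": ["F0"], "zygosity": ["MZ"],
                              "sex_1": [0], "sex_2": [0], "age": [16.0],
                              "y_1": [0.3], "y_2": [0.1]})
        sing = {"MZ": np.ones((2, 2)), "DZ": np.eye(2)}
        zero = {"MZ": np.zeros(2), "DZ": np.zeros(2)}
        assert fiml_neg2ll(pairs, "y", zero, sing) >= 1e11  # flagged as unusable


class TestFitModel:
    def test_saturated_minus2ll_equals_sample_ml_moments(self, bullying_residualized):
        sat = ta.fit_model(bullying_residualized, ta.ModelSpec("saturated", ("bullying",)))
        means, covs = {}, {}
        for zyg in ("MZ", "DZ"):
            sub = bullying_residualized[bullying_residualized["zygosity"] == zyg]
            Y = sub[["bullying_1", "bullying_2"]].to_numpy()
            means[zyg] = Y.mean(axis=0)
            covs[zyg] = np.cov(Y.T, ddof=0)
        direct = fiml_neg2ll(bullying_residualized, "bullying", means, covs)
        assert sat.minus2ll == pytest.approx(direct, abs=1e-6)

    def test_estimates_recover_generating_values(self, bullying_residualized):
        fit = ta.fit_model(bullying_residualized, ta.ModelSpec("ACE", ("bullying",)))
        assert fit.converged
        # single cohort at the paper's n: estimates within ~3 sampling SDs
        assert fit.estimates["a2"] == pytest.approx(0.35, abs=0.15)
        assert fit.estimates["c2"] == pytest.approx(0.26, abs=0.13)
        assert fit.estimates["e2"] == pytest.approx(0.39, abs=0.06)

    def test_ce_misfit_far_exceeds_ace_on_genetic_data(self, bullying_residualized):
        sat = ta.fit_model(bullying_residualized, ta.ModelSpec("saturated", ("bullying",)))
        ace = ta.fit_model(bullying_residualized, ta.ModelSpec("ACE", ("bullying",)))
        ce = ta.fit_model(bullying_residualized, ta.ModelSpec("CE", ("bullying",)))
        rows = ta.compare_models([ace, ce], sat)
        lrt = {r.model: r.lrt for r in rows if r.lrt is not None}
        assert lrt["CE"] > lrt["ACE"] + 20

    def test_nesting_monotonicity(self, bullying_residualized):
        m2 = {}
        for fam in ("saturated", "ACE", "CE", "E"):
            m2[fam] = ta.fit_model(bullying_residualized,
                                   ta.ModelSpec(fam, ("bullying",))).minus2ll
        assert m2["E"] >= m2["CE"] - 1e-6
        assert m2["CE"] >= m2["ACE"] - 1e-6
        assert m2["ACE"] >= m2["saturated"] - 1e-6

    def test_df_bookkeeping_univariate(self, bullying_residualized):
        sat = ta.fit_model(bullying_residualized, ta.ModelSpec("saturated", ("bullying",)))
        ace = ta.fit_model(bullying_residualized, ta.ModelSpec("ACE", ("bullying",)))
        ae = ta.fit_model(bullying_residualized, ta.ModelSpec("AE", ("bullying",)))
        assert sat.n_free == 10 and ace.n_free == 4
        assert ace.df - sat.df == 6
        assert ae.df - sat.df == 7

    def test_df_bookkeeping_bivariate(self, bivariate_residualized):
        sat = ta.fit_model(bivariate_residualized,
                           ta.ModelSpec("saturated", ("bullying", "paranoia")))
        full = ta.fit_model(bivariate_residualized,
                            ta.ModelSpec("ACE", ("bullying", "paranoia")))
        drop = ta.fit_model(bivariate_residualized,
                            ta.ModelSpec("ACE_drop_rc", ("bullying", "paranoia")))
        assert sat.n_free == 28 and full.n_free == 11
        assert full.df - sat.df == 17
        assert drop.df - sat.df == 18

    def test_standardized_components_sum_to_one(self, bivariate_residualized):
        fit = ta.fit_model(bivariate_residualized,
                           ta.ModelSpec("ACE_drop_rc", ("bullying", "paranoia")))
        est = fit.estimates
        assert est["a2_x"] + est["c2_x"] + est["e2_x"] == pytest.approx(1, abs=1e-10)
        assert est["biva2"] + est["bivc2"] + est["bive2"] == pytest.approx(1, abs=1e-10)


class TestProfileCI:
    def test_matches_delta_method_at_large_n(self):
        spec = ta.UnivariateGenSpec(a2=0.4, c2=0.2, e2=0.4, n_mz=4000,
                                    n_dz=4000, seed=31, beta_sex=0, beta_age=0)
        pairs = ta.residualize_pairs(ta.simulate_univariate(spec), "trait")
        est = ta.UnivariateACE(model="ACE", trait="trait").fit(pairs)
        lo, hi = est.profile_ci("a2")
        # delta-method oracle: numeric Hessian of -2LL over free params
        from twinace.ace import _objective
        fun = _objective(est._family_obj, est._patterns)
        th = est.theta_
        h = 1e-4
        k = len(th)
        H = np.zeros((k, k))
        for i in range(k):
            for j in range(i, k):
                pp = th.copy(); pp[i] += h; pp[j] += h
                pm = th.copy(); pm[i] += h; pm[j] -= h
                mp = th.copy(); mp[i] -= h; mp[j] += h
                mm = th.copy(); mm[i] -= h; mm[j] -= h
                H[i, j] = H[j, i] = (fun(pp) - fun(pm) - fun(mp) + fun(mm)) / (4 * h * h)
        cov = 2 * np.linalg.inv(H)
        grad = np.zeros(k)
        for i in range(k):
            pp = th.copy(); pp[i] += h
            pm = th.copy(); pm[i] -= h
            grad[i] = (est._family_obj.reportable(pp)["a2"]
                       - est._family_obj.reportable(pm)["a2"]) / (2 * h)
        se = math.sqrt(grad @ cov @ grad)
        a2 = est.estimates_["a2"]
        assert lo == pytest.approx(a2 - 1.96 * se, abs=0.015 * max(se * 4, 1))
        assert hi - lo == pytest.approx(2 * 1.96 * se, rel=0.05)

    def test_dropped_parameter_rejected(self, bivariate_residualized):
        est = ta.BivariateACE(model="ACE_drop_rc", trait_x="bullying",
                              trait_y="paranoia").fit(bivariate_residualized)
        with pytest.raises(ValueError, match="not a free parameter"):
            est.profile_ci("r_c")

    def test_bounds_respect_domain(self, bivariate_residualized):
        est = ta.BivariateACE(model="ACE_drop_rc", trait_x="bullying",
                              trait_y="paranoia").fit(bivariate_residualized)
        lo, hi = est.profile_ci("biva2")
        assert lo <= est.estimates_["biva2"] <= hi
        assert hi <= 1.0 + 1e-9


class TestCompareModels:
    @staticmethod
    def _mk(model, m2ll, df, n_pairs=3268):
        return FitResult(model=model, minus2ll=m2ll, df=df, n_free=0,
                         n_obs=0, estimates={}, params=None,
                         n_used={"MZ": n_pairs // 2, "DZ": n_pairs - n_pairs // 2},
                         converged=True, boundary=False)

    def test_lrt_from_printed_minus2ll(self):
        # AE vs saturated: 23513.44 - 23507.87 = 5.57 on 7 df, p ~ .59
        sat = self._mk("saturated", 23507.87, 6525)
        ae = self._mk("AE", 23513.44, 6532)
        rows = ta.compare_models([ae], sat)
        assert rows[1].lrt == pytest.approx(5.57, abs=1e-9)
        assert rows[1].delta_df == 7
        assert rows[1].p == pytest.approx(stats.chi2.sf(5.57, 7), abs=1e-12)
        assert rows[1].p == pytest.approx(0.59, abs=0.01)

    def test_model_compared_to_itself(self):
        sat = self._mk("saturated", 1000.0, 500)
        rows = ta.compare_models([self._mk("saturated2", 1000.0, 500)], sat)
        assert rows[1].lrt == 0.0 and rows[1].p == 1.0

    def test_bic_difference_at_back_computed_n(self):
        # ACE vs CE for the paranoia fits at ln(N) = 8.101
        n = round(math.exp(8.101))
        sat = self._mk("saturated", 23507.87, 6525, n)
        ace = self._mk("ACE", 23511.61, 6531, n)
        ce = self._mk("CE", 23580.53, 6532, n)
        rows = ta.compare_models([ace, ce], sat, n_for_bic=n)
        diff = rows[2].bic - rows[1].bic
        assert diff == pytest.approx(-29335.67 - (-29396.49), abs=0.05)

    def test_negative_lrt_rejected(self):
        sat = self._mk("saturated", 1000.0, 500)
        with pytest.raises(ValueError, match="negative LRT"):
            ta.compare_models([self._mk("ACE", 999.0, 506)], sat)

    def test_select_best_prefers_parsimonious_unrejected(self):
        n = 3268
        sat = self._mk("saturated", 23507.87, 6525, n)
        ace = self._mk("ACE", 23511.61, 6531, n)
        ae = self._mk("AE", 23513.44, 6532, n)
        ce = self._mk("CE", 23580.53, 6532, n)
        rows = ta.compare_models([ace, ae, ce], sat)
        assert ta.select_best(rows) == "AE"


class TestFalconer:
    def test_bullying_iccs(self):
        # 2(.62-.42)=.40, 2*.42-.62=.22, 1-.62=.38
        assert ta.falconer_univariate(0.62, 0.42) == pytest.approx(
            (0.40, 0.22, 0.38), abs=1e-12)

    def test_exact_ae_pattern(self):
        assert ta.falconer_univariate(0.5, 0.25) == pytest.approx(
            (0.5, 0.0, 0.5), abs=1e-12)

    def test_no_truncation(self):
        a2, c2, e2 = ta.falconer_univariate(0.8, 0.2)
        assert c2 < 0  # may exit [0, 1]; caller decides

    def test_fiml_equivalence_on_moment_matched_data(self, moment_matched_pairs):
        # just-identified case: ML estimates equal the Falconer solution
        fit = ta.fit_model(moment_matched_pairs, ta.ModelSpec("ACE", ("y",)))
        a2, c2, e2 = ta.falconer_univariate(0.6, 0.4)
        assert fit.estimates["a2"] == pytest.approx(a2, abs=1e-4)
        assert fit.estimates["c2"] == pytest.approx(c2, abs=1e-4)
        assert fit.estimates["e2"] == pytest.approx(e2, abs=1e-4)

    def test_bivariate_ctct_decomposition(self):
        a_cov, c_cov, e_cov = ta.falconer_bivariate(0.26, 0.12, 0.26)
        assert (a_cov, c_cov, e_cov) == pytest.approx((0.28, -0.02, 0.0), abs=1e-12)

    def test_equal_ctct_gives_zero_genetic_covariance(self):
        a_cov, _, _ = ta.falconer_bivariate(0.2, 0.2, 0.3)
        assert a_cov == 0.0

    def test_components_conserve_phenotypic_r(self):
        a_cov, c_cov, e_cov = ta.falconer_bivariate(0.31, 0.17, 0.24)
        assert a_cov + c_cov + e_cov == pytest.approx(0.24, abs=1e-12)


class TestDerivedBivariate:
    def test_printed_best_fit_solution_gives_93_percent(self):
        p = BivariateACEParams(
            a_x=math.sqrt(0.35), c_x=math.sqrt(0.26), e_x=math.sqrt(0.39),
            a_y=math.sqrt(0.52), c_y=0.0, e_y=math.sqrt(0.48),
            r_a=0.55, r_c=0.0, r_e=0.04)
        d = ta.derived_bivariate(p)
        assert d["biva2"] == pytest.approx(0.93, abs=0.005)

    def test_pure_genetic_overlap(self):
        p = BivariateACEParams(a_x=0.6, c_x=0.4, e_x=0.5,
                               a_y=0.7, c_y=0.2, e_y=0.6, r_a=0.5)
        assert ta.derived_bivariate(p)["biva2"] == pytest.approx(1.0, abs=1e-12)

    def test_shares_sum_to_one(self):
        p = BivariateACEParams(a_x=0.5, c_x=0.45, e_x=0.6,
                               a_y=0.65, c_y=0.3, e_y=0.5,
                               r_a=0.4, r_c=0.3, r_e=0.2)
        d = ta.derived_bivariate(p)
        assert d["biva2"] + d["bivc2"] + d["bive2"] == pytest.approx(1, abs=1e-10)

    def test_zero_implied_correlation_is_error(self):
        p = BivariateACEParams(a_x=0.6, c_x=0.4, e_x=0.5,
                               a_y=0.7, c_y=0.2, e_y=0.6)
        with pytest.raises(ValueError, match="undefined"):
            ta.derived_bivariate(p)
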