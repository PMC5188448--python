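"""Logistic/linear engine: closed-form oracles and stratified-fit properties."""

import numpy as np
import pandas as pd
import pytest

import obgrs
from obgrs.association import (DesignError, SeparationError, build_design,
                               fit_logistic, interaction_test, lrt,
                               stratified_or)
from obgrs.simulate import SimulationConfig, simulate_cohort


def subjects_from_2x2(a, b, c, d):
    """Subject-level data for a 2x2 table: (exposed cases, exposed non-cases,
    unexposed cases, unexposed non-cases)."""
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return y, x


def design_with_const(x):
    return pd.DataFrame({"const": 1.0, "x": x})


class TestLogisticOracle:
    def test_or_equals_cross_product_ratio(self):
        """Saturated MLE: OR from the fit equals ad/bc exactly (a=20,b=80,c=10,d=90)."""
        y, x = subjects_from_2x2(20, 80, 10, 90)
        fit = fit_logistic(y, design_with_const(x))
        assert np.exp(fit.params[1]) == pytest.approx(2.25, rel=1e-8)

    def test_wald_ci_closed_form(self):
        y, x = subjects_from_2x2(20, 80, 10, 90)
        fit = fit_logistic(y, design_with_const(x))
        se = np.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90)
        lo, hi = np.exp(np.log(2.25) + np.array([-1, 1]) * 1.959963984540054 * se)
        b, s = fit.params[1], fit.bse[1]
        assert np.exp(b - 1.959963984540054 * s) == pytest.approx(lo, rel=1e-6)
        assert np.exp(b + 1.959963984540054 * s) == pytest.approx(hi, rel=1e-6)

    @pytest.mark.parametrize("table", [(5, 7, 11, 13), (1, 9, 3, 2), (40, 2, 7, 33)])
    def test_cross_product_identity_random_tables(self, table):
        a, b, c, d = table
        y, x = subjects_from_2x2(a, b, c, d)
        fit = fit_logistic(y, design_with_const(x))
        assert np.exp(fit.params[1]) == pytest.approx(a * d / (b * c), rel=1e-8)

    def test_null_balanced_table_gives_or_one(self):
        y, x = subjects_from_2x2(25, 75, 25, 75)
        fit = fit_logistic(y, design_with_const(x))
        assert np.exp(fit.params[1]) == pytest.approx(1.0, abs=1e-10)

    def test_perfect_separation_flagged(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(SeparationError):
            fit_logistic(y, design_with_const(x))

    def test_rank_deficiency_names_columns(self):
        y, x = subjects_from_2x2(20, 80, 10, 90)
        X = design_with_const(x)
        X["x_copy"] = X["x"]
        with pytest.raises(DesignError, match="x"):
            fit_logistic(y, X)

    def test_single_class_outcome_is_error(self):
        with pytest.raises(DesignError):
            fit_logistic(np.zeros(10), design_with_const(np.arange(10) % 2))


class TestLRT:
    def test_statistic_matches_saturated_deviance_oracle(self):
        """2x2 LRT equals the closed-form binomial deviance difference."""
        a, b, c, d = 20, 80, 10, 90
        y, x = subjects_from_2x2(a, b, c, d)
        full = fit_logistic(y, design_with_const(x))
        red = fit_logistic(y, pd.DataFrame({"const": np.ones_like(y)}))
        stat, df, p = lrt(full, red)

        def bin_ll(k, n):
            p_hat = k / n
            return k * np.log(p_hat) + (n - k) * np.log(1 - p_hat)

        n = a + b + c + d
        ll_sat = bin_ll(a, a + b) + bin_ll(c, c + d)
        ll_null = bin_ll(a + c, n)
        assert stat == pytest.approx(2 * (ll_sat - ll_null), rel=1e-8)
        assert df == 1

    def test_nonnegative_and_scale_invariant(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 * x)))).astype(float)
        X1 = pd.DataFrame({"const": 1.0, "x": x, "z": z})
        X2 = X1.assign(z=z * 1000.0)  # covariate rescaling
        red = fit_logistic(y, X1[["const", "z"]])
        s1 = lrt(fit_logistic(y, X1), red)[0]
        red2 = fit_logistic(y, X2[["const", "z"]])
        s2 = lrt(fit_logistic(y, X2), red2)[0]
        assert s1 >= 0
        assert s1 == pytest.approx(s2, rel=1e-6)


@pytest.fixture(scope="module")
def effect_cohort():
    return simulate_cohort(SimulationConfig(bmi_genotype_effect_t2d=0.0), seed=99)


class TestStratifiedOR:
    def test_stratified_equals_full_interaction_model(self, effect_cohort):
        """Stratified fits with no shared covariates reproduce the saturated
        interaction model's implied stratum effects."""
        cohort = effect_cohort
        df = cohort.data
        from obgrs.association import _genotype_columns
        gdf, gcols, _ = _genotype_columns(cohort, "rs7903146", "codominant")
        ob = df["obesity"].astype(float)
        X = pd.DataFrame({"const": 1.0}, index=df.index)
        X["ob"] = ob
        for g in gcols:
            X[g] = gdf[g]
            X[f"{g}_x"] = gdf[g] * ob
        keep = X.notna().all(axis=1)
        full = fit_logistic(df.loc[keep, "t2d_prevalent"].astype(int), X[keep])
        params = pd.Series(full.params, index=X.columns)

        for stratum_val, mask in ((0, ~df["obesity"]), (1, df["obesity"])):
            sub = df[mask]
            gsub = gdf[mask]
            Xs = pd.concat([pd.Series(1.0, index=sub.index, name="const"), gsub], axis=1)
            keep_s = Xs.notna().all(axis=1)
            fit_s = fit_logistic(sub.loc[keep_s, "t2d_prevalent"].astype(int), Xs[keep_s])
            ps = pd.Series(fit_s.params, index=Xs.columns)
            for g in gcols:
                implied = params[g] + stratum_val * params[f"{g}_x"]
                assert ps[g] == pytest.approx(implied, abs=1e-6)

    def test_effect_pattern_recovered(self, effect_cohort):
        """One draw at the generating OR pattern (non-obese 1.78/2.26 per het/hom,
        obese 1.27/1.53): stratified CIs cover the generating values."""
        res = stratified_or(effect_cohort, "rs7903146", model="Model1")
        gen = {("non-obese", "CT vs CC"): 1.78, ("non-obese", "TT vs CC"): 2.26,
               ("obese", "CT vs CC"): 1.27, ("obese", "TT vs CC"): 1.53}
        for r in res:
            target = gen[(r.stratum, r.contrast)]
            assert r.ci_low < target < r.ci_high
        assert all(r.p_interaction < 0.05 for r in res)

    def test_null_cohort_or_near_one(self):
        from obgrs.simulate import null_effect_config
        cohort = simulate_cohort(null_effect_config(n_subjects=4000), seed=17)
        res = stratified_or(cohort, "rs7903146", model="Model1")
        for r in res:
            assert r.ci_low < 1.0 < r.ci_high

    def test_degenerate_stratum_flagged_not_fatal(self):
        from conftest import make_phenotype_frame
        from obgrs.cohort import SNPAnnotation, load_cohort
        ann = SNPAnnotation("rs7903146", "TCF7L2", "C", "T", "T")
        df = make_phenotype_frame(
            8,
            genotypes={"rs7903146": ["CC", "CT", "TT", "CC", "CT", "TT", "CC", "CT"]},
            bmi=[25, 25, 25, 25, 35, 35, 35, 35],
            t2d_prevalent=[True, False, True, False, False, False, False, False],
        )
        cohort = load_cohort(df, annotations=[ann])
        res = stratified_or(cohort, "rs7903146", model="Model1")
        obese = [r for r in res if r.stratum == "obese"]
        assert all(np.isnan(r.or_value) for r in obese)  # outcome prevalence 0

    def test_outcome_equal_stratifier_rejected(self, effect_cohort):
        with pytest.raises(DesignError):
            stratified_or(effect_cohort, "rs7903146", outcome="obesity", stratify_by="obesity")


class TestLinearTrait:
    def test_adjusted_means_equal_raw_means_when_unadjusted(self):
        """Closed-form oracle: with no covariates the adjusted genotype means
        are the raw cell means."""
        cfg = SimulationConfig(n_subjects=3000, bmi_genotype_effect_t2d=-0.8)
        cohort = simulate_cohort(cfg, seed=5)
        res0 = obgrs.fit_linear_trait(cohort, "rs7903146", trait="bmi", model=())
        df = cohort.data
        from obgrs.cohort import additive_codes
        dose = additive_codes(cohort, "rs7903146")
        for s_name, s_mask in (("non-T2D", ~df["t2d_prevalent"]), ("T2D", df["t2d_prevalent"])):
            for geno, g_val in (("ref", 0), ("het", 1), ("hom", 2)):
                raw = df.loc[s_mask & (dose == g_val), "bmi"].mean()
                assert res0["adjusted_means"][s_name][geno] == pytest.approx(raw, abs=1e-8)

    def test_t2d_confined_effect_detected(self):
        """A -0.8 kg/m2 per-allele BMI effect confined to diabetic subjects
        yields a significant genotype-by-T2D interaction at cohort scale."""
        cfg = SimulationConfig(bmi_genotype_effect_t2d=-0.8)
        cohort = simulate_cohort(cfg, seed=21)
        res = obgrs.fit_linear_trait(cohort, "rs7903146", trait="bmi", model="Model2")
        assert res["p_interaction"] < 0.05
        means = res["adjusted_means"]
        assert means["T2D"]["hom"] < means["T2D"]["ref"]

    def test_null_effect_interaction_calibration(self):
        """With no genotype effect the interaction p is approximately uniform."""
        # note: the genotype must be null on T2D too, not just on BMI --
        # stratum-specific prevalence ORs make genotype and BMI dependent
        # within T2D strata (conditioning on a common effect)
        from obgrs.simulate import null_effect_config
        ps = []
        cfg = null_effect_config(n_subjects=1500)
        for seed in range(40):
            cohort = simulate_cohort(cfg, seed=1000 + seed)
            res = obgrs.fit_linear_trait(cohort, "rs7903146", trait="bmi", model="Model1")
            ps.append(res["p_interaction"])
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestInteractionTest:
    def test_detects_generated_stratum_contrast(self):
        cohort = simulate_cohort(SimulationConfig(bmi_genotype_effect_t2d=0.0), seed=31)
        p = interaction_test(cohort, "rs7903146", "obesity", "t2d_prevalent", "Model1")
        assert p < 0.05
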