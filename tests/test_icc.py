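"""ICC estimators: hand-computed cases, estimator contrasts, oracles."""

import numpy as np
import pandas as pd
import pytest

import cagecorr as cc
from cagecorr.icc import VarianceComponents

from conftest import toy_cohort


# ---------------------------------------------------------------------------
# ANOVA moment estimator


def test_anova_perfect_agreement_gives_one():
    df = toy_cohort([(1.0, 1.0), (-1.0, -1.0)])
    assert cc.anova_icc(df).estimate == pytest.approx(1.0)


def test_anova_perfect_dispersion_gives_minus_one():
    # cages (1,-1) and (2,-2): cage means 0, SSW=10 -> MSB=0, MSW=5,
    # k0=2 -> ICC = (0-5)/(0+5) = -1
    df = toy_cohort([(1.0, -1.0), (2.0, -2.0)])
    assert cc.anova_icc(df).estimate == pytest.approx(-1.0)


def test_anova_recovery_large_sample():
    st = cc.make_cage_structure(2000, 4, n_arms=1, seed=201)
    df = cc.sample_exchangeable_outcomes(st, cc.GeneratorConfig(icc=0.05,
                                                                seed=201))
    se = np.sqrt(2 * 0.95**2 * 1.15**2 / (4 * 3 * 1999))
    assert abs(cc.anova_icc(df).estimate - 0.05) < 3 * se


def test_anova_error_cases():
    with pytest.raises(ValueError, match="singleton"):
        cc.anova_icc(toy_cohort([(1.0,), (2.0,), (3.0,)]))
    with pytest.raises(ValueError, match="2 clusters"):
        cc.anova_icc(toy_cohort([(1.0, 2.0)]))


def test_anova_residualizes_covariates():
    df = toy_cohort([(10.0, 11.0), (10.5, 11.5)], arm=["a", "b"])
    # arm explains the cage separation entirely; residual ICC is the
    # within-cage pattern only
    est_adj = cc.anova_icc(df, residualize_on=("arm",)).estimate
    est_raw = cc.anova_icc(df).estimate
    assert est_adj < est_raw


# ---------------------------------------------------------------------------
# REML random intercept + LMM ICC


def test_lmm_icc_arithmetic():
    def vc(b, e):
        return VarianceComponents(sigma2_between=b, sigma2_within=e,
                                  fixed_effects=pd.Series(dtype=float),
                                  reml_loglik=0.0)
    assert cc.lmm_icc(vc(1.0, 19.0)).estimate == pytest.approx(0.05)
    assert cc.lmm_icc(vc(0.0, 5.0)).estimate == 0.0
    assert cc.lmm_icc(vc(2.0, 2.0)).estimate == pytest.approx(0.5)


def test_reml_boundary_on_independent_data(independent_cohort):
    assert cc.anova_icc(independent_cohort).estimate < 0
    vc = cc.reml_random_intercept(independent_cohort, fixed_terms=("arm",))
    # moment estimate below zero: REML must truncate exactly at sigma2_b=0
    assert vc.boundary
    assert vc.sigma2_between == 0.0
    assert cc.lmm_icc(vc).estimate == 0.0


def test_reml_matches_anova_on_balanced_positive_data(small_positive_cohort):
    """Classical equivalence: balanced one-way REML = ANOVA when interior."""
    df = small_positive_cohort
    a = cc.anova_icc(df, residualize_on=("arm",)).estimate
    assert a > 0
    vc = cc.reml_random_intercept(df, fixed_terms=("arm",))
    assert cc.lmm_icc(vc).estimate == pytest.approx(a, abs=2e-3)


def test_lmm_truncates_where_anova_goes_negative(negative_cohort):
    a = cc.anova_icc(negative_cohort).estimate
    vc = cc.reml_random_intercept(negative_cohort)
    assert a < 0
    assert vc.boundary
    assert cc.lmm_icc(vc).estimate == 0.0


def test_reml_matches_statsmodels_mixedlm(small_positive_cohort):
    smf = pytest.importorskip("statsmodels.formula.api")
    df = small_positive_cohort
    vc = cc.reml_random_intercept(df, fixed_terms=("arm",))
    fit = smf.mixedlm("lifespan_months ~ arm", df,
                      groups=df["cage_id"]).fit(reml=True)
    # tolerances reflect the two optimizers' stopping rules (this fit's
    # restricted log-likelihood is >= the statsmodels one)
    assert vc.sigma2_between == pytest.approx(float(fit.cov_re.iloc[0, 0]),
                                              abs=2e-3)
    assert vc.sigma2_within == pytest.approx(fit.scale, rel=1e-4)
    assert vc.reml_loglik >= fit.llf - 1e-6


def test_reml_rejects_singular_design(small_positive_cohort):
    df = small_positive_cohort.copy()
    df["arm2"] = df["arm"]
    with pytest.raises(ValueError, match="aliased"):
        cc.reml_random_intercept(df, fixed_terms=("arm", "arm2"))


# ---------------------------------------------------------------------------
# parametric bootstrap


def test_bootstrap_ci_boundary_pileup(independent_cohort):
    vc = cc.reml_random_intercept(independent_cohort)
    lo, hi = cc.parametric_bootstrap_ci(vc, B=200, seed=1)
    assert lo == 0.0          # truncation piles mass at zero
    assert hi >= lo


def test_bootstrap_requires_enough_draws(independent_cohort):
    vc = cc.reml_random_intercept(independent_cohort)
    with pytest.raises(ValueError):
        cc.parametric_bootstrap_ci(vc, B=50)


def test_bootstrap_degenerate_no_noise_zero_width():
    # outcome exactly reproducible from cage intercepts: every refit is
    # identical, so the percentile interval collapses
    rng = np.random.default_rng(3)
    df = toy_cohort([tuple(rng.normal(30, 3, 1).repeat(4)) for _ in range(50)])
    vc = cc.reml_random_intercept(df)
    lo, hi = cc.parametric_bootstrap_ci(vc, B=200, seed=2)
    assert hi - lo < 1e-3
    assert cc.lmm_icc(vc).estimate > 0.99


# ---------------------------------------------------------------------------
# exchangeable working correlation (GEE)


def brute_force_pairwise_alpha(df):
    """Independent oracle: explicit double loop over within-cage pairs."""
    y = df["lifespan_months"].to_numpy(dtype=float)
    e = y - y.mean()
    phi = (e @ e) / (len(e) - 1)
    tot, n_pairs = 0.0, 0
    for _, sub in df.groupby("cage_id"):
        idx = sub.index.to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                tot += e[df.index.get_loc(idx[a])] * e[df.index.get_loc(idx[b])]
                n_pairs += 1
    return tot / (phi * n_pairs)


def test_gee_equals_pairwise_moment_oracle():
    st = cc.make_cage_structure(50, 4, n_arms=1, seed=210)
    df = cc.sample_exchangeable_outcomes(st, cc.GeneratorConfig(icc=0.08,
                                                                seed=210))
    est = cc.gee_exchangeable(df, ci=None).estimate
    assert est == pytest.approx(brute_force_pairwise_alpha(df), abs=1e-6)


def test_gee_sees_negative_correlation(negative_cohort):
    g = cc.gee_exchangeable(negative_cohort, ci=None).estimate
    l = cc.lmm_icc(cc.reml_random_intercept(negative_cohort)).estimate
    assert g < -0.05
    assert l == 0.0


def test_gee_null_within_noise(independent_cohort):
    est = cc.gee_exchangeable(independent_cohort, fixed_terms=("arm",),
                              ci=None).estimate
    se = np.sqrt(2 / (4 * 3 * 399))
    assert abs(est) < 3 * se


def test_gee_close_to_statsmodels(small_positive_cohort):
    sm = pytest.importorskip("statsmodels.api")
    df = small_positive_cohort
    mine = cc.gee_exchangeable(df, fixed_terms=("arm",), ci=None).estimate
    ex = sm.cov_struct.Exchangeable()
    sm.GEE.from_formula("lifespan_months ~ arm", groups="cage_id", data=df,
                        family=sm.families.Gaussian(), cov_struct=ex).fit()
    # statsmodels subtracts the coefficient count from the pair total in
    # its moment denominator; with 200 cages that is a ~0.1% difference
    assert mine == pytest.approx(float(ex.dep_params), abs=2e-3)


def test_gee_warns_with_few_clusters():
    df = toy_cohort([tuple(np.random.default_rng(j).normal(30, 3, 4))
                     for j in range(8)])
    with pytest.warns(UserWarning, match="clusters"):
        cc.gee_exchangeable(df, ci=None)


def test_gee_ci_width_comparable_to_lmm(small_positive_cohort):
    """Matched data: LMM and GEE interval widths differ by < 0.1."""
    df = small_positive_cohort
    vc = cc.reml_random_intercept(df, fixed_terms=("arm",))
    lmm = cc.lmm_icc(vc, B=300, seed=3)
    gee = cc.gee_exchangeable(df, fixed_terms=("arm",), B=300, seed=3)
    w_l = lmm.ci_high - lmm.ci_low
    w_g = gee.ci_high - gee.ci_low
    assert abs(w_l - w_g) < 0.1
    for est in (lmm, gee):
        assert est.ci_low - 1e-9 <= est.estimate <= est.ci_high + 1e-9


def test_gee_sandwich_delta_option(small_positive_cohort):
    est = cc.gee_exchangeable(small_positive_cohort, fixed_terms=("arm",),
                              ci="sandwich_delta")
    assert est.ci_method == "sandwich_delta"
    assert est.ci_low < est.estimate < est.ci_high


# ---------------------------------------------------------------------------
# permutation test


def test_permutation_saturates_under_strong_clustering():
    st = cc.make_cage_structure(200, 4, n_arms=1, seed=220)
    df = cc.sample_exchangeable_outcomes(st, cc.GeneratorConfig(icc=0.3,
                                                                seed=220))
    res = cc.permutation_icc_test(df, n_perm=400, seed=220)
    assert res.p_value == pytest.approx(1.0 / 401.0)


def test_permutation_default_is_one_thousand():
    import inspect
    sig = inspect.signature(cc.permutation_icc_test)
    assert sig.parameters["n_perm"].default == 1000


def test_permutation_pvalue_identity():
    st = cc.make_cage_structure(50, 4, n_arms=1, seed=221)
    df = cc.sample_exchangeable_outcomes(st, cc.GeneratorConfig(icc=0.0,
                                                                seed=221))
    res = cc.permutation_icc_test(df, n_perm=399, seed=221)
    exceed = int(np.sum(res.null_draws >= res.observed_icc))
    assert res.p_value == pytest.approx((1 + exceed) / 400)
    assert 0 < res.p_value <= 1


def test_permutation_respects_strata():
    # two arms with very different means: permuting across arms would
    # fabricate clustering, permuting within arms must not
    st = cc.make_cage_structure(60, 4, n_arms=2, seed=222)
    df = cc.sample_exchangeable_outcomes(
        st, cc.GeneratorConfig(icc=0.0, effect=15.0, seed=222))
    res = cc.permutation_icc_test(df, n_perm=300, seed=222,
                                  strata=("arm",))
    assert res.p_value > 0.01


def test_permutation_gee_estimator_runs(negative_cohort):
    res = cc.permutation_icc_test(negative_cohort.head(400),
                                  estimator="gee_exchangeable",
                                  n_perm=300, seed=5, alternative="two-sided")
    assert 0 < res.p_value <= 1


def test_permutation_needs_two_cages_per_stratum():
    df = toy_cohort([(1.0, 2.0)], arm=["a"])
    df2 = toy_cohort([(3.0, 4.0)], arm=["b"])
    both = pd.concat([df, df2.assign(cage_id="C9")], ignore_index=True)
    with pytest.raises(ValueError, match="2 cages"):
        cc.permutation_icc_test(both, n_perm=300, strata=("arm",))


# ---------------------------------------------------------------------------
# two-level model


def _long_data(icc_cage, icc_animal, n_cages_per_arm=50, k=4, ages=(1, 2, 3),
               seed=230):
    st = cc.make_cage_structure(n_cages_per_arm, k, n_arms=2, seed=seed)
    return cc.sample_longitudinal(st, icc_cage=icc_cage,
                                  icc_animal=icc_animal, ages=list(ages),
                                  diet_effects={"treatment": 1.0},
                                  residual_sd=1.0, age_slope=0.1, seed=seed)


def test_two_level_cage_boundary_when_share_zero():
    # this seed's empirical cage share is negative, so the constrained
    # fit must land exactly on the sigma2_cage = 0 boundary
    df = _long_data(0.0, 0.3, seed=235)
    vc = cc.two_level_reml(df)
    assert vc.sigma2_between == 0.0
    assert vc.boundary
    assert cc.proportion_of_variance_icc(vc).estimate == 0.0


def test_two_level_matches_statsmodels():
    smf = pytest.importorskip("statsmodels.formula.api")
    df = _long_data(0.1, 0.3, n_cages_per_arm=30, seed=232)
    vc = cc.two_level_reml(df)
    md = smf.mixedlm("value ~ diet + age", df, groups=df["cage_id"],
                     re_formula="1",
                     vc_formula={"animal": "0 + C(animal_id)"})
    fit = md.fit(reml=True)
    assert vc.sigma2_between == pytest.approx(float(fit.cov_re.iloc[0, 0]),
                                              abs=2e-3)
    assert vc.sigma2_animal == pytest.approx(float(fit.vcomp[0]), abs=2e-3)
    assert vc.sigma2_within == pytest.approx(fit.scale, rel=1e-3)


def test_two_level_rejects_non_nested_ids():
    df = _long_data(0.05, 0.3, seed=233)
    df.loc[df.index[-1], "animal_id"] = df["animal_id"].iloc[0]
    with pytest.raises(ValueError, match="non-nested"):
        cc.two_level_reml(df)


def test_two_level_rejects_single_observation_per_animal():
    df = _long_data(0.05, 0.3, ages=(12,), seed=234)
    with pytest.raises(ValueError, match="single-level"):
        cc.two_level_reml(df)


def test_proportion_of_variance_arithmetic():
    def vc(c, a, e):
        return VarianceComponents(sigma2_between=c, sigma2_within=e,
                                  sigma2_animal=a,
                                  fixed_effects=pd.Series(dtype=float),
                                  reml_loglik=0.0, n_clusters=10, n_obs=100)
    assert cc.proportion_of_variance_icc(vc(1, 9, 10)).estimate == \
        pytest.approx(0.05)
    assert cc.proportion_of_variance_icc(vc(0, 3, 7)).estimate == 0.0
    single = VarianceComponents(sigma2_between=1.0, sigma2_within=1.0,
                                fixed_effects=pd.Series(dtype=float),
                                reml_loglik=0.0)
    with pytest.raises(ValueError):
        cc.proportion_of_variance_icc(single)


# ---------------------------------------------------------------------------
# joint fixed-effect tests


def test_joint_test_f_equals_squared_t():
    st = cc.make_cage_structure(40, 4, n_arms=2, seed=240)
    df = cc.sample_exchangeable_outcomes(st, cc.GeneratorConfig(icc=0.05,
                                                                seed=240))
    for with_cage in (False, True):
        F, (q, dden), p = cc.joint_fixed_effect_test(
            df, ("arm",), "arm", with_cage_effect=with_cage)
        assert q == 1
        assert F >= 0
        assert 0 <= p <= 1
    # OLS route: F(1, N-2) of the arm term is the squared two-sample t
    F, (q, dden), p = cc.joint_fixed_effect_test(df, ("arm",), "arm", False)
    y = df["lifespan_months"]
    import scipy.stats as st_
    t, p_t = st_.ttest_ind(y[df["arm"] == "treatment"],
                           y[df["arm"] == "control"])
    assert F == pytest.approx(t**2, rel=1e-9)
    assert p == pytest.approx(p_t, rel=1e-9)


def test_ignoring_cages_understates_pvalues_under_positive_icc():
    """Paired replicates: OLS p below mixed p on average when ICC > 0."""
    diffs = []
    for r in range(60):
        st = cc.make_cage_structure(25, 4, n_arms=2, seed=250 + r)
        df = cc.sample_exchangeable_outcomes(
            st, cc.GeneratorConfig(icc=0.1, seed=250 + r))
        _, _, p_ols = cc.joint_fixed_effect_test(df, ("arm",), "arm", False)
        _, _, p_mix = cc.joint_fixed_effect_test(df, ("arm",), "arm", True)
        diffs.append(p_ols - p_mix)
    assert np.mean(diffs) < 0
    # sign test: most replicates have the OLS p smaller
    assert np.mean(np.array(diffs) < 0) > 0.6


def test_joint_test_rejects_unknown_term(small_positive_cohort):
    with pytest.raises(ValueError):
        cc.joint_fixed_effect_test(small_positive_cohort, ("arm",), "sex",
                                   with_cage_effect=False)
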