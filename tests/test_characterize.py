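"""Tests of the downstream statistics: covariate-adjusted ANOVA, chi-square,
BH-FDR, partial Spearman correlations, and survival analysis."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols

import amysustain as am

from conftest import no_covariate_config


def _null_frame(rng, n=150, shift=0.0):
    g = rng.integers(0, 2, n)
    return pd.DataFrame({
        "y": rng.normal(size=n) + shift * g,
        "g": g,
        "age": rng.normal(72, 7, n),
        "gender": rng.integers(0, 2, n),
        "education": rng.normal(16, 2.6, n),
    })


def test_compare_continuous_matches_statsmodels_anova():
    """Dual route: the nested-model F statistic equals statsmodels' type-II
    ANOVA on the same (centred and scaled) design."""
    rng = np.random.default_rng(0)
    df = _null_frame(rng, n=120, shift=0.6)
    rep = am.compare_continuous(df, "y", "g")
    scaled = df.copy()
    for col in ("y", "age", "education"):
        scaled[col] = (scaled[col] - scaled[col].mean()) / scaled[col].std(
            ddof=1)
    scaled["gender"] = scaled["gender"] - scaled["gender"].mean()
    fit = ols("y ~ C(g) + age + gender + education", data=scaled).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    assert rep.statistic == pytest.approx(table.loc["C(g)", "F"], rel=1e-8)
    assert rep.p == pytest.approx(table.loc["C(g)", "PR(>F)"], rel=1e-8)


def test_compare_continuous_location_invariance_and_power():
    rng = np.random.default_rng(1)
    df = _null_frame(rng, n=200, shift=1.0)
    rep = am.compare_continuous(df, "y", "g")
    shifted = df.copy()
    shifted["y"] = shifted["y"] + 57.0
    rep2 = am.compare_continuous(shifted, "y", "g")
    assert rep.statistic == pytest.approx(rep2.statistic, rel=1e-9)
    assert rep.p < 0.001  # a 1 SD shift at n=100/group is detected


def test_compare_continuous_rejects_single_group():
    rng = np.random.default_rng(2)
    df = _null_frame(rng)
    df["g"] = 0
    with pytest.raises(ValueError):
        am.compare_continuous(df, "y", "g")


def test_compare_categorical_proportional_rows_give_zero():
    rep = am.compare_categorical([[10, 20, 30], [20, 40, 60]])
    assert rep.statistic == pytest.approx(0.0, abs=1e-12)
    assert rep.dof == (2,)
    assert rep.p == pytest.approx(1.0)


def test_fdr_adjust_worked_example():
    adj = am.fdr_adjust([0.01, 0.02, 0.03])
    assert np.allclose(adj, [0.03, 0.03, 0.03])
    assert am.fdr_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(am.fdr_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        am.fdr_adjust([0.5, 1.5])


def test_fdr_adjust_monotone_and_above_raw():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=30)
    adj = am.fdr_adjust(p)
    assert np.all(adj >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_stage_profile_correlation_monotone_and_signed():
    rng = np.random.default_rng(4)
    n = 300
    stages = rng.integers(1, 11, n)
    covs = pd.DataFrame({"age": rng.normal(72, 7, n),
                         "gender": rng.integers(0, 2, n),
                         "education": rng.normal(16, 2.6, n)})
    rho, p = am.stage_profile_correlation(stages, stages * 2.0 + 1.0, covs)
    assert rho == pytest.approx(1.0, abs=1e-6)
    # a negatively stage-linked profile (CSF amyloid style) has rho < 0
    prof = 1400 - 60 * stages + rng.normal(0, 100, n)
    rho_neg, p_neg = am.stage_profile_correlation(stages, prof, covs)
    assert rho_neg < -0.5 and p_neg < 1e-6


def test_cox_invariances():
    cfg = no_covariate_config(seed=30, n_subjects=500)
    cohort, truth = am.generate_cohort(cfg)
    t = cohort.merge(truth, on="subject_id")
    covs = t[["age", "gender", "education"]]
    pred = (t["true_subtype"] == 2).astype(float)
    fit = am.cox_conversion(t["followup_years"], t["converted"], pred, covs)
    assert fit.ci_low <= fit.hazard_ratio <= fit.ci_high
    # subject order invariance
    perm = np.random.default_rng(0).permutation(len(t))
    fit_p = am.cox_conversion(t["followup_years"].iloc[perm],
                              t["converted"].iloc[perm], pred.iloc[perm],
                              covs.iloc[perm])
    assert fit.hazard_ratio == pytest.approx(fit_p.hazard_ratio, rel=1e-6)
    # rescaling a centred covariate leaves the predictor's HR unchanged
    covs2 = covs.copy()
    covs2["age"] = (covs2["age"] - covs2["age"].mean()) * 10.0
    fit_s = am.cox_conversion(t["followup_years"], t["converted"], pred,
                              covs2)
    assert fit.hazard_ratio == pytest.approx(fit_s.hazard_ratio, rel=1e-5)


def test_cox_rejects_no_events():
    covs = pd.DataFrame({"age": [70, 71, 72, 73.0],
                         "gender": [0, 1, 0, 1.0],
                         "education": [12, 14, 16, 18.0]})
    with pytest.raises(ValueError):
        am.cox_conversion([1, 2, 3, 4.0], [0, 0, 0, 0], [0, 1, 0, 1.0], covs)


def test_km_product_limit_hand_calculation():
    # times 1,2,3 with events 1,0,1: S(1) = 2/3, censor at 2, S(3) = 0
    curves = am.survival_curves([1.0, 2.0, 3.0], [1, 0, 1],
                                ["all", "all", "all"])
    km = curves["km"].set_index("time")["survival"]
    assert km.loc[1.0] == pytest.approx(2 / 3)
    assert km.loc[3.0] == pytest.approx(0.0)


def test_survival_curves_trivial_cases():
    ones = am.survival_curves([2.0, 3.0, 4.0], [0, 0, 0], ["g", "g", "g"])
    assert (ones["km"]["survival"] == 1.0).all()
    drop = am.survival_curves([1.0, 1.0, 1.0], [1, 1, 1], ["g", "g", "g"])
    km = drop["km"].set_index("time")["survival"]
    assert km.loc[1.0] == pytest.approx(0.0)


def test_characterize_battery_matches_generator_directions():
    """Full Table-2-shaped battery on a synthetic cohort: the fitted signs
    match the configured subtype contrasts."""
    cfg = no_covariate_config(seed=31, n_subjects=1200)
    cohort, truth = am.generate_cohort(cfg)
    # oracle assignment: truth labels, no exclusions, to isolate the stats
    assign = pd.DataFrame({
        "subject_id": cohort["subject_id"],
        "ml_subtype": truth["true_subtype"],
        "ml_stage": truth["true_stage"],
        "excluded": False,
    })
    report = am.characterize_subtypes(cohort, assign)
    report = report.set_index("profile")
    assert set(report.index) >= {"memory", "csf_abeta", "csf_ttau",
                                 "apoe_e4"}
    assert (report["p_fdr"] >= report["p"] - 1e-15).all()
    # configured directions: subtype 2 has lower amyloid, higher tau,
    # worse memory, more APOE e4 carriage
    mem = report.loc["memory", "groups"]
    assert mem["2"][0] < mem["1"][0]
    abeta = report.loc["csf_abeta", "groups"]
    assert abeta["2"][0] < abeta["1"][0]
    ttau = report.loc["csf_ttau", "groups"]
    assert ttau["2"][0] > ttau["1"][0]
    assert report.loc["memory", "p_fdr"] < 0.01
    assert report.loc["apoe_e4", "p_fdr"] < 0.01
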