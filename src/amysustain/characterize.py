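"""Downstream characterisation of subtypes and stages: covariate-adjusted
group comparisons with FDR control, stage-profile rank correlations, and
conversion-risk survival models censored at a fixed horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from lifelines import CoxPHFitter, KaplanMeierFitter

__all__ = ["StatsReport", "SurvivalFit", "compare_continuous",
           "compare_categorical", "fdr_adjust", "stage_profile_correlation",
           "cox_conversion", "survival_curves", "characterize_subtypes"]

DEFAULT_COVARIATES = ("age", "gender", "education")

#: Table-2-shaped battery: clinical composites, CSF biomarkers, APOE.
PROFILE_BATTERY = ("mmse", "memory", "executive", "language", "visuospatial",
                   "csf_abeta", "csf_ttau", "csf_ptau")


@dataclass
class StatsReport:
    """One test of the characterisation battery."""

    name: str
    test: str                  # "anova" | "chi-square"
    statistic: float
    dof: tuple
    p: float
    p_fdr: float | None = None
    group_summaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class SurvivalFit:
    """Cox proportional-hazards result for one predictor."""

    predictor: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    coefficients: dict
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
            raise ValueError("hazard ratio outside its confidence interval")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")


def _scale(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def compare_continuous(df: pd.DataFrame, profile: str, group: str,
                       covariates=DEFAULT_COVARIATES) -> StatsReport:
    """Covariate-adjusted group comparison of a continuous profile.

    Fits the linear model ``profile ~ group + age + gender + education``
    (continuous variables centred and scaled) and F-tests the group factor
    by comparing against the covariate-only model.
    """
    data = df[[profile, group, *covariates]].dropna()
    if data[group].nunique() < 2:
        raise ValueError("need at least two groups")
    y = _scale(data[profile].to_numpy(dtype=float))
    n = y.size
    cov_cols = []
    for c in covariates:
        x = data[c].to_numpy(dtype=float)
        cov_cols.append(_scale(x) if np.unique(x).size > 2 else x - x.mean())
    X_red = np.column_stack([np.ones(n), *cov_cols])
    dummies = pd.get_dummies(data[group], drop_first=True).to_numpy(float)
    X_full = np.column_stack([X_red, dummies])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design")

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_r, rss_f = rss(X_red), rss(X_full)
    q = dummies.shape[1]
    df_denom = n - X_full.shape[1]
    F = ((rss_r - rss_f) / q) / (rss_f / df_denom)
    p = float(stats.f.sf(F, q, df_denom))
    summaries = {
        str(g): (float(sub[profile].mean()), float(sub[profile].std(ddof=1)))
        for g, sub in data.groupby(group)
    }
    return StatsReport(name=profile, test="anova", statistic=float(F),
                       dof=(q, df_denom), p=p, group_summaries=summaries)


def compare_categorical(counts) -> StatsReport:
    """Pearson chi-square on an RxC contingency table, no continuity
    correction; dof = (R-1)(C-1)."""
    table = np.asarray(counts, dtype=float)
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq <= 0).any():
        raise ValueError("expected cell count of zero")
    summaries = {f"row{i}": tuple(int(v) for v in row)
                 for i, row in enumerate(table)}
    return StatsReport(name="categorical", test="chi-square",
                       statistic=float(res.statistic), dof=(int(res.dof),),
                       p=float(res.pvalue), group_summaries=summaries)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def stage_profile_correlation(stages, profile, covariates: pd.DataFrame
                              ) -> tuple[float, float]:
    """Spearman correlation between stage and a profile after residualising
    both on the covariates (partial rank correlation)."""
    stages = np.asarray(stages, dtype=float)
    profile = np.asarray(profile, dtype=float)
    C = np.column_stack([np.ones(stages.size),
                         covariates.to_numpy(dtype=float)])
    keep = np.isfinite(stages) & np.isfinite(profile) \
        & np.isfinite(C).all(axis=1)
    stages, profile, C = stages[keep], profile[keep], C[keep]

    def resid(v):
        beta, *_ = np.linalg.lstsq(C, v, rcond=None)
        return v - C @ beta

    rho, p = stats.spearmanr(resid(stages), resid(profile))
    return float(rho), float(p)


def _truncate(time, event, horizon):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time < 0).any():
        raise ValueError("negative follow-up time")
    over = time > horizon
    time = np.minimum(time, horizon)
    event = np.where(over, 0, event)
    return time, event


def cox_conversion(time, event, predictor, covariates: pd.DataFrame,
                   horizon: float = 6.0,
                   predictor_name: str = "predictor") -> SurvivalFit:
    """Cox proportional-hazards fit of conversion risk on one predictor,
    adjusted for age/gender/education; follow-up truncated at the horizon,
    Efron handling of ties; Wald CI and p for the predictor."""
    time, event = _truncate(time, event, horizon)
    if event.sum() == 0:
        raise ValueError("no conversion events within the horizon")
    frame = covariates.reset_index(drop=True).copy()
    frame[predictor_name] = np.asarray(predictor, dtype=float)
    frame["time"] = time
    frame["event"] = event
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time", event_col="event")
    s = cph.summary.loc[predictor_name]
    return SurvivalFit(
        predictor=predictor_name,
        hazard_ratio=float(np.exp(s["coef"])),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p=float(s["p"]),
        coefficients={k: float(v) for k, v in cph.params_.items()},
        n=int(len(frame)),
        n_events=int(event.sum()),
    )


def survival_curves(time, event, groups, covariates: pd.DataFrame | None = None,
                    horizon: float = 6.0) -> dict:
    """Kaplan-Meier curves per group plus, when covariates are given,
    Cox-adjusted survival curves evaluated at the covariate means.
    Returned as tidy step-function tables."""
    time, event = _truncate(time, event, horizon)
    groups = np.asarray(groups)
    km_rows = []
    for g in pd.unique(groups):
        sel = groups == g
        km = KaplanMeierFitter()
        km.fit(time[sel], event[sel])
        surv = km.survival_function_
        at_risk = km.event_table["at_risk"]
        for t, s in surv.itertuples():
            km_rows.append({"group": g, "time": float(t),
                            "survival": float(s),
                            "at_risk": int(at_risk.get(t, 0))})
    out = {"km": pd.DataFrame(km_rows)}

    if covariates is not None and event.sum() > 0:
        frame = covariates.reset_index(drop=True).copy()
        gdum = pd.get_dummies(pd.Series(groups, name="group"),
                              prefix="g", drop_first=True).astype(float)
        frame = pd.concat([frame, gdum.reset_index(drop=True)], axis=1)
        frame["time"] = time
        frame["event"] = event
        cph = CoxPHFitter()
        cph.fit(frame, duration_col="time", event_col="event")
        cov_means = covariates.mean()
        rows = []
        for g in pd.unique(groups):
            x = pd.DataFrame([cov_means])
            for col in gdum.columns:
                x[col] = 1.0 if col == f"g_{g}" else 0.0
            sf = cph.predict_survival_function(x)
            for t, s in sf.itertuples():
                rows.append({"group": g, "time": float(t),
                             "survival": float(s[0] if hasattr(s, "__len__")
                                               else s)})
        out["cox_adjusted"] = pd.DataFrame(rows)
    return out


def characterize_subtypes(cohort: pd.DataFrame, assignment_table: pd.DataFrame,
                          covariates=DEFAULT_COVARIATES,
                          profiles=PROFILE_BATTERY) -> pd.DataFrame:
    """Run the full subtype-characterisation battery on non-excluded
    subjects: covariate-adjusted ANOVA for each continuous profile plus the
    APOE chi-square, with BH-FDR over the whole family.  Returns a tidy
    report table."""
    merged = cohort.merge(assignment_table, on="subject_id")
    merged = merged[~merged["excluded"]]
    reports: list[StatsReport] = []
    for prof in profiles:
        if prof not in merged.columns:
            continue
        reports.append(compare_continuous(merged, prof, "ml_subtype",
                                          covariates))
    if "apoe_e4" in merged.columns:
        tab = pd.crosstab(merged["ml_subtype"], merged["apoe_e4"])
        rep = compare_categorical(tab.to_numpy())
        rep.name = "apoe_e4"
        reports.append(rep)
    adj = fdr_adjust([r.p for r in reports])
    for r, a in zip(reports, adj):
        r.p_fdr = float(a)
    return pd.DataFrame([{
        "profile": r.name, "test": r.test, "statistic": r.statistic,
        "dof": "x".join(str(d) for d in r.dof), "p": r.p, "p_fdr": r.p_fdr,
        "groups": r.group_summaries,
    } for r in reports])
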