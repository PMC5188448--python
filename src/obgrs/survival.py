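"""Incidence analysis: person-years, crude rates, Cox models, Kaplan-Meier.

All operations act on the baseline-diabetes-free subset of a cohort.  Time
zero is study entry and the time variable is length of follow-up; deaths and
end of study are treated as right censoring.  Ties are handled with Efron's
approximation (the lifelines default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .association import build_design
from .cohort import Cohort, SNPAnnotation, code_genotype

logger = logging.getLogger(__name__)

#: Adjustment sets for the two multivariable Cox models.  The basic model
#: includes the trial's intervention arm; the full model adds lifestyle and
#: clinical covariates.
COX_MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "Model1": ("sex", "age", "center", "arm"),
    "Model2": (
        "sex", "age", "center", "arm", "energy_kcal", "meddiet_score",
        "alcohol_g", "smoker", "physical_activity", "dyslipidemia", "hypertension",
    ),
}


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalResult:
    """One genotype-within-stratum cell of the incidence table."""

    cell_label: str
    stratum: str
    model: str
    n_cases: int
    n_noncases: int
    person_years: float
    incidence_rate: float
    hr: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    global_p: float | None = None
    p_interaction: float | None = None


# ---------------------------------------------------------------------------
# Person-time and crude rates
# ---------------------------------------------------------------------------

def person_time(durations: Sequence[float] | pd.Series) -> float:
    """Total person-years contributed by a group of subjects."""
    arr = np.asarray(durations, dtype=float)
    arr = arr[~np.isnan(arr)]
    if (arr < 0).any():
        raise SurvivalError("negative follow-up time encountered")
    return float(arr.sum())


def incidence_rate(n_cases: int, person_years: float) -> float:
    """Crude incidence rate per 1000 person-years."""
    if person_years <= 0:
        raise SurvivalError("incidence_rate: person-years must be positive")
    return 1000.0 * n_cases / person_years


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------

def fit_cox(df: pd.DataFrame, duration_col: str, event_col: str,
            covariate_cols: Sequence[str]) -> CoxPHFitter:
    """Fit a Cox proportional-hazards model (Efron ties, Wald CIs).

    ``covariate_cols`` must already be numeric; use
    :func:`obgrs.association.build_design` for categorical expansion.
    """
    if df[event_col].sum() == 0:
        raise SurvivalError("fit_cox: no events in the data")
    sub = df[[duration_col, event_col, *covariate_cols]]
    X = sub[list(covariate_cols)].to_numpy(dtype=float)
    if X.shape[1] and np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise SurvivalError("fit_cox: design matrix is rank deficient")
    cph = CoxPHFitter()
    cph.fit(sub, duration_col=duration_col, event_col=event_col)
    return cph


def cox_lrt_interaction(df: pd.DataFrame, duration_col: str, event_col: str,
                        exposure_col: str, modifier_col: str,
                        covariate_cols: Sequence[str] = ()) -> float:
    """1-df likelihood-ratio p-value for an exposure-by-modifier product term."""
    work = df.copy()
    work["_inter"] = work[exposure_col] * work[modifier_col]
    base_cols = [exposure_col, modifier_col, *covariate_cols]
    reduced = fit_cox(work, duration_col, event_col, base_cols)
    full = fit_cox(work, duration_col, event_col, base_cols + ["_inter"])
    lr = 2.0 * (full.log_likelihood_ - reduced.log_likelihood_)
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def _genotype_design(cohort_df: pd.DataFrame, calls: pd.Series,
                     ann: SNPAnnotation, coding: str) -> tuple[pd.DataFrame, list[str]]:
    """Numeric genotype columns for the requested genetic model."""
    if coding == "codominant":
        pairs = calls.map(lambda c: code_genotype(c, ann, "codominant"))
        out = pd.DataFrame(
            {"g_het": pairs.map(lambda t: t[0]), "g_hom": pairs.map(lambda t: t[1])},
            index=cohort_df.index,
        )
        return out, ["g_het", "g_hom"]
    code = calls.map(lambda c: code_genotype(c, ann, coding)).astype(float)
    return pd.DataFrame({"g": code}, index=cohort_df.index), ["g"]


def cox_stratified_and_interaction(
    cohort: Cohort,
    snp_id: str,
    model: str = "Model1",
    coding: str = "codominant",
) -> tuple[list[SurvivalResult], float]:
    """Obesity-stratified genotype hazard ratios plus the interaction p-value.

    Returns per-stratum cells (counts, person-years, crude rate, HR vs the
    homozygous non-risk reference, stratum-level global p) and the
    likelihood-ratio p for the genotype-by-obesity product term(s) fitted on
    the pooled incidence subset.
    """
    ann = cohort.annotations[snp_id]
    inc = cohort.incidence_subset().data
    calls = inc["snp:" + snp_id]
    gdf, gcols = _genotype_design(inc, calls, ann, coding)
    covs = COX_MODEL_COVARIATES[model] if isinstance(model, str) else tuple(model)
    model = model if isinstance(model, str) else "custom"
    design = build_design(inc, covs, add_intercept=False)
    work = pd.concat(
        [inc[["followup_years", "t2d_incident", "obesity"]], gdf, design], axis=1
    ).dropna()
    work["t2d_incident"] = work["t2d_incident"].astype(int)

    results: list[SurvivalResult] = []
    global_ps: dict[str, float] = {}
    for stratum, mask in (("non-obese", ~work["obesity"]), ("obese", work["obesity"])):
        sub = work[mask].drop(columns=["obesity"])
        cols = gcols + [c for c in design.columns]
        cols = [c for c in cols if sub[c].nunique() > 1]  # drop constants within stratum
        try:
            fit = fit_cox(sub, "followup_years", "t2d_incident", cols)
            red = fit_cox(
                sub, "followup_years", "t2d_incident",
                [c for c in cols if c not in gcols],
            )
            lr = 2.0 * (fit.log_likelihood_ - red.log_likelihood_)
            global_ps[stratum] = float(
                stats.chi2.sf(max(lr, 0.0), df=len([c for c in gcols if c in cols]))
            )
        except SurvivalError:
            fit = None
            global_ps[stratum] = float("nan")
        results.extend(
            _stratum_cells(sub, gcols, coding, ann, stratum, model, fit, global_ps[stratum])
        )

    # pooled interaction test: genotype, obesity, covariates vs + products
    pool = work.copy()
    pool["obesity"] = pool["obesity"].astype(float)
    inter_cols = []
    for g in gcols:
        pool[f"{g}_x_ob"] = pool[g] * pool["obesity"]
        inter_cols.append(f"{g}_x_ob")
    base_cols = gcols + ["obesity"] + [c for c in design.columns if pool[c].nunique() > 1]
    reduced = fit_cox(pool, "followup_years", "t2d_incident", base_cols)
    full = fit_cox(pool, "followup_years", "t2d_incident", base_cols + inter_cols)
    lr = 2.0 * (full.log_likelihood_ - reduced.log_likelihood_)
    p_interaction = float(stats.chi2.sf(max(lr, 0.0), df=len(inter_cols)))
    for r in results:
        r.p_interaction = p_interaction
    return results, p_interaction


def _stratum_cells(sub: pd.DataFrame, gcols: list[str], coding: str,
                   ann: SNPAnnotation, stratum: str, model: str,
                   fit: CoxPHFitter | None, global_p: float) -> list[SurvivalResult]:
    """Assemble count/rate/HR rows for the genotype cells of one stratum."""
    ref_label = 2 * ann.non_risk_allele
    het_label = "".join(sorted(ann.non_risk_allele + ann.risk_allele))
    hom_label = 2 * ann.risk_allele
    if coding == "codominant":
        cells = [(ref_label, sub[gcols[0]].eq(0) & sub[gcols[1]].eq(0), None),
                 (het_label, sub[gcols[0]].eq(1), "g_het"),
                 (hom_label, sub[gcols[1]].eq(1), "g_hom")]
    elif coding == "recessive":
        cells = [(f"{het_label}/{ref_label} carriers", sub["g"].eq(0), None),
                 (hom_label, sub["g"].eq(1), "g")]
    else:  # additive: cells by dosage, single HR per allele
        cells = [(ref_label, sub["g"].eq(0), None),
                 (het_label, sub["g"].eq(1), "g"),
                 (hom_label, sub["g"].eq(2), None)]
    out = []
    for label, mask, coef in cells:
        cases = int(sub.loc[mask, "t2d_incident"].sum())
        py = person_time(sub.loc[mask, "followup_years"])
        rate = incidence_rate(cases, py) if py > 0 else float("nan")
        if coef is not None and fit is not None and coef in fit.params_.index:
            hr = float(np.exp(fit.params_[coef]))
            lo, hi = np.exp(fit.confidence_intervals_.loc[coef])
            p = float(fit.summary.loc[coef, "p"])
        elif coef is None:
            hr, lo, hi, p = (1.0, None, None, None) if label.endswith("carriers") or label == ref_label else (None, None, None, None)
        else:
            hr = lo = hi = p = None
        out.append(
            SurvivalResult(
                cell_label=label, stratum=stratum, model=model,
                n_cases=cases, n_noncases=int(mask.sum() - cases),
                person_years=py, incidence_rate=rate,
                hr=hr, ci_low=None if lo is None else float(lo),
                ci_high=None if hi is None else float(hi),
                p_value=p, global_p=global_p,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_one_minus_survival(
    durations: Sequence[float],
    events: Sequence[int],
    groups: Sequence | None = None,
) -> dict[str, pd.DataFrame]:
    """Product-limit 1 - S(t) per group, as (time, cum_incidence, at_risk) tables."""
    dur = np.asarray(durations, dtype=float)
    ev = np.asarray(events, dtype=int)
    grp = np.asarray(groups) if groups is not None else np.array(["all"] * len(dur))
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(grp):
        mask = grp == g
        if mask.sum() == 0:
            out[str(g)] = pd.DataFrame(columns=["time", "cum_incidence", "at_risk"])
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(dur[mask], ev[mask])
        tbl = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        out[str(g)] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "cum_incidence": 1.0 - surv.to_numpy(),
                "at_risk": tbl["at_risk"].to_numpy(),
            }
        )
    return out
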