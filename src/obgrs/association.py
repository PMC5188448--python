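"""Logistic and linear association engine for baseline analyses.

Implements the stratified odds-ratio workflow for prevalent type-2 diabetes
(and for obesity as outcome), the genotype-by-modifier interaction tests,
and covariate-adjusted genotype means for continuous adiposity traits.

Two adjustment sets are used throughout: a basic model (sex, age, field
center) and a fully adjusted model that adds total energy intake, adherence
to the Mediterranean diet, alcohol, smoking, physical activity,
dyslipidemia, and hypertension.  Field center enters as a categorical
indicator set.  Interaction p-values come from likelihood-ratio tests
(2 df for the codominant coding, 1 df otherwise); each stratum also carries
a global polymorphism p from the 2-df likelihood ratio on both genotype
contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, SNPAnnotation, code_genotype

logger = logging.getLogger(__name__)

MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "Model1": ("sex", "age", "center"),
    "Model2": (
        "sex", "age", "center", "energy_kcal", "meddiet_score", "alcohol_g",
        "smoker", "physical_activity", "dyslipidemia", "hypertension",
    ),
}

_CATEGORICAL = {"sex", "center", "arm"}


def _resolve_covariates(model) -> tuple[str, ...]:
    """Accept a named adjustment set ("Model1"/"Model2") or an explicit tuple."""
    return MODEL_COVARIATES[model] if isinstance(model, str) else tuple(model)


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist."""


class DesignError(ValueError):
    """Structural problem with the design matrix (rank deficiency etc.)."""


@dataclass
class AssociationResult:
    """One genotype (or score) contrast within one stratum and model."""

    contrast: str
    estimate: float          # log-odds (logistic) or beta (linear)
    or_value: float | None   # exp(estimate) for logistic results
    ci_low: float
    ci_high: float
    p_value: float
    stratum: str
    model: str
    n: int
    global_p: float | None = None
    p_interaction: float | None = None


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_design(df: pd.DataFrame, covariates: Sequence[str],
                 add_intercept: bool = True) -> pd.DataFrame:
    """Numeric design from named covariates; categoricals become indicator sets."""
    parts = []
    for cov in covariates:
        if cov not in df.columns:
            raise DesignError(f"covariate {cov!r} not in cohort table")
        if cov in _CATEGORICAL or df[cov].dtype == object:
            dummies = pd.get_dummies(df[cov].astype(str), prefix=cov, drop_first=True)
            parts.append(dummies.astype(float))
        else:
            parts.append(df[[cov]].astype(float))
    out = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)
    if add_intercept:
        out.insert(0, "const", 1.0)
    return out


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name a culprit: columns whose removal restores full column rank
        bad = []
        for j, col in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(col)
        raise DesignError(f"design matrix rank deficient; collinear column(s): {bad}")


# ---------------------------------------------------------------------------
# Core fits
# ---------------------------------------------------------------------------

def fit_logistic(outcome: Sequence[int] | pd.Series, design: pd.DataFrame):
    """Maximum-likelihood logistic fit (Newton, tol 1e-10, <=100 iterations).

    Raises :class:`SeparationError` on (quasi-)perfect separation and
    :class:`DesignError` on rank deficiency or a single-class outcome.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise DesignError("outcome has a single class")
    _check_rank(design)
    with np.errstate(all="ignore"):
        try:
            res = sm.Logit(y, design.to_numpy(dtype=float)).fit(
                method="newton", tol=1e-10, maxiter=100, disp=False,
            )
        except Exception as exc:  # statsmodels raises PerfectSeparationError
            raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", True) or np.any(np.abs(res.params) > 25):
        raise SeparationError("logistic fit did not converge; separation suspected")
    res.model.exog_names[:] = list(design.columns)
    return res


def lrt(full, reduced) -> tuple[float, int, float]:
    """Likelihood-ratio statistic, df, and p between two nested ML fits."""
    statistic = 2.0 * (full.llf - reduced.llf)
    df = int(full.df_model - reduced.df_model)
    return max(float(statistic), 0.0), df, float(stats.chi2.sf(max(statistic, 0.0), df))


def _genotype_columns(cohort: Cohort, snp_id: str, coding: str) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Genotype design columns plus human-readable contrast labels."""
    ann = cohort.annotations[snp_id]
    calls = cohort.genotype_calls(snp_id)
    ref = 2 * ann.non_risk_allele
    het = "".join(sorted(ann.non_risk_allele + ann.risk_allele))
    hom = 2 * ann.risk_allele
    if coding == "codominant":
        pairs = calls.map(lambda c: code_genotype(c, ann, "codominant"))
        gdf = pd.DataFrame(
            {"g_het": pairs.map(lambda t: t[0]), "g_hom": pairs.map(lambda t: t[1])},
            index=cohort.data.index, dtype=float,
        )
        return gdf, ["g_het", "g_hom"], [f"{het} vs {ref}", f"{hom} vs {ref}"]
    code = calls.map(lambda c: code_genotype(c, ann, coding)).astype(float)
    label = f"per {ann.risk_allele} allele" if coding == "additive" else f"{hom} vs {ann.non_risk_allele}-carriers"
    return pd.DataFrame({"g": code}, index=cohort.data.index), ["g"], [label]


# ---------------------------------------------------------------------------
# Stratified odds ratios and interaction tests
# ---------------------------------------------------------------------------

def stratified_or(
    cohort: Cohort,
    snp_id: str,
    outcome: str = "t2d_prevalent",
    stratify_by: str = "obesity",
    model: str = "Model1",
    coding: str = "codominant",
) -> list[AssociationResult]:
    """Per-stratum genotype odds ratios vs the homozygous non-risk reference.

    Each stratum carries a global polymorphism p (likelihood ratio over all
    genotype contrasts); every row carries the pooled genotype-by-stratifier
    interaction p.  Degenerate strata (single-class outcome, empty genotype
    cell) yield rows with NaN estimates rather than aborting the batch.
    """
    if outcome == stratify_by:
        raise DesignError("outcome and stratifying variable must differ")
    gdf, gcols, labels = _genotype_columns(cohort, snp_id, coding)
    covs = _resolve_covariates(model)
    df = cohort.data
    strata = (("non-obese", ~df[stratify_by].astype(bool)), ("obese", df[stratify_by].astype(bool))) \
        if stratify_by == "obesity" else \
        (("non-T2D", ~df[stratify_by].astype(bool)), ("T2D", df[stratify_by].astype(bool)))

    try:
        p_int = interaction_test(cohort, snp_id, stratify_by, outcome, covs, coding)
    except (SeparationError, DesignError):
        p_int = float("nan")
    model = model if isinstance(model, str) else "custom"

    results: list[AssociationResult] = []
    for stratum, mask in strata:
        sub = df[mask]
        gsub = gdf[mask]
        design = build_design(sub, covs)
        keep = gsub.notna().all(axis=1) & design.notna().all(axis=1) & sub[outcome].notna()
        sub, gsub, design = sub[keep], gsub[keep], design[keep]
        design = design.loc[:, (design.nunique() > 1) | (design.columns == "const")]
        full_X = pd.concat([gsub, design], axis=1)
        n = len(sub)
        try:
            full = fit_logistic(sub[outcome].astype(int), full_X)
            red = fit_logistic(sub[outcome].astype(int), design)
            _, _, global_p = lrt(full, red)
            params = pd.Series(full.params, index=full_X.columns)
            bse = pd.Series(full.bse, index=full_X.columns)
            pvals = pd.Series(full.pvalues, index=full_X.columns)
            for col, label in zip(gcols, labels):
                b, se = params[col], bse[col]
                results.append(
                    AssociationResult(
                        contrast=label, estimate=float(b), or_value=float(np.exp(b)),
                        ci_low=float(np.exp(b - 1.959963984540054 * se)),
                        ci_high=float(np.exp(b + 1.959963984540054 * se)),
                        p_value=float(pvals[col]), stratum=stratum, model=model,
                        n=n, global_p=global_p, p_interaction=p_int,
                    )
                )
        except (SeparationError, DesignError) as exc:
            logger.warning("stratified_or: stratum %s undefined (%s)", stratum, exc)
            for label in labels:
                results.append(
                    AssociationResult(
                        contrast=label, estimate=float("nan"), or_value=float("nan"),
                        ci_low=float("nan"), ci_high=float("nan"), p_value=float("nan"),
                        stratum=stratum, model=model, n=n,
                        global_p=float("nan"), p_interaction=p_int,
                    )
                )
    return results


def interaction_test(
    cohort: Cohort,
    snp_id: str,
    modifier: str = "obesity",
    outcome: str = "t2d_prevalent",
    model: str = "Model1",
    coding: str = "codominant",
) -> float:
    """LRT p for the genotype-by-modifier product term(s) in the pooled model.

    Degrees of freedom equal the number of genotype contrasts (2 codominant,
    1 additive/recessive).
    """
    gdf, gcols, _ = _genotype_columns(cohort, snp_id, coding)
    df = cohort.data
    covs = _resolve_covariates(model)
    design = build_design(df, covs)
    mod = df[modifier].astype(float)
    base = pd.concat([gdf, mod.rename("modifier"), design], axis=1)
    keep = base.notna().all(axis=1) & df[outcome].notna()
    base = base[keep]
    y = df.loc[keep, outcome].astype(int)
    inter = pd.DataFrame(
        {f"{g}_x_mod": base[g] * base["modifier"] for g in gcols}, index=base.index
    )
    reduced = fit_logistic(y, base)
    full = fit_logistic(y, pd.concat([base, inter], axis=1))
    _, _, p = lrt(full, reduced)
    return p


# ---------------------------------------------------------------------------
# Continuous traits
# ---------------------------------------------------------------------------

def fit_linear_trait(
    cohort: Cohort,
    snp_id: str,
    trait: str = "bmi",
    stratify_by: str = "t2d_prevalent",
    model: str = "Model1",
) -> dict:
    """Covariate-adjusted genotype means of a continuous trait, by stratum.

    Fits one OLS model with codominant genotype terms, the stratifier, their
    products, and the adjustment covariates; the interaction p is the exact
    F-test on the product terms, and adjusted means are model predictions at
    the grand covariate means.
    """
    gdf, gcols, labels = _genotype_columns(cohort, snp_id, "codominant")
    df = cohort.data
    covs = _resolve_covariates(model)
    design = build_design(df, covs)
    strat = df[stratify_by].astype(float).rename("stratum")
    X = pd.concat([gdf, strat, design], axis=1)
    inter = pd.DataFrame({f"{g}_x_s": X[g] * X["stratum"] for g in gcols}, index=X.index)
    X = pd.concat([X, inter], axis=1)
    keep = X.notna().all(axis=1) & df[trait].notna()
    X, y = X[keep], df.loc[keep, trait].astype(float)
    _check_rank(X)
    fit = sm.OLS(y.to_numpy(), X.to_numpy(dtype=float)).fit()
    names = list(X.columns)

    r_mat = np.zeros((len(gcols), len(names)))
    for i, g in enumerate(gcols):
        r_mat[i, names.index(f"{g}_x_s")] = 1.0
    ftest = fit.f_test(r_mat)
    p_interaction = float(ftest.pvalue)

    cov_means = X.mean()
    adjusted: dict[str, dict[str, float]] = {}
    for s_val, s_name in ((0.0, "non-T2D" if stratify_by == "t2d_prevalent" else "non-obese"),
                          (1.0, "T2D" if stratify_by == "t2d_prevalent" else "obese")):
        adjusted[s_name] = {}
        for geno, (het, hom) in zip(["ref", "het", "hom"], [(0, 0), (1, 0), (0, 1)]):
            row = cov_means.copy()
            row[gcols[0]], row[gcols[1]] = het, hom
            row["stratum"] = s_val
            row[f"{gcols[0]}_x_s"] = het * s_val
            row[f"{gcols[1]}_x_s"] = hom * s_val
            adjusted[s_name][geno] = float(np.dot(fit.params, row[names].to_numpy(dtype=float)))
    return {
        "adjusted_means": adjusted,
        "p_interaction": p_interaction,
        "n": int(len(y)),
        "fit": fit,
        "columns": names,
    }
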