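"""Repeated-measures analysis of BMI trajectories by genotype and diabetes.

The question: does the risk genotype associate with lower BMI over 4- or
6-year follow-up, and only in diabetic subjects (genotype-by-T2D
interaction)?  Panels are complete-case: a subject enters the 4-year window
only with BMI measured at baseline and years 1-4, and the 6-year window
only with all seven annual measurements.

Because genotype and baseline diabetes status are both constant within
subject, their effects -- and their interaction -- are between-subject
effects.  For a complete balanced panel the between-subject stratum of the
classical repeated-measures ANCOVA is algebraically an ANCOVA on the
per-subject mean response, which is also the exact between-subject test of
the compound-symmetry (random-intercept) mixed model.  The tests here are
therefore computed as exact F-tests on subject-mean BMI, which is both the
classical construction and numerically robust.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import DesignError, _check_rank, build_design
from .cohort import GENOTYPE_PREFIX, Cohort, code_genotype

logger = logging.getLogger(__name__)


def build_panel(cohort: Cohort, bmi_long: pd.DataFrame, window_years: int) -> pd.DataFrame:
    """Complete-case long panel for a follow-up window of ``window_years``.

    ``bmi_long`` must hold columns (subject_id, visit_year, bmi).  Subjects
    are retained only if BMI is present at every visit 0..window_years;
    duplicate (subject, visit) keys are a hard error.  Subject-level columns
    from the cohort are merged in; the retention count is logged.
    """
    required = {"subject_id", "visit_year", "bmi"}
    if missing := required - set(bmi_long.columns):
        raise DesignError(f"bmi panel missing column(s): {sorted(missing)}")
    if bmi_long.duplicated(["subject_id", "visit_year"]).any():
        raise DesignError("duplicate (subject_id, visit_year) rows in BMI panel")
    visits = list(range(window_years + 1))
    sub = bmi_long[bmi_long["visit_year"].isin(visits) & bmi_long["bmi"].notna()]
    counts = sub.groupby("subject_id")["visit_year"].nunique()
    complete = counts[counts == len(visits)].index
    panel = sub[sub["subject_id"].isin(complete)].copy()
    logger.info(
        "build_panel: %d of %d subjects complete over %d-year window",
        len(complete), bmi_long["subject_id"].nunique(), window_years,
    )
    baseline = cohort.data.drop(columns=["bmi"], errors="ignore")
    return panel.merge(baseline, on="subject_id", how="inner").sort_values(
        ["subject_id", "visit_year"]
    ).reset_index(drop=True)


def fit_repeated_bmi(
    panel: pd.DataFrame,
    snp_id: str,
    annotations=None,
    covariates: Sequence[str] = (),
    stratify_by: str = "t2d_prevalent",
) -> dict:
    """Between-subject genotype and genotype-by-T2D tests on a BMI panel.

    Returns exact F-test p-values for the overall (codominant, 2-df)
    genotype effect and the genotype-by-diabetes interaction, plus
    covariate-adjusted mean BMI per genotype x diabetes x visit cell
    (predictions at covariate means).
    """
    ann = annotations[snp_id] if annotations else None
    if ann is None:
        raise DesignError("fit_repeated_bmi requires a SNPAnnotation for the SNP")

    pairs = panel[GENOTYPE_PREFIX + snp_id].map(lambda c: code_genotype(c, ann, "codominant"))
    panel = panel.assign(
        g_het=pairs.map(lambda t: t[0]).astype(float),
        g_hom=pairs.map(lambda t: t[1]).astype(float),
        stratum=panel[stratify_by].astype(float),
    ).dropna(subset=["g_het", "g_hom", "bmi"])

    subj_cols = ["g_het", "g_hom", "stratum", *covariates]
    means = panel.groupby("subject_id").agg(
        {**{c: "first" for c in subj_cols}, "bmi": "mean"}
    )
    for side in (0.0, 1.0):
        sub = means.loc[means["stratum"] == side, ["g_het", "g_hom"]]
        if len(sub) and sub.drop_duplicates().shape[0] < 2:
            raise DesignError("need >=2 genotype groups in both strata")

    design = build_design(means, subj_cols[:3])
    if covariates:
        design = pd.concat([design, build_design(means, covariates, add_intercept=False)], axis=1)
    if means["stratum"].nunique() > 1:
        inter = pd.DataFrame(
            {"g_het_x_s": design["g_het"] * design["stratum"],
             "g_hom_x_s": design["g_hom"] * design["stratum"]},
            index=design.index,
        )
    else:  # single-stratum panel: no interaction terms are estimable
        inter = pd.DataFrame(index=design.index)
    X = pd.concat([design, inter], axis=1)
    # a genotype class absent from the panel leaves an all-zero column
    X = X.loc[:, (X.nunique() > 1) | (X.columns == "const")]
    _check_rank(X)
    fit = sm.OLS(means["bmi"].to_numpy(), X.to_numpy(dtype=float)).fit()
    names = list(X.columns)

    def f_test(cols: list[str]) -> float:
        cols = [c for c in cols if c in names]
        if not cols:
            return float("nan")
        r = np.zeros((len(cols), len(names)))
        for i, c in enumerate(cols):
            r[i, names.index(c)] = 1.0
        return float(fit.f_test(r).pvalue)

    p_interaction = f_test(["g_het_x_s", "g_hom_x_s"])
    p_genotype = f_test(["g_het", "g_hom", "g_het_x_s", "g_hom_x_s"])
    # genotype main effect (up to 2 df depending on classes present)
    p_genotype_nonstratum = f_test(["g_het", "g_hom"])

    # adjusted means per genotype x stratum x visit: per-visit OLS predictions
    cov_means = X.mean()
    adjusted = []
    for visit, vdf in panel.groupby("visit_year"):
        vX = pd.concat(
            [
                build_design(vdf, subj_cols[:3]),
                build_design(vdf, covariates, add_intercept=False) if covariates else pd.DataFrame(index=vdf.index),
            ],
            axis=1,
        )
        vX["g_het_x_s"] = vX["g_het"] * vX["stratum"]
        vX["g_hom_x_s"] = vX["g_hom"] * vX["stratum"]
        vfit = sm.OLS(vdf["bmi"].to_numpy(), vX[names].to_numpy(dtype=float)).fit()
        for s_val, s_name in ((0.0, "non-T2D"), (1.0, "T2D")):
            for geno, (het, hom) in (("ref", (0, 0)), ("het", (1, 0)), ("hom", (0, 1))):
                row = cov_means.copy()
                row["g_het"], row["g_hom"], row["stratum"] = het, hom, s_val
                row["g_het_x_s"], row["g_hom_x_s"] = het * s_val, hom * s_val
                adjusted.append(
                    (visit, s_name, geno,
                     float(np.dot(vfit.params, row[names].to_numpy(dtype=float))))
                )
    adjusted_df = pd.DataFrame(
        adjusted, columns=["visit_year", "stratum", "genotype", "adjusted_bmi"]
    )
    return {
        "p_interaction": p_interaction,
        "p_genotype": p_genotype,
        "p_genotype_main": p_genotype_nonstratum,
        "n_subjects": int(len(means)),
        "adjusted_means": adjusted_df,
        "fit": fit,
    }
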