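"""Obesity-specific genetic risk scores: screening, partition, scoring, ROC.

The procedure: each candidate T2D SNP is screened for association with
prevalent diabetes separately in obese and non-obese subjects (additive
coding, adjusted logistic models).  A SNP joins the score of the stratum in
which its association is stronger (smaller p), provided that p clears an
entry threshold; this yields a non-obese score (nobGRS) and an obese score
(obGRS).  Scores are unweighted risk-allele counts, 0..2 per SNP, so a
five-SNP score ranges over 0..10.  Predictive value is measured by the area
under the ROC curve of the raw integer score, by stratum, with the
Mann-Whitney construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import (AssociationResult, DesignError, SeparationError,
                          build_design, fit_logistic)
from .cohort import Cohort, SNPAnnotation, additive_codes

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_IN = 0.10


@dataclass
class GRSPartition:
    """Disjoint SNP sets defining the two obesity-specific scores."""

    nob_set: list[str]
    ob_set: list[str]
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (snp, reason)
    alpha_in: float = DEFAULT_ALPHA_IN

    def audit(self) -> dict:
        return {
            "rule": "SNP joins the stratum with the smaller screening p-value, "
                    f"provided p < alpha_in = {self.alpha_in}",
            "nobGRS": self.nob_set,
            "obGRS": self.ob_set,
            "excluded": [{"snp_id": s, "reason": r} for s, r in self.excluded],
        }


@dataclass
class ROCResult:
    """AUC with a Mann-Whitney p-value against the chance value 0.5."""

    auc: float
    p_value: float
    n_cases: int
    n_controls: int
    curve: pd.DataFrame           # columns: threshold, fpr, tpr
    ci_low: float | None = None   # bootstrap percentile CI when requested
    ci_high: float | None = None


# ---------------------------------------------------------------------------
# Screening and partition
# ---------------------------------------------------------------------------

def screen_snps(
    cohort: Cohort,
    snp_ids: Sequence[str] | None = None,
    outcome: str = "t2d_prevalent",
    covariates: Sequence[str] = ("age", "sex"),
) -> pd.DataFrame:
    """Per-SNP, per-stratum additive logistic screen against prevalent T2D.

    Returns a tidy table (snp_id, stratum, n, or_per_allele, p_value); the
    "all" stratum is additionally adjusted for obesity.  Fit failures
    (monomorphic SNP, separation) are flagged with NaN rows instead of
    aborting the batch.
    """
    ids = list(snp_ids) if snp_ids is not None else cohort.snp_ids
    df = cohort.data
    rows = []
    strata = (
        ("all", pd.Series(True, index=df.index), tuple(covariates) + ("obesity",)),
        ("non-obese", ~df["obesity"].astype(bool), tuple(covariates)),
        ("obese", df["obesity"].astype(bool), tuple(covariates)),
    )
    for snp in ids:
        dose = additive_codes(cohort, snp)
        for stratum, mask, covs in strata:
            sub = df[mask]
            d = dose[mask]
            design = build_design(sub, covs)
            keep = d.notna() & design.notna().all(axis=1) & sub[outcome].notna()
            X = pd.concat([d[keep].rename("g"), design[keep]], axis=1)
            try:
                if d[keep].nunique() < 2:
                    raise DesignError("monomorphic SNP in stratum")
                fit = fit_logistic(sub.loc[keep, outcome].astype(int), X)
                params = pd.Series(fit.params, index=X.columns)
                pvals = pd.Series(fit.pvalues, index=X.columns)
                rows.append((snp, stratum, int(keep.sum()),
                             float(np.exp(params["g"])), float(pvals["g"])))
            except (DesignError, SeparationError) as exc:
                logger.warning("screen_snps: %s in %s flagged (%s)", snp, stratum, exc)
                rows.append((snp, stratum, int(keep.sum()), float("nan"), float("nan")))
    return pd.DataFrame(rows, columns=["snp_id", "stratum", "n", "or_per_allele", "p_value"])


def partition_snps(table: pd.DataFrame, alpha_in: float = DEFAULT_ALPHA_IN) -> GRSPartition:
    """Assign each screened SNP to the obesity-specific score of its stronger stratum.

    A SNP joins nobGRS if its non-obese p is the smaller one and clears
    ``alpha_in`` (default 0.10, configurable), symmetrically for obGRS;
    otherwise it is excluded with a reason.  The rule and threshold are
    logged for audit.
    """
    nob, ob, excluded = [], [], []
    for snp, sub in table.groupby("snp_id", sort=False):
        by = sub.set_index("stratum")
        try:
            p_nob = float(by.loc["non-obese", "p_value"])
            p_ob = float(by.loc["obese", "p_value"])
        except KeyError:
            excluded.append((snp, "missing stratum row"))
            continue
        if np.isnan(p_nob) and np.isnan(p_ob):
            excluded.append((snp, "no stratum fit available"))
        elif min(p for p in (p_nob, p_ob) if not np.isnan(p)) >= alpha_in:
            excluded.append((snp, f"no stratum p below alpha_in={alpha_in}"))
        elif np.isnan(p_ob) or (not np.isnan(p_nob) and p_nob <= p_ob):
            nob.append(snp)
        else:
            ob.append(snp)
    part = GRSPartition(nob_set=nob, ob_set=ob, excluded=excluded, alpha_in=alpha_in)
    logger.info("partition_snps: %s", part.audit())
    return part


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def compute_grs(cohort: Cohort, snp_set: Iterable[str]) -> pd.Series:
    """Unweighted risk-allele count over a SNP set (0..2 per SNP).

    Subjects missing any member genotype receive a missing score: partial
    counts are never prorated.  SNPs lacking a risk-allele annotation are a
    hard error.
    """
    snps = list(snp_set)
    for snp in snps:
        if snp not in cohort.annotations:
            raise KeyError(f"compute_grs: no risk-allele annotation for {snp!r}")
    if not snps:
        return pd.Series(0.0, index=cohort.data.index, name="grs")
    mat = pd.concat([additive_codes(cohort, s) for s in snps], axis=1)
    score = mat.sum(axis=1, skipna=False)
    return score.rename("grs")


def grs_association(
    cohort: Cohort,
    score: pd.Series,
    outcome: str = "t2d_prevalent",
    covariates: Sequence[str] = ("age", "sex", "obesity"),
    model_label: str = "GRS",
) -> list[AssociationResult]:
    """Per-point (per risk allele) odds ratio of a continuous score on T2D.

    Fitted overall and within each obesity stratum; the overall fit keeps
    the obesity adjustment, stratum fits drop it.
    """
    df = cohort.data
    strata = (
        ("all", pd.Series(True, index=df.index), tuple(covariates)),
        ("non-obese", ~df["obesity"].astype(bool),
         tuple(c for c in covariates if c != "obesity")),
        ("obese", df["obesity"].astype(bool),
         tuple(c for c in covariates if c != "obesity")),
    )
    out = []
    for stratum, mask, covs in strata:
        sub = df[mask]
        s = score[mask]
        if s.dropna().nunique() < 2:
            raise DesignError(f"grs_association: score is constant in stratum {stratum!r}")
        design = build_design(sub, covs)
        keep = s.notna() & design.notna().all(axis=1) & sub[outcome].notna()
        X = pd.concat([s[keep].rename("grs"), design[keep]], axis=1)
        fit = fit_logistic(sub.loc[keep, outcome].astype(int), X)
        params = pd.Series(fit.params, index=X.columns)
        bse = pd.Series(fit.bse, index=X.columns)
        pvals = pd.Series(fit.pvalues, index=X.columns)
        b, se = params["grs"], bse["grs"]
        out.append(
            AssociationResult(
                contrast="per risk allele", estimate=float(b),
                or_value=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.959963984540054 * se)),
                ci_high=float(np.exp(b + 1.959963984540054 * se)),
                p_value=float(pvals["grs"]), stratum=stratum,
                model=model_label, n=int(keep.sum()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(
    score: Sequence[float] | pd.Series,
    outcome: Sequence[int] | pd.Series,
    n_boot: int = 0,
    seed: int = 0,
) -> ROCResult:
    """AUC by the Mann-Whitney rank construction, ties counted one half.

    The p-value is the two-sided normal-approximation Mann-Whitney test of
    AUC = 0.5 (tie-corrected variance).  The full step curve is returned;
    an optional seeded bootstrap (percentile, ``n_boot`` resamples) yields a
    confidence interval.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=int)
    ok = ~np.isnan(s)
    s, y = s[ok], y[ok]
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc: both outcome classes must be present")

    auc = _auc_rank(s, y)
    # tie-corrected normal approximation for U under H0
    n = n1 + n0
    _, counts = np.unique(s, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        p = 1.0
    else:
        z = (auc * n1 * n0 - n1 * n0 / 2.0) / np.sqrt(var_u)
        p = float(2.0 * stats.norm.sf(abs(z)))

    thresholds = np.unique(s)[::-1]
    tpr = [(s[y == 1] >= t).mean() for t in thresholds]
    fpr = [(s[y == 0] >= t).mean() for t in thresholds]
    curve = pd.DataFrame(
        {
            "threshold": np.concatenate(([np.inf], thresholds)),
            "fpr": np.concatenate(([0.0], fpr)),
            "tpr": np.concatenate(([0.0], tpr)),
        }
    )

    ci_low = ci_high = None
    if n_boot:
        rng = np.random.default_rng(seed)
        idx1, idx0 = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate(
                [rng.choice(idx1, n1, replace=True), rng.choice(idx0, n0, replace=True)]
            )
            reps[b] = _auc_rank(s[take], y[take])
        ci_low, ci_high = (float(q) for q in np.percentile(reps, [2.5, 97.5]))

    return ROCResult(auc=float(auc), p_value=p, n_cases=n1, n_controls=n0,
                     curve=curve, ci_low=ci_low, ci_high=ci_high)


def _auc_rank(s: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
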