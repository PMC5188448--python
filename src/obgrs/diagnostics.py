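"""Predictive-value metrics for a binary genetic test on a binary outcome.

Used for the recessive-model question: how well does carrying two risk
alleles (TT) "predict" incident type-2 diabetes, and how does that differ
between obese and non-obese subjects?  Reports sensitivity, specificity,
PPV, and NPV with exact Clopper-Pearson intervals, plus the Pearson
chi-square association p for the underlying 2x2 table (Fisher's exact test
when any expected cell is below 5, which is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class DiagnosticResult:
    stratum: str
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    p_value: float
    test_used: str


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _safe_prop(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def predictive_values(test, outcome, stratum: str = "all") -> DiagnosticResult:
    """Sensitivity/specificity/PPV/NPV of a binary test against a binary outcome.

    Proportions with empty denominators (e.g. specificity when everyone has
    the outcome) are reported as NaN rather than raising.
    """
    t = np.asarray(test, dtype=bool)
    y = np.asarray(outcome, dtype=bool)
    if t.size == 0:
        raise ValueError("predictive_values: empty stratum")
    tp = int((t & y).sum())
    fp = int((t & ~y).sum())
    fn = int((~t & y).sum())
    tn = int((~t & ~y).sum())

    table = np.array([[tp, fp], [fn, tn]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        p, used = float("nan"), "undefined (degenerate table)"
    else:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if expected.min() < 5:
            p = float(stats.fisher_exact(table)[1])
            used = "fisher"
            logger.info("predictive_values[%s]: expected cell < 5, Fisher exact used", stratum)
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            p, used = float(p), "pearson-chi2"

    return DiagnosticResult(
        stratum=stratum, tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=_safe_prop(tp, tp + fn),
        specificity=_safe_prop(tn, tn + fp),
        ppv=_safe_prop(tp, tp + fp),
        npv=_safe_prop(tn, tn + fn),
        sensitivity_ci=_clopper_pearson(tp, tp + fn),
        specificity_ci=_clopper_pearson(tn, tn + fp),
        ppv_ci=_clopper_pearson(tp, tp + fp),
        npv_ci=_clopper_pearson(tn, tn + fn),
        p_value=p, test_used=used,
    )
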