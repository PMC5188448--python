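"""Synthetic cohort generator and Monte-Carlo power estimation.

The generator emulates the statistical structure of a large Mediterranean
primary-prevention cohort of older adults at high cardiovascular risk
(n = 7018): Hardy-Weinberg genotypes at ten candidate T2D SNPs, roughly 47%
obesity prevalence, roughly 49% prevalent type-2 diabetes, obesity-stratified
genotype odds ratios for prevalent T2D, and incident T2D over a staggered
open cohort (uniform enrollment over a 6.2-year accrual window, administrative
censoring 8.7 years after study start, hence median follow-up about 5.7
years) with obesity-stratified genotype hazard ratios.  An optional long
panel of annual BMI measurements carries a genotype-by-diabetes effect on
BMI trajectories.

All stochastic draws go through one :class:`numpy.random.Generator` so a
seed reproduces a cohort byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import GENOTYPE_PREFIX, Cohort, SNPAnnotation

STRATA = ("non-obese", "obese")

#: Default SNP panel.  Risk-allele frequencies for the index TCF7L2 variant
#: derive from the cohort's genotype distribution (T-allele 0.374); the other
#: nine use typical European frequencies.  Stratum-specific per-genotype odds
#: ratios reproduce the observed pattern: the TCF7L2 effect is concentrated
#: in non-obese subjects; the remaining SNPs carry a modest per-allele effect
#: confined to the stratum whose score they later join.
DEFAULT_SNPS: tuple[dict, ...] = (
    dict(snp_id="rs7903146", gene="TCF7L2", alleles=("C", "T"), risk="T", freq=0.374,
         or_het={"non-obese": 1.78, "obese": 1.27}, or_hom={"non-obese": 2.26, "obese": 1.53}),
    dict(snp_id="rs12899811", gene="PRC1", alleles=("G", "C"), risk="C", freq=0.30,
         or_het={"non-obese": 1.15, "obese": 1.0}, or_hom={"non-obese": 1.15 ** 2, "obese": 1.0}),
    dict(snp_id="rs11634397", gene="ZFAND6", alleles=("A", "G"), risk="G", freq=0.40,
         or_het={"non-obese": 1.15, "obese": 1.0}, or_hom={"non-obese": 1.15 ** 2, "obese": 1.0}),
    dict(snp_id="rs11257655", gene="CDC123_CAMK1D", alleles=("C", "T"), risk="T", freq=0.18,
         or_het={"non-obese": 1.15, "obese": 1.0}, or_hom={"non-obese": 1.15 ** 2, "obese": 1.0}),
    dict(snp_id="rs163184", gene="KCNQ1", alleles=("T", "G"), risk="G", freq=0.47,
         or_het={"non-obese": 1.15, "obese": 1.0}, or_hom={"non-obese": 1.15 ** 2, "obese": 1.0}),
    dict(snp_id="rs6798189", gene="ADCY5", alleles=("A", "G"), risk="G", freq=0.33,
         or_het={"non-obese": 1.0, "obese": 1.15}, or_hom={"non-obese": 1.0, "obese": 1.15 ** 2}),
    dict(snp_id="rs4402960", gene="IGF2BP2", alleles=("G", "T"), risk="T", freq=0.32,
         or_het={"non-obese": 1.0, "obese": 1.15}, or_hom={"non-obese": 1.0, "obese": 1.15 ** 2}),
    dict(snp_id="rs3802177", gene="SLC30A8", alleles=("A", "G"), risk="G", freq=0.31,
         or_het={"non-obese": 1.0, "obese": 1.15}, or_hom={"non-obese": 1.0, "obese": 1.15 ** 2}),
    dict(snp_id="rs10842994", gene="KLHDC5", alleles=("T", "C"), risk="C", freq=0.21,
         or_het={"non-obese": 1.0, "obese": 1.15}, or_hom={"non-obese": 1.0, "obese": 1.15 ** 2}),
    dict(snp_id="rs2261181", gene="HMGA2", alleles=("C", "T"), risk="T", freq=0.11,
         or_het={"non-obese": 1.0, "obese": 1.15}, or_hom={"non-obese": 1.0, "obese": 1.15 ** 2}),
)


@dataclass(frozen=True)
class SNPModel:
    """Allele frequency and stratum-specific prevalence effects for one SNP."""

    snp_id: str
    gene_label: str
    allele_a: str
    allele_b: str
    risk_allele: str
    risk_freq: float
    or_het: Mapping[str, float]
    or_hom: Mapping[str, float]

    def annotation(self) -> SNPAnnotation:
        return SNPAnnotation(self.snp_id, self.gene_label, self.allele_a,
                             self.allele_b, self.risk_allele)


def _default_snp_models() -> tuple[SNPModel, ...]:
    return tuple(
        SNPModel(
            snp_id=d["snp_id"], gene_label=d["gene"], allele_a=d["alleles"][0],
            allele_b=d["alleles"][1], risk_allele=d["risk"], risk_freq=d["freq"],
            or_het=dict(d["or_het"]), or_hom=dict(d["or_hom"]),
        )
        for d in DEFAULT_SNPS
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters mirroring the fitted quantities of the analysis.

    The defaults are the study conditions: cohort size 7018; obesity
    prevalence 46.7%; per-stratum prevalent-T2D fractions 49.1% (non-obese)
    and 48.4% (obese); incident-T2D baseline rates in homozygous non-risk
    subjects of 11.6 (non-obese) and 17.7 (obese) per 1000 person-years with
    hazard ratios 1.14/1.81 (non-obese CT/TT) and 1.05/1.01 (obese CT/TT);
    accrual uniform over 6.2 years with administrative censoring at 8.7
    years; BMI mean 29.7, SD 3.8 kg/m2 at baseline with a -0.5 kg/m2 per
    risk-allele effect confined to diabetic subjects.
    """

    n_subjects: int = 7018
    snps: tuple[SNPModel, ...] = field(default_factory=_default_snp_models)
    obesity_prevalence: float = 3279 / 7018
    t2d_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"non-obese": 1835 / 3739, "obese": 1586 / 3279}
    )
    # incidence model (index SNP only drives the hazard)
    baseline_rate: Mapping[str, float] = field(
        default_factory=lambda: {"non-obese": 0.0116, "obese": 0.0177}
    )
    hr_het: Mapping[str, float] = field(
        default_factory=lambda: {"non-obese": 1.14, "obese": 1.05}
    )
    hr_hom: Mapping[str, float] = field(
        default_factory=lambda: {"non-obese": 1.81, "obese": 1.01}
    )
    accrual_years: float = 6.2
    admin_censor_years: float = 8.7
    # BMI model
    bmi_sd: float = 3.8
    bmi_genotype_effect_t2d: float = -0.5   # kg/m2 per risk allele, diabetic subjects
    bmi_genotype_effect_nont2d: float = 0.0
    # longitudinal panel
    bmi_annual_drift: float = -0.05         # kg/m2 per year, population drift
    bmi_within_subject_sd: float = 0.8      # visit-to-visit measurement/biology noise
    bmi_slope_effect_t2d: float = 0.0       # extra per-allele slope in diabetics
    n_centers: int = 7

    @property
    def index_snp(self) -> SNPModel:
        return self.snps[0]

    @property
    def bmi_mean(self) -> float:
        """Baseline BMI location implied by the obesity prevalence target."""
        return OBESITY_THRESHOLD - self.bmi_sd * stats.norm.ppf(1.0 - self.obesity_prevalence)


OBESITY_THRESHOLD = 30.0


# ---------------------------------------------------------------------------
# Calibration helpers
# ---------------------------------------------------------------------------

def _hwe_probs(freq: float) -> np.ndarray:
    q = 1.0 - freq
    return np.array([q * q, 2 * q * freq, freq * freq])


def _solve_intercept(target: float, genotype_probs: np.ndarray, logors: np.ndarray) -> float:
    """Intercept of a logistic prevalence model hitting a marginal target."""

    def marginal(b0: float) -> float:
        return float(np.sum(genotype_probs * (1 / (1 + np.exp(-(b0 + logors)))))) - target

    return optimize.brentq(marginal, -20.0, 20.0)


def expected_event_probability(rate: float, accrual: float, admin: float) -> float:
    """P(event) under an exponential hazard with uniform staggered entry.

    Entry is uniform on [0, accrual]; a subject entering at u is observed for
    at most admin - u years, so the censoring horizon C is uniform on
    [admin - accrual, admin] and P(event) = 1 - E[exp(-rate C)].
    """
    lo, hi = admin - accrual, admin
    if rate <= 0:
        return 0.0
    return 1.0 - (math.exp(-rate * lo) - math.exp(-rate * hi)) / (rate * (hi - lo))


def calibrate_baseline_rate(config: SimulationConfig, target_events: float,
                            n_subjects: int | None = None) -> SimulationConfig:
    """Scale both stratum baseline hazards so expected incident events hit a target.

    The expectation integrates over the genotype distribution of the index
    SNP, obesity prevalence, and the uniform-entry censoring horizon.
    """
    n = n_subjects if n_subjects is not None else config.n_subjects
    snp = config.index_snp
    gp = _hwe_probs(snp.risk_freq)
    p_ob = config.obesity_prevalence

    def expected(scale: float) -> float:
        total = 0.0
        for stratum, w_str in (("non-obese", 1 - p_ob), ("obese", p_ob)):
            base = config.baseline_rate[stratum] * scale
            hrs = np.array([1.0, config.hr_het[stratum], config.hr_hom[stratum]])
            for pg, hr in zip(gp, hrs):
                total += n * w_str * pg * expected_event_probability(
                    base * hr, config.accrual_years, config.admin_censor_years
                )
        return total - target_events

    scale = optimize.brentq(expected, 1e-4, 1e3)
    return replace(
        config,
        baseline_rate={k: v * scale for k, v in config.baseline_rate.items()},
    )


# ---------------------------------------------------------------------------
# Config constructors for standard experimental conditions
# ---------------------------------------------------------------------------

def _with_effects(snp: SNPModel, or_het: Mapping[str, float],
                  or_hom: Mapping[str, float]) -> SNPModel:
    return replace(snp, or_het=dict(or_het), or_hom=dict(or_hom))


def null_effect_config(**overrides) -> SimulationConfig:
    """Every SNP null on prevalence, the index SNP null on incidence too."""
    base = SimulationConfig(**overrides)
    ones = {"non-obese": 1.0, "obese": 1.0}
    return replace(
        base,
        snps=tuple(_with_effects(s, ones, ones) for s in base.snps),
        hr_het=dict(ones), hr_hom=dict(ones),
        bmi_genotype_effect_t2d=0.0,
    )


def null_interaction_config(**overrides) -> SimulationConfig:
    """Real index-SNP main effects but identical in both obesity strata.

    Used for null-calibration checks of the interaction tests: prevalence
    ORs 1.78 (het) and 2.26 (hom) in both strata, incidence HRs 1.14/1.81 in
    both strata.
    """
    base = SimulationConfig(**overrides)
    ones = {"non-obese": 1.0, "obese": 1.0}
    snps = [_with_effects(base.snps[0],
                          {"non-obese": 1.78, "obese": 1.78},
                          {"non-obese": 2.26, "obese": 2.26})]
    snps += [_with_effects(s, ones, ones) for s in base.snps[1:]]
    return replace(
        base,
        snps=tuple(snps),
        hr_het={"non-obese": 1.14, "obese": 1.14},
        hr_hom={"non-obese": 1.81, "obese": 1.81},
        bmi_genotype_effect_t2d=0.0,
    )


def confined_effects_config(per_allele_or: float = 1.15, **overrides) -> SimulationConfig:
    """All ten SNPs carry a per-allele OR confined to their score's stratum.

    The five non-obese-score SNPs (index SNP included) act only in non-obese
    subjects and the five obese-score SNPs only in obese subjects -- the
    generative counterpart of the obesity-specific-score hypothesis.
    """
    base = SimulationConfig(**overrides)
    snps = []
    for i, s in enumerate(base.snps):
        stratum = "non-obese" if i < 5 else "obese"
        other = "obese" if i < 5 else "non-obese"
        snps.append(
            _with_effects(
                s,
                {stratum: per_allele_or, other: 1.0},
                {stratum: per_allele_or ** 2, other: 1.0},
            )
        )
    return replace(base, snps=tuple(snps), bmi_genotype_effect_t2d=0.0)


#: SNP ids of the two obesity-specific scores under the default panel.
NOB_SET = tuple(d["snp_id"] for d in DEFAULT_SNPS[:5])
OB_SET = tuple(d["snp_id"] for d in DEFAULT_SNPS[5:])


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _draw_genotypes(rng: np.random.Generator, snp: SNPModel, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (dose, call string) arrays for one SNP under HWE."""
    dose = rng.choice(3, size=n, p=_hwe_probs(snp.risk_freq))
    ref, risk = snp.non_risk, snp.risk_allele
    calls = np.array(
        ["".join(sorted(ref + ref)), "".join(sorted(ref + risk)), "".join(sorted(risk + risk))]
    )[dose]
    return dose, calls


# convenience accessor, kept off the frozen dataclass
def _snp_non_risk(self: SNPModel) -> str:
    return self.allele_b if self.risk_allele == self.allele_a else self.allele_a


SNPModel.non_risk = property(_snp_non_risk)  # type: ignore[attr-defined]


def simulate_cohort(config: SimulationConfig, seed: int | np.random.Generator) -> Cohort:
    """Draw one cohort under the generative model.

    Order of generation: genotypes (independent loci, HWE) -> covariates ->
    baseline BMI -> obesity (BMI >= 30) -> prevalent T2D from the
    obesity-stratified logistic model -> genotype-by-T2D BMI shift (obesity
    recomputed afterwards so the BMI >= 30 invariant holds) -> incident T2D
    for prevalence-free subjects from stratified exponential hazards with
    uniform staggered entry and administrative censoring.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_subjects

    doses: dict[str, np.ndarray] = {}
    calls: dict[str, np.ndarray] = {}
    for snp in config.snps:
        doses[snp.snp_id], calls[snp.snp_id] = _draw_genotypes(rng, snp, n)

    age = np.clip(rng.normal(67.0, 6.2, n), 55, 80).round(1)
    sex = np.where(rng.random(n) < 0.574, "female", "male")
    center = np.array([f"C{i + 1}" for i in rng.integers(0, config.n_centers, n)])
    arm = np.array(["MedDiet+EVOO", "MedDiet+nuts", "control"])[rng.integers(0, 3, n)]
    energy = np.clip(rng.normal(2276, 607, n), 500, 6000).round(0)
    meddiet = np.clip(rng.normal(8.7, 2.0, n), 0, 14).round(0)
    alcohol = np.clip(rng.exponential(8.4, n), 0, 120).round(1)
    smoker = rng.random(n) < 0.141
    phys_act = np.clip(rng.normal(231.6, 240.4, n), 0, 2000).round(0)
    dyslipidemia = rng.random(n) < 0.72
    hypertension = rng.random(n) < 0.83

    bmi = rng.normal(config.bmi_mean, config.bmi_sd, n)
    obesity = bmi >= OBESITY_THRESHOLD

    # prevalent T2D: stratum-specific logistic in the index-SNP genotype plus
    # modest additive effects of the other SNPs confined to their stratum
    logit = np.zeros(n)
    for stratum, mask in (("non-obese", ~obesity), ("obese", obesity)):
        lin = np.zeros(mask.sum())
        for snp in config.snps:
            d = doses[snp.snp_id][mask]
            lin += np.where(d == 1, math.log(snp.or_het[stratum]), 0.0)
            lin += np.where(d == 2, math.log(snp.or_hom[stratum]), 0.0)
        # intercept calibrated against the expected linear-predictor mix
        probs_cells, logor_cells = _cell_distribution(config, stratum)
        b0 = _solve_intercept(config.t2d_prevalence[stratum], probs_cells, logor_cells)
        logit[mask] = b0 + lin
    t2d_prev = rng.random(n) < 1 / (1 + np.exp(-logit))

    # genotype-by-diabetes effect on BMI (the trajectory model's baseline)
    idx_dose = doses[config.index_snp.snp_id]
    bmi = bmi + np.where(
        t2d_prev,
        config.bmi_genotype_effect_t2d,
        config.bmi_genotype_effect_nont2d,
    ) * idx_dose
    obesity = bmi >= OBESITY_THRESHOLD

    # incidence among prevalence-free subjects
    entry = rng.uniform(0.0, config.accrual_years, n)
    horizon = config.admin_censor_years - entry
    rate = np.empty(n)
    for stratum, mask in (("non-obese", ~obesity), ("obese", obesity)):
        hr = np.select(
            [idx_dose[mask] == 1, idx_dose[mask] == 2],
            [config.hr_het[stratum], config.hr_hom[stratum]],
            default=1.0,
        )
        rate[mask] = config.baseline_rate[stratum] * hr
    event_time = rng.exponential(1.0 / rate)
    incident = (~t2d_prev) & (event_time <= horizon)
    followup = np.where(t2d_prev, np.nan, np.minimum(event_time, horizon))

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "center": center,
            "arm": arm,
            "bmi": bmi.round(2),
            "obesity": obesity,
            "t2d_prevalent": t2d_prev,
            "followup_years": np.round(followup, 4),
            "t2d_incident": incident,
            "energy_kcal": energy,
            "meddiet_score": meddiet,
            "alcohol_g": alcohol,
            "smoker": smoker,
            "physical_activity": phys_act,
            "dyslipidemia": dyslipidemia,
            "hypertension": hypertension,
        }
    )
    for snp in config.snps:
        df[GENOTYPE_PREFIX + snp.snp_id] = calls[snp.snp_id]

    annotations = {snp.snp_id: snp.annotation() for snp in config.snps}
    return Cohort(data=df, annotations=annotations)


def _cell_distribution(config: SimulationConfig, stratum: str) -> tuple[np.ndarray, np.ndarray]:
    """Joint genotype-cell probabilities and log-OR sums for intercept calibration.

    Loci are independent, so the expected prevalence is a product-mixture;
    enumerating all cells is exponential in SNP count, so the mixture is
    collapsed to a Monte-Carlo-free approximation: the index SNP exactly, the
    other loci through the expectation of exp(logit) (adequate because their
    effects are small).
    """
    snp = config.index_snp
    probs = _hwe_probs(snp.risk_freq)
    logors = np.array(
        [0.0, math.log(snp.or_het[stratum]), math.log(snp.or_hom[stratum])]
    )
    # mean linear-predictor shift from the small-effect background loci
    shift = 0.0
    for other in config.snps[1:]:
        p = _hwe_probs(other.risk_freq)
        lo = np.array([0.0, math.log(other.or_het[stratum]), math.log(other.or_hom[stratum])])
        shift += float(np.dot(p, lo))
    return probs, logors + shift


# ---------------------------------------------------------------------------
# Longitudinal BMI panel
# ---------------------------------------------------------------------------

def simulate_bmi_panel(
    cohort: Cohort,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    n_years: int = 6,
) -> pd.DataFrame:
    """Annual BMI measurements (long format) for every cohort subject.

    BMI at visit t = baseline BMI + drift t + per-allele slope effect (T2D
    subjects only) t + subject-independent visit noise.  The baseline value
    already carries the genotype-by-T2D level effect from the cohort draw.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = cohort.data
    idx = config.index_snp.snp_id
    dose = df[GENOTYPE_PREFIX + idx].map(
        lambda c: c.count(config.index_snp.risk_allele) if isinstance(c, str) else np.nan
    ).to_numpy(dtype=float)
    rows = []
    for t in range(n_years + 1):
        slope = config.bmi_annual_drift * t + np.where(
            df["t2d_prevalent"], config.bmi_slope_effect_t2d * dose * t, 0.0
        )
        noise = rng.normal(0.0, config.bmi_within_subject_sd, len(df)) if t > 0 else 0.0
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": df["subject_id"],
                    "visit_year": t,
                    "bmi": (df["bmi"] + slope + noise).round(2),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Monte-Carlo power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerResult:
    """Detection fraction of an interaction test over simulation replicates."""

    alpha: float
    n_replicates: int
    n_detected: int
    n_failed: int
    effect_label: str

    @property
    def power(self) -> float:
        return self.n_detected / (self.n_replicates - self.n_failed)

    def binomial_ci(self, level: float = 0.95) -> tuple[float, float]:
        n = self.n_replicates - self.n_failed
        lo, hi = stats.binomtest(self.n_detected, n).proportion_ci(level, method="exact")
        return float(lo), float(hi)


def simulate_incidence_design(
    rng: np.random.Generator,
    n: int,
    carrier_freq: float,
    obesity_prev: float,
    hr_interaction: float,
    baseline_rate: Mapping[str, float],
    accrual: float,
    admin: float,
) -> pd.DataFrame:
    """Lean incident-only cohort for power studies (recessive carrier model).

    The risk-genotype effect acts in non-obese subjects only, so the
    interaction hazard ratio (ratio of stratum-specific carrier HRs) equals
    ``hr_interaction`` -- the observed pattern of effect confinement.
    """
    carrier = rng.random(n) < carrier_freq
    obese = rng.random(n) < obesity_prev
    rate = np.where(obese, baseline_rate["obese"], baseline_rate["non-obese"])
    rate = rate * np.where(carrier & ~obese, hr_interaction, 1.0)
    entry = rng.uniform(0.0, accrual, n)
    horizon = admin - entry
    t = rng.exponential(1.0 / rate)
    return pd.DataFrame(
        {
            "carrier": carrier.astype(float),
            "obese": obese.astype(float),
            "time": np.minimum(t, horizon),
            "event": (t <= horizon).astype(int),
        }
    )


def estimate_power(
    effect_hr: float = 1.75,
    n_subjects: int = 3607,
    target_events: float = 312.0,
    carrier_freq: float = 0.118,
    obesity_prev: float = 0.47,
    alpha: float = 0.05,
    n_replicates: int = 300,
    seed: int | np.random.Generator = 0,
    accrual_years: float = 6.2,
    admin_censor_years: float = 8.7,
) -> PowerResult:
    """Monte-Carlo power of the recessive-model Cox gene-obesity interaction test.

    Each replicate draws a T2D-free cohort with the stated carrier frequency
    and obesity prevalence, baseline hazards (obese:non-obese rate ratio
    ~1.5) jointly calibrated so the expected event count matches
    ``target_events``, and a carrier hazard ratio of ``effect_hr`` confined
    to non-obese subjects.  The interaction is tested by the 1-df likelihood
    ratio comparing Cox models with and without the carrier-by-obesity
    product term.
    """
    from .survival import cox_lrt_interaction

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    base = {"non-obese": 0.0116, "obese": 0.0177}

    def expected(scale: float) -> float:
        tot = 0.0
        for stratum, w in (("non-obese", 1 - obesity_prev), ("obese", obesity_prev)):
            for carrier_p, hr in ((1 - carrier_freq, 1.0),
                                  (carrier_freq, effect_hr if stratum == "non-obese" else 1.0)):
                tot += n_subjects * w * carrier_p * expected_event_probability(
                    base[stratum] * scale * hr, accrual_years, admin_censor_years
                )
        return tot - target_events

    scale = optimize.brentq(expected, 1e-3, 1e3)
    rates = {k: v * scale for k, v in base.items()}

    detected = failed = 0
    for _ in range(n_replicates):
        df = simulate_incidence_design(
            rng, n_subjects, carrier_freq, obesity_prev, effect_hr,
            rates, accrual_years, admin_censor_years,
        )
        try:
            p = cox_lrt_interaction(df, "time", "event", "carrier", "obese")
        except Exception:
            failed += 1
            continue
        detected += int(p < alpha)
    if failed > 0.05 * n_replicates:
        raise RuntimeError(f"power estimation unstable: {failed} replicate fits failed")
    return PowerResult(
        alpha=alpha,
        n_replicates=n_replicates,
        n_detected=detected,
        n_failed=failed,
        effect_label=f"recessive gene-obesity interaction HR {effect_hr}",
    )
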