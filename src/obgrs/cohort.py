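"""Cohort loading, genotype coding, and Hardy-Weinberg quality checks.

The universal input of the package is a subject-level cohort table: one row
per participant carrying demographics, lifestyle covariates, the obesity and
prevalent-diabetes phenotypes, follow-up information, and genotype calls at
up to ten candidate SNPs.  Genotypes may be supplied inline (columns named
``snp:<rsid>`` holding calls such as ``"CT"``) or in a small VCF whose sample
ids match the phenotype table's ``subject_id`` column.

Obesity is defined as BMI >= 30 kg/m2 and is always recomputed from BMI at
load time; a supplied flag that disagrees is overridden (and the conflict
logged) so that a single rule governs every downstream stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

OBESITY_BMI_THRESHOLD = 30.0

#: Columns that must be present in every phenotype table.
MANDATORY_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "center",
    "arm",
    "bmi",
    "t2d_prevalent",
    "followup_years",
    "t2d_incident",
)

#: Lifestyle/clinical covariates used by the fully adjusted models ("Model 2").
LIFESTYLE_COVARIATES = (
    "energy_kcal",
    "meddiet_score",
    "alcohol_g",
    "smoker",
    "physical_activity",
    "dyslipidemia",
    "hypertension",
)

GENOTYPE_PREFIX = "snp:"


class CohortError(ValueError):
    """Raised for structural problems in cohort inputs."""


@dataclass(frozen=True)
class SNPAnnotation:
    """Identity and allele information for one biallelic SNP.

    ``risk_allele`` is the allele whose dosage (0/1/2) defines the additive
    code and whose homozygote defines the recessive "exposed" group.
    """

    snp_id: str
    gene_label: str
    allele_a: str
    allele_b: str
    risk_allele: str

    def __post_init__(self) -> None:
        if self.risk_allele not in (self.allele_a, self.allele_b):
            raise CohortError(
                f"{self.snp_id}: risk allele {self.risk_allele!r} is not one of "
                f"the declared alleles ({self.allele_a!r}, {self.allele_b!r})"
            )

    @property
    def non_risk_allele(self) -> str:
        return self.allele_b if self.risk_allele == self.allele_a else self.allele_a


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts ordered as (hom non-risk, het, hom risk)."""

    n_homref: int
    n_het: int
    n_homalt: int

    @property
    def total(self) -> int:
        return self.n_homref + self.n_het + self.n_homalt


@dataclass
class Cohort:
    """Validated subject-level table plus SNP annotations.

    ``data`` holds one row per subject; genotype calls live in ``snp:<rsid>``
    columns as normalized two-letter strings (alphabetical order) with NaN for
    missing calls.
    """

    data: pd.DataFrame
    annotations: dict[str, SNPAnnotation] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def snp_ids(self) -> list[str]:
        return [
            c[len(GENOTYPE_PREFIX):]
            for c in self.data.columns
            if c.startswith(GENOTYPE_PREFIX)
        ]

    def genotype_calls(self, snp_id: str) -> pd.Series:
        col = GENOTYPE_PREFIX + snp_id
        if col not in self.data.columns:
            raise CohortError(f"no genotype column for SNP {snp_id!r}")
        return self.data[col]

    def incidence_subset(self) -> "Cohort":
        """Subjects free of diabetes at baseline with positive follow-up."""
        sub = self.data[~self.data["t2d_prevalent"].astype(bool)].copy()
        return Cohort(data=sub, annotations=self.annotations)


# ---------------------------------------------------------------------------
# Annotation and genotype I/O
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[SNPAnnotation]:
    """Read a SNP annotation CSV (snp_id, gene_label, allele_a, allele_b, risk_allele)."""
    df = pd.read_csv(path, dtype=str)
    required = {"snp_id", "gene_label", "allele_a", "allele_b", "risk_allele"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"annotation file missing column(s): {sorted(missing)}")
    return [
        SNPAnnotation(
            snp_id=r.snp_id,
            gene_label=r.gene_label,
            allele_a=r.allele_a,
            allele_b=r.allele_b,
            risk_allele=r.risk_allele,
        )
        for r in df.itertuples()
    ]


def normalize_call(call: object) -> float | str:
    """Normalize a diploid genotype call to alphabetical order ("TC" -> "CT").

    Anything that is not two alphabetic characters (empty strings, half calls
    like ``"C."``, None/NaN) is mapped to NaN = missing.
    """
    if call is None or (isinstance(call, float) and np.isnan(call)):
        return np.nan
    s = str(call).strip().upper().replace("/", "").replace("|", "")
    if len(s) != 2 or not s.isalpha():
        return np.nan
    return "".join(sorted(s))


def read_vcf_genotypes(path: str | Path, snp_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Read diploid GT calls from a VCF into a subject x SNP call table.

    Only the GT field is used; half calls and missing calls become NaN.
    Returns a DataFrame indexed by sample id with ``snp:<rsid>`` columns of
    normalized calls.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = set(snp_ids) if snp_ids is not None else None
    columns: dict[str, list[object]] = {}
    for variant in vcf:
        vid = variant.ID
        if vid is None or (wanted is not None and vid not in wanted):
            continue
        alleles = [variant.REF] + list(variant.ALT)
        calls: list[object] = []
        for gt in variant.genotypes:
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:  # half-calls or missing -> missing
                calls.append(np.nan)
            else:
                calls.append(normalize_call(alleles[a1] + alleles[a2]))
        columns[GENOTYPE_PREFIX + vid] = calls
    vcf.close()
    return pd.DataFrame(columns, index=pd.Index(samples, name="subject_id"))


# ---------------------------------------------------------------------------
# Cohort loading
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def load_cohort(
    phenotype_table: str | Path | pd.DataFrame,
    genotype_source: str | Path | None = None,
    annotations: Iterable[SNPAnnotation] | None = None,
) -> Cohort:
    """Load and validate a cohort from a phenotype table and genotype source.

    Validation is complete-case: rows failing a record-level invariant
    (missing BMI/age/sex, negative follow-up, incident case flagged in a
    prevalent case) are dropped and the count logged.  Structural problems
    (missing mandatory columns, subject-id mismatch with the VCF) are hard
    errors.
    """
    df = phenotype_table.copy() if isinstance(phenotype_table, pd.DataFrame) else _read_table(phenotype_table)

    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortError(f"phenotype table missing mandatory column(s): {missing_cols}")

    ann = {a.snp_id: a for a in annotations} if annotations else {}

    if genotype_source is not None:
        gpath = str(genotype_source)
        if gpath.endswith((".vcf", ".vcf.gz")):
            geno = read_vcf_genotypes(gpath, snp_ids=list(ann) or None)
        else:
            gdf = _read_table(gpath)
            if "subject_id" not in gdf.columns:
                raise CohortError("genotype table missing 'subject_id' column")
            geno = gdf.set_index("subject_id")
            geno.columns = [
                c if c.startswith(GENOTYPE_PREFIX) else GENOTYPE_PREFIX + c
                for c in geno.columns
            ]
        unknown = set(df["subject_id"].astype(str)) ^ set(geno.index.astype(str))
        if unknown:
            raise CohortError(
                f"subject ids do not match between phenotype and genotype files: {sorted(unknown)[:10]}"
            )
        geno.index = geno.index.astype(str)
        df = df.assign(subject_id=df["subject_id"].astype(str)).merge(
            geno, left_on="subject_id", right_index=True, how="left"
        )

    geno_cols = [c for c in df.columns if c.startswith(GENOTYPE_PREFIX)]
    for c in geno_cols:
        df[c] = df[c].map(normalize_call)

    n_in = len(df)
    keep = df["bmi"].notna() & df["age"].notna() & df["sex"].notna()
    keep &= ~(df["followup_years"].fillna(0) < 0)
    # an incident event in a prevalent case is contradictory
    keep &= ~(df["t2d_incident"].astype(bool) & df["t2d_prevalent"].astype(bool))
    # prevalence-free subjects must carry usable follow-up
    free = ~df["t2d_prevalent"].astype(bool)
    keep &= ~(free & (df["followup_years"].isna() | (df["followup_years"] <= 0)))
    dropped = int(n_in - keep.sum())
    if dropped:
        logger.info("load_cohort: dropped %d of %d rows failing validation", dropped, n_in)
    df = df[keep].reset_index(drop=True)

    derived = df["bmi"] >= OBESITY_BMI_THRESHOLD
    if "obesity" in df.columns:
        conflicts = int((df["obesity"].astype(bool) != derived).sum())
        if conflicts:
            logger.warning(
                "load_cohort: %d supplied obesity flags conflict with BMI>=30 rule; overridden",
                conflicts,
            )
    df["obesity"] = derived
    df["t2d_prevalent"] = df["t2d_prevalent"].astype(bool)
    df["t2d_incident"] = df["t2d_incident"].astype(bool)
    return Cohort(data=df, annotations=ann)


# ---------------------------------------------------------------------------
# Genotype coding
# ---------------------------------------------------------------------------

def code_genotype(call: object, ann: SNPAnnotation, scheme: str = "additive"):
    """Numerically code one genotype call under the given genetic model.

    additive   -> count of risk alleles in {0, 1, 2}
    recessive  -> 1 iff homozygous for the risk allele, else 0
    codominant -> (het indicator, hom-risk indicator); the homozygous
                  non-risk genotype is the (0, 0) reference
    Missing calls propagate as NaN (a NaN pair for codominant).
    """
    norm = normalize_call(call)
    if isinstance(norm, float) and np.isnan(norm):
        return (np.nan, np.nan) if scheme == "codominant" else np.nan
    dose = norm.count(ann.risk_allele)
    if scheme == "additive":
        return dose
    if scheme == "recessive":
        return int(dose == 2)
    if scheme == "codominant":
        return (int(dose == 1), int(dose == 2))
    raise ValueError(f"unknown coding scheme {scheme!r}")


def additive_codes(cohort: Cohort, snp_id: str) -> pd.Series:
    """Risk-allele dosage (0/1/2, NaN missing) for every subject."""
    ann = cohort.annotations[snp_id]
    return cohort.genotype_calls(snp_id).map(
        lambda c: code_genotype(c, ann, "additive")
    ).astype(float)


def genotype_counts(cohort: Cohort, snp_id: str) -> GenotypeCounts:
    codes = additive_codes(cohort, snp_id).dropna()
    return GenotypeCounts(
        n_homref=int((codes == 0).sum()),
        n_het=int((codes == 1).sum()),
        n_homalt=int((codes == 2).sum()),
    )


def genotype_frequencies(counts: GenotypeCounts) -> dict[str, float]:
    """Genotype percentages and the risk-allele frequency.

    Percentages refer to (hom non-risk, het, hom risk) and sum to 100 before
    rounding; the allele frequency is (n_het + 2 n_homalt) / (2 total).
    """
    total = counts.total
    if total <= 0:
        raise CohortError("genotype_frequencies: zero genotyped subjects")
    return {
        "pct_homref": 100.0 * counts.n_homref / total,
        "pct_het": 100.0 * counts.n_het / total,
        "pct_homalt": 100.0 * counts.n_homalt / total,
        "allele_freq": (counts.n_het + 2 * counts.n_homalt) / (2.0 * total),
    }


def hwe_test(counts: GenotypeCounts) -> tuple[float, float]:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    Expected counts derive from the estimated allele frequency; a monomorphic
    SNP is in trivial equilibrium (statistic 0, p = 1).  Used as the
    genotyping quality gate before any association analysis.
    """
    total = counts.total
    if total <= 0:
        raise CohortError("hwe_test: zero genotyped subjects")
    p = (counts.n_het + 2 * counts.n_homalt) / (2.0 * total)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    q = 1.0 - p
    expected = np.array([q * q, 2 * p * q, p * p]) * total
    observed = np.array([counts.n_homref, counts.n_het, counts.n_homalt], dtype=float)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))
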