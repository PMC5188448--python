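"""GRS screening, partition rule, additive scoring, and AUC oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import obgrs
from obgrs.grs import (DEFAULT_ALPHA_IN, compute_grs, grs_association,
                       partition_snps, roc_auc, screen_snps)
from obgrs.simulate import (NOB_SET, OB_SET, confined_effects_config,
                            simulate_cohort)

NOB_EXPECTED = ["rs7903146", "rs12899811", "rs11634397", "rs11257655", "rs163184"]
OB_EXPECTED = ["rs6798189", "rs4402960", "rs3802177", "rs10842994", "rs2261181"]


def screen_row(snp, stratum, p, or_=1.2, n=500):
    return {"snp_id": snp, "stratum": stratum, "n": n, "or_per_allele": or_, "p_value": p}


def make_screen_table(p_by_snp):
    """p_by_snp: {snp: (p_nonobese, p_obese)}."""
    rows = []
    for snp, (p_nob, p_ob) in p_by_snp.items():
        rows.append(screen_row(snp, "all", min(p_nob, p_ob)))
        rows.append(screen_row(snp, "non-obese", p_nob))
        rows.append(screen_row(snp, "obese", p_ob))
    return pd.DataFrame(rows)


class TestPartition:
    def test_reference_pattern_reproduced(self):
        """A screen table with the canonical stratum pattern yields the two
        five-SNP obesity-specific sets."""
        table = make_screen_table(
            {**{s: (0.01, 0.5) for s in NOB_EXPECTED}, **{s: (0.5, 0.01) for s in OB_EXPECTED}}
        )
        part = partition_snps(table)
        assert sorted(part.nob_set) == sorted(NOB_EXPECTED)
        assert sorted(part.ob_set) == sorted(OB_EXPECTED)
        assert part.excluded == []

    def test_nonsignificant_everywhere_excluded(self):
        part = partition_snps(make_screen_table({"rs7903146": (0.5, 0.5)}))
        assert part.nob_set == [] and part.ob_set == []
        assert part.excluded[0][0] == "rs7903146"

    def test_obese_only_signal_joins_ob_set(self):
        part = partition_snps(make_screen_table({"rs4402960": (0.4, 0.02)}))
        assert part.ob_set == ["rs4402960"]

    def test_threshold_is_strict(self):
        part = partition_snps(make_screen_table({"rs1": (DEFAULT_ALPHA_IN, 0.9)}))
        assert part.nob_set == []

    def test_sets_are_disjoint(self):
        rng = np.random.default_rng(4)
        table = make_screen_table(
            {f"rs{i}": tuple(rng.random(2) * 0.2) for i in range(20)}
        )
        part = partition_snps(table)
        assert set(part.nob_set).isdisjoint(part.ob_set)


class TestScreening:
    def test_stratum_confined_effect_ranks_p_correctly(self):
        """Effects confined to the obese stratum screen smaller p there."""
        cfg = confined_effects_config(per_allele_or=1.6, n_subjects=1200, n_centers=1)
        wins = 0
        reps = 40
        for seed in range(reps):
            cohort = simulate_cohort(cfg, seed=300 + seed)
            tab = screen_snps(cohort, ["rs4402960"])  # obese-confined SNP
            by = tab.set_index("stratum")["p_value"]
            wins += by["obese"] < by["non-obese"]
        assert wins / reps >= 0.9

    def test_monomorphic_snp_flagged_others_returned(self, tcf7l2):
        from conftest import make_phenotype_frame
        from obgrs.cohort import SNPAnnotation, load_cohort
        rng = np.random.default_rng(6)
        n = 200
        mono = SNPAnnotation("rs000", "GENE", "A", "G", "G")
        df = make_phenotype_frame(
            n,
            genotypes={
                "rs7903146": rng.choice(["CC", "CT", "TT"], n),
                "rs000": ["AA"] * n,
            },
            bmi=rng.normal(30, 4, n).round(1),
            t2d_prevalent=rng.random(n) < 0.5,
            sex=rng.choice(["male", "female"], n),
            age=rng.normal(67, 6, n).round(1),
        )
        cohort = load_cohort(df, annotations=[tcf7l2, mono])
        tab = screen_snps(cohort)
        mono_rows = tab[tab.snp_id == "rs000"]
        other_rows = tab[tab.snp_id == "rs7903146"]
        assert mono_rows["p_value"].isna().all()
        assert other_rows["p_value"].notna().all()


class TestScoring:
    @pytest.fixture()
    def cohort10(self):
        return simulate_cohort(confined_effects_config(n_subjects=400), seed=44)

    def test_extreme_scores(self, tcf7l2):
        from conftest import make_phenotype_frame
        from obgrs.cohort import load_cohort
        df = make_phenotype_frame(2, genotypes={"rs7903146": ["CC", "TT"]})
        cohort = load_cohort(df, annotations=[tcf7l2])
        s = compute_grs(cohort, ["rs7903146"])
        assert s.tolist() == [0.0, 2.0]

    def test_additivity_over_disjoint_sets(self, cohort10):
        a = compute_grs(cohort10, NOB_SET)
        b = compute_grs(cohort10, OB_SET)
        both = compute_grs(cohort10, NOB_SET + OB_SET)
        pd.testing.assert_series_equal(a + b, both, check_names=False)

    def test_permutation_invariance(self, cohort10):
        fwd = compute_grs(cohort10, list(NOB_SET))
        rev = compute_grs(cohort10, list(NOB_SET)[::-1])
        pd.testing.assert_series_equal(fwd, rev)

    def test_score_range(self, cohort10):
        s = compute_grs(cohort10, NOB_SET)
        assert s.between(0, 2 * len(NOB_SET)).all()

    def test_missing_member_genotype_gives_missing_score(self, tcf7l2):
        from conftest import make_phenotype_frame
        from obgrs.cohort import SNPAnnotation, load_cohort
        ann2 = SNPAnnotation("rs163184", "KCNQ1", "T", "G", "G")
        df = make_phenotype_frame(
            2, genotypes={"rs7903146": ["CC", "CT"], "rs163184": ["GG", None]}
        )
        cohort = load_cohort(df, annotations=[tcf7l2, ann2])
        s = compute_grs(cohort, ["rs7903146", "rs163184"])
        assert s.iloc[0] == 2.0 and np.isnan(s.iloc[1])

    def test_unannotated_snp_is_hard_error(self, cohort10):
        with pytest.raises(KeyError):
            compute_grs(cohort10, ["rs_unknown"])


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert r.auc == 1.0

    def test_constant_score_all_ties(self):
        r = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_hand_counted_example(self):
        # cases {3,5}, controls {2,3}: pairs (3>2)=1, (3=3)=0.5, (5>2)=1, (5>3)=1
        r = roc_auc([3, 5, 2, 3], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.875)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        scores=st.lists(st.integers(0, 10), min_size=2, max_size=50),
        flips=st.data(),
    )
    def test_equals_exhaustive_pair_counting(self, scores, flips):
        """Exhaustive oracle on all inputs up to n=50."""
        y = flips.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        y = np.array(y)
        if y.sum() in (0, len(y)):
            y[0], y[-1] = 0, 1
        s = np.array(scores, dtype=float)
        cases, controls = s[y == 1], s[y == 0]
        pairs = sum(
            1.0 if c > k else 0.5 if c == k else 0.0
            for c in cases for k in controls
        )
        expected = pairs / (len(cases) * len(controls))
        assert roc_auc(s, y).auc == pytest.approx(expected, abs=1e-12)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(15)
        s = rng.integers(0, 10, 80).astype(float)
        y = (rng.random(80) < 0.4).astype(int)
        assert roc_auc(s, y).auc == pytest.approx(1 - roc_auc(-s, y).auc)

    def test_curve_monotone(self):
        rng = np.random.default_rng(16)
        s = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(int)
        c = roc_auc(s, y).curve
        assert (c["fpr"].diff().dropna() >= 0).all()
        assert (c["tpr"].diff().dropna() >= 0).all()

    def test_one_class_is_error(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_p_value_against_mannwhitney(self):
        """Cross-check the normal-approximation p with scipy's asymptotic test."""
        from scipy import stats
        rng = np.random.default_rng(17)
        s = rng.integers(0, 11, 300).astype(float)
        y = (rng.random(300) < 0.45).astype(int)
        r = roc_auc(s, y)
        ref = stats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(18)
        s = rng.normal(size=200) + np.repeat([0.0, 0.8], 100)
        y = np.repeat([0, 1], 100)
        r = roc_auc(s, y, n_boot=200, seed=1)
        assert r.ci_low < r.auc < r.ci_high


class TestGRSAssociation:
    def test_stratum_confined_score_effect(self):
        """Non-obese-confined per-allele effects: the nobGRS association is
        stronger in non-obese than obese subjects in most replicates."""
        cfg = confined_effects_config(per_allele_or=1.3, n_subjects=1000, n_centers=1)
        wins = 0
        reps = 30
        for seed in range(reps):
            cohort = simulate_cohort(cfg, seed=600 + seed)
            score = compute_grs(cohort, NOB_SET)
            res = {a.stratum: a for a in grs_association(cohort, score)}
            wins += res["non-obese"].p_value < res["obese"].p_value
        assert wins / reps >= 0.8

    def test_null_score_or_near_one(self):
        from obgrs.simulate import null_effect_config
        cohort = simulate_cohort(null_effect_config(n_subjects=2000), seed=20)
        score = compute_grs(cohort, NOB_SET)
        res = {a.stratum: a for a in grs_association(cohort, score)}
        assert res["all"].ci_low < 1.0 < res["all"].ci_high

    def test_constant_score_is_error(self):
        from obgrs.simulate import null_effect_config
        from obgrs.association import DesignError
        cohort = simulate_cohort(null_effect_config(n_subjects=100), seed=21)
        with pytest.raises(DesignError):
            grs_association(cohort, pd.Series(3.0, index=cohort.data.index))
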