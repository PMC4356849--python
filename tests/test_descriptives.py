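"""Scale scoring, psychometrics, QC, cross-tabs, group comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

import ptstraj as pt
from ptstraj.descriptives import (compare_included_vs_dropped, crosstab_by_class,
                                  cronbach_alpha, genotype_qc, hwe_chi2_test,
                                  hwe_exact_test, median_split, score_cts,
                                  score_pcl, spearman_rge)


class TestScaleScoring:
    def test_pcl_extremes(self):
        total, flag = score_pcl([1] * 17)
        assert total == 17 and not flag
        total, flag = score_pcl([5] * 17)
        assert total == 85 and flag

    def test_pcl_boundary_rule_configurable(self):
        items = [3] * 10 + [2] * 7  # sums to 44
        total, flag = score_pcl(items)
        assert total == 44 and flag  # default: >= cut-off counts
        _, strict = score_pcl(items, strict_exceed=True)
        assert not strict  # 44 does not exceed 44

    def test_pcl_out_of_range_names_item(self):
        items = [1] * 17
        items[4] = 6
        with pytest.raises(ValueError, match="item 5"):
            score_pcl(items)

    def test_cts_examples(self):
        assert score_cts([0] * 6) == 0
        assert score_cts([4] * 6) == 24
        assert score_cts([1, 0, 2, 0, 0, 1]) == 4

    def test_cts_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_cts([0, 0, 5, 0, 0, 0])
        with pytest.raises(ValueError):
            score_cts([0, 0, -1, 0, 0, 0])

    def test_fuzzed_scores_respect_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pcl = rng.integers(1, 6, size=17)
            total, _ = score_pcl(pcl)
            assert 17 <= total <= 85
            cts = rng.integers(0, 5, size=6)
            assert 0 <= score_cts(cts) <= 24


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        # parallel items (equal variance, correlation 1) give alpha = 1
        x = np.arange(10, dtype=float)
        X = np.column_stack([x, x + 1, x - 2])
        assert cronbach_alpha(X) == pytest.approx(1.0, abs=1e-10)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20000, 2))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_hand_matrix_matches_direct_arithmetic(self):
        X = np.array([
            [1.0, 2.0, 3.0],
            [2.0, 3.0, 3.0],
            [3.0, 4.0, 5.0],
            [4.0, 4.0, 6.0],
        ])
        k = 3
        item_vars = X.var(axis=0, ddof=1).sum()
        total_var = X.sum(axis=1).var(ddof=1)
        expected = k / (k - 1) * (1 - item_vars / total_var)
        assert cronbach_alpha(X) == pytest.approx(expected, abs=1e-12)

    def test_zero_total_variance_undefined(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((5, 3)))


class TestSpearman:
    def test_strictly_monotone_pair(self):
        rho, _ = spearman_rge([0, 1, 2, 3, 4, 5], [2, 4, 6, 8, 10, 12])
        assert rho == pytest.approx(1.0)

    def test_ties_use_midranks(self):
        # dosage vectors are heavily tied; midranks keep |rho| < 1
        rho, _ = spearman_rge([0, 0, 1, 1, 2, 2], [1, 2, 3, 4, 5, 6])
        assert 0.9 < rho < 1.0

    def test_untied_example_matches_rank_formula(self):
        # ranks of y are (3, 1, 2, 5, 4); d = (-2, 1, 1, -1, 1), sum d^2 = 8
        # rho = 1 - 6*8/(5*(25-1)) = 0.6  (classical rank-difference formula)
        rho, _ = spearman_rge([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert rho == pytest.approx(1 - 6 * 8 / (5 * 24), abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(ValueError):
            spearman_rge([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_rge([0, 1, 2], [1, 2, 3])


def _hwe_oracle(n_hom_minor, n_het, n_hom_major):
    """Exact-fraction enumeration oracle using math.comb directly on the
    conditional distribution of the heterozygote count."""
    from fractions import Fraction

    n = n_hom_minor + n_het + n_hom_major
    nm = 2 * n_hom_minor + n_het
    nm = min(nm, 2 * n - nm)
    probs = {}
    total = Fraction(0)
    for h in range(nm % 2, nm + 1, 2):
        a = (nm - h) // 2
        b = n - a - h
        if b < 0:
            continue
        # multinomial count of genotype configurations x 2^h allele phasings
        w = Fraction(2**h * math.factorial(n),
                     math.factorial(a) * math.factorial(h) * math.factorial(b))
        probs[h] = w
        total += w
    obs = probs[n_het]
    return float(sum(w for w in probs.values() if w <= obs) / total)


class TestHWE:
    def test_four_het_example(self):
        # AA=0, Aa=4, aa=0: enumeration over h in {0,2,4}
        assert hwe_exact_test(0, 4, 0) == pytest.approx(0.3143, abs=2e-4)

    def test_matches_enumeration_oracle_all_small_tables(self):
        for n in range(1, 21):
            for a in range(n + 1):
                for h in range(n - a + 1):
                    b = n - a - h
                    p = hwe_exact_test(a, h, b)
                    q = _hwe_oracle(a, h, b)
                    assert p == pytest.approx(q, abs=1e-9), (a, h, b)

    def test_agrees_with_chi_square_at_large_n(self):
        # near-equilibrium tables at n >= 500
        for (a, h, b) in [(45, 210, 245), (80, 240, 180), (20, 160, 320)]:
            exact = hwe_exact_test(a, h, b)
            approx = hwe_chi2_test(a, h, b)
            assert abs(exact - approx) < 0.02


class TestGenotypeQC:
    def test_low_call_rate_fails(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, size=200).astype(float)
        d[:20] = np.nan  # 10% missing
        _, kept, report = genotype_qc(d[:, None], ["s1"])
        assert kept == []
        assert "call rate" in report.loc[0, "reason"]

    def test_monomorphic_dropped_for_maf(self):
        d = np.zeros((100, 1))
        _, kept, report = genotype_qc(d, ["s1"])
        assert kept == []
        assert report.loc[0, "maf"] == 0.0
        assert "MAF" in report.loc[0, "reason"]

    def test_maf_matches_counting_oracle(self):
        # 6 het + 2 hom-minor among 20 called: maf = (6 + 4) / 40 = 0.25
        d = np.array([2.0] * 2 + [1.0] * 6 + [0.0] * 12)
        _, kept, report = genotype_qc(d[:, None], ["s1"])
        assert report.loc[0, "maf"] == pytest.approx(0.25)
        assert kept == ["s1"]

    def test_hwe_violation_dropped(self):
        # all heterozygotes: extreme disequilibrium at large n
        d = np.ones(3000)
        _, kept, report = genotype_qc(d[:, None], ["s1"])
        assert kept == []
        assert "HWE" in report.loc[0, "reason"]


class TestCrosstabs:
    def test_hand_counts_to_percentages(self):
        labels = np.array(["high"] * 31 + ["low"] * 10)
        dosages = np.array([0.0] * 18 + [1.0] * 13 + [0.0] * 10)
        tab = crosstab_by_class(labels, dosages, class_order=["high", "low"])
        row = tab[tab["class"] == "high"].iloc[0]
        assert row["n"] == 31
        assert row["pct_dose0"] == pytest.approx(58.1, abs=0.05)
        assert row["pct_dose1"] == pytest.approx(41.9, abs=0.05)
        assert row["pct_dose2"] == 0.0

    def test_all_reference_dosage(self):
        labels = np.array(["a", "a", "b", "b"])
        tab = crosstab_by_class(labels, np.zeros(4))
        assert np.all(tab["pct_dose0"] == 100.0)
        assert np.all(tab[["pct_dose1", "pct_dose2"]] == 0.0)

    def test_rows_sum_to_hundred_and_rebuild_from_counts(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["w", "x", "y"], size=200)
        dosages = rng.binomial(2, 0.2, size=200).astype(float)
        tab = crosstab_by_class(labels, dosages)
        pct = tab[["pct_dose0", "pct_dose1", "pct_dose2"]].sum(axis=1)
        np.testing.assert_allclose(pct, 100.0, atol=1e-9)
        rebuilt = 100 * tab[["n_dose0", "n_dose1", "n_dose2"]].to_numpy() \
            / tab["n"].to_numpy()[:, None]
        np.testing.assert_allclose(
            rebuilt, tab[["pct_dose0", "pct_dose1", "pct_dose2"]], atol=1e-9
        )

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(4)
        labels = rng.choice(["w", "x"], size=100)
        dosages = rng.binomial(2, 0.3, size=100).astype(float)
        perm = rng.permutation(100)
        a = crosstab_by_class(labels, dosages)
        b = crosstab_by_class(labels[perm], dosages[perm])
        pd.testing.assert_frame_equal(a, b)

    def test_median_split_assigns_ties_to_low(self):
        strata = median_split([0, 1, 2, 2, 5, 9])
        # median = 2; exact-median values belong to the low stratum
        assert list(strata) == ["low", "low", "low", "low", "high", "high"]

    def test_stratified_tables(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(["w", "x"], size=300)
        dosages = rng.binomial(2, 0.2, size=300).astype(float)
        abuse = rng.integers(0, 10, size=300)
        out = crosstab_by_class(labels, dosages, stratifier=abuse)
        assert set(out) == {"low", "high"}
        n_total = out["low"]["n"].sum() + out["high"]["n"].sum()
        assert n_total == 300


class TestGroupComparison:
    def test_identical_groups_not_flagged(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=400)
        df = pd.DataFrame({"v": x, "c": rng.integers(0, 2, size=400)})
        mask = np.arange(400) < 200
        out = compare_included_vs_dropped(
            df, mask, {"v": "continuous", "c": "categorical"}
        )
        assert not out["significant"].any()

    def test_shifted_variable_flagged(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(1.0, 1, 200), rng.normal(0.0, 1, 200)])
        df = pd.DataFrame({"v": x})
        mask = np.arange(400) < 200
        out = compare_included_vs_dropped(df, mask, {"v": "continuous"})
        assert bool(out.loc[0, "significant"])
        assert out.loc[0, "test"] == "welch_t"

    def test_degenerate_group_skipped(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        out = compare_included_vs_dropped(df, [True, True, True],
                                          {"v": "continuous"})
        assert "skipped" in out.loc[0, "note"]
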