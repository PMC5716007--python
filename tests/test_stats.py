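"""Chi-squared tests, multiple-testing corrections, and p-value bounds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import cohortaf as ca
from cohortaf.stats import (
    DEPLETED,
    ENRICHED,
    benjamini_hochberg,
    bound_pvalues,
    chi2_goodness_of_fit,
    chi2_two_sample,
    exact_binomial_check,
)


def _brute_gof(rare, total, q):
    obs = np.array([rare, total - rare], dtype=float)
    exp = np.array([q * total, (1 - q) * total])
    return float(((obs - exp) ** 2 / exp).sum())


class TestGoodnessOfFit:
    def test_strong_enrichment_worked_example(self):
        # 44 heterozygous carriers out of 44 individuals (88 alleles)
        # against a population frequency of 8%
        chi2, p = chi2_goodness_of_fit(44, 88, 0.08)
        assert chi2 == pytest.approx(_brute_gof(44, 88, 0.08), abs=1e-10)
        assert chi2 == pytest.approx(210.913, abs=1e-3)
        assert p == sps.chi2.sf(chi2, 1)

    def test_observed_equals_expected_gives_zero(self):
        chi2, p = chi2_goodness_of_fit(16, 200, 0.08)
        assert chi2 == 0.0
        assert p == 1.0

    def test_depletion_closed_form(self):
        chi2, _ = chi2_goodness_of_fit(0, 200, 0.5)
        assert chi2 == pytest.approx(200.0)

    def test_agrees_with_brute_force_on_random_tables(self):
        rng = np.random.default_rng(12)
        totals = rng.integers(2, 5000, size=10_000)
        rares = rng.integers(0, totals + 1)
        qs = rng.uniform(0.001, 0.999, size=10_000)
        chi2, _ = chi2_goodness_of_fit(rares, totals, qs)
        brute = np.array([_brute_gof(r, t, q) for r, t, q in zip(rares, totals, qs)])
        assert np.max(np.abs(chi2 - brute) / np.maximum(1.0, brute)) < 1e-10


class TestTwoSample:
    def test_matches_scipy_contingency_without_yates(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            ta, tb = rng.integers(10, 400, size=2)
            ra = rng.integers(1, ta)
            rb = rng.integers(1, tb)
            chi2, p = chi2_two_sample(ra, ta, rb, tb)
            table = [[ra, ta - ra], [rb, tb - rb]]
            ref = sps.chi2_contingency(table, correction=False)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_margin_gives_null_result(self):
        chi2, p = chi2_two_sample(0, 100, 0, 100)
        assert chi2 == 0.0
        assert p == 1.0

    def test_converges_to_goodness_of_fit_for_huge_catalogue(self):
        # with a million catalogued alleles the 2x2 test and the fixed-q
        # test should agree to within 1%
        q = 0.08
        an = 1_000_000
        _, p_gof = chi2_goodness_of_fit(44, 200, q)
        _, p_two = chi2_two_sample(44, 200, round(q * an), an)
        assert np.log(p_two) == pytest.approx(np.log(p_gof), rel=0.01)


class TestChi2VsCatalogue:
    def _freqs(self, rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "rare_allele", "rare_count", "allele_total",
                     "n_unknown_alleles", "freq", "freq_lower", "freq_upper",
                     "untestable"],
        )

    def _cat(self, rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "snp_id", "ref_allele", "rare_allele",
                     "rare_freq", "allele_number", "source"],
        )

    def test_direction_and_statistic(self):
        freqs = self._freqs(
            [
                ("1", 100, "G", 44, 88, 0, 0.5, 0.5, 0.5, False),
                ("1", 200, "T", 0, 200, 0, 0.0, 0.0, 0.0, False),
            ]
        )
        cat = self._cat(
            [
                ("1", 100, "rs1", "A", "G", 0.08, 10_000, "pop"),
                ("1", 200, "rs2", "A", "T", 0.50, 10_000, "pop"),
            ]
        )
        out = ca.chi2_vs_catalogue(freqs, cat)
        assert out.loc[0, "direction"] == ENRICHED
        assert out.loc[0, "chi2"] == pytest.approx(210.913, abs=1e-3)
        assert out.loc[1, "direction"] == DEPLETED
        assert out.loc[1, "chi2"] == pytest.approx(200.0)

    def test_untestable_and_degenerate_q_excluded(self):
        freqs = self._freqs(
            [
                ("1", 100, "G", 0, 0, 4, np.nan, np.nan, np.nan, True),
                ("1", 200, "T", 1, 10, 0, 0.1, 0.1, 0.1, False),
            ]
        )
        cat = self._cat(
            [
                ("1", 100, "rs1", "A", "G", 0.2, None, "pop"),
                ("1", 200, "rs2", "A", "T", 1.0, None, "pop"),
            ]
        )
        out = ca.chi2_vs_catalogue(freqs, cat)
        assert out.empty

    def test_low_expected_flagged_not_dropped(self):
        freqs = self._freqs([("1", 100, "G", 2, 20, 0, 0.1, 0.1, 0.1, False)])
        cat = self._cat([("1", 100, "rs1", "A", "G", 0.01, None, "pop")])
        out = ca.chi2_vs_catalogue(freqs, cat)
        assert len(out) == 1
        assert out.loc[0, "low_expected"]  # expected rare cell = 0.2 < 1
        checked = exact_binomial_check(out)
        assert 0 < checked.loc[0, "p_exact"] <= 1

    def test_two_sample_mode_requires_allele_number(self):
        freqs = self._freqs([("1", 100, "G", 2, 20, 0, 0.1, 0.1, 0.1, False)])
        cat = self._cat([("1", 100, "rs1", "A", "G", 0.1, None, "pop")])
        with pytest.raises(ValueError, match="allele_number"):
            ca.chi2_vs_catalogue(freqs, cat, mode="two_sample")


class TestCorrections:
    def _results(self, p_values):
        return pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(len(p_values)),
                "rare_allele": "G",
                "p_raw": p_values,
            }
        )

    def test_bonferroni_over_catalogue_sized_denominator(self):
        out = ca.correct_pvalues(self._results([1.2e-47]), m=121_000)
        assert out.loc[0, "p_bonferroni"] == pytest.approx(1.452e-42, rel=1e-6)
        assert out.loc[0, "p_bonferroni"] < 1e-8
        assert out.loc[0, "significant"]

    def test_ceiling_at_one(self):
        out = ca.correct_pvalues(self._results([1.0, 0.5]))
        assert out["p_bonferroni"].max() == 1.0
        assert out["q_fdr"].max() == 1.0

    def test_bh_hand_example(self):
        # step-up over {0.001, 0.002, 0.03} with m=3:
        # ranks 1..3 give 0.003, 0.003, 0.03
        q = benjamini_hochberg(np.array([0.001, 0.002, 0.03]))
        assert q == pytest.approx([0.003, 0.003, 0.03])

    def test_bh_matches_statsmodels_when_m_equals_n(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=500) ** 3
        ours = benjamini_hochberg(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, ref)

    def test_bh_monotone_in_sorted_order(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200)
        q = benjamini_hochberg(p, m=500)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_bonferroni_significant_set_within_bh_set(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=300) ** 5
        out = ca.correct_pvalues(self._results(p), alpha=0.01)
        bonf = out["p_bonferroni"] < 0.01
        bh = out["q_fdr"] < 0.01
        assert (bonf & ~bh).sum() == 0

    def test_output_sorted_by_raw_p(self):
        out = ca.correct_pvalues(self._results([0.5, 0.001, 0.2]))
        assert list(out["p_raw"]) == sorted(out["p_raw"])

    def test_external_m_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg(np.array([0.1, 0.2]), m=1)

    def test_empty_input_gives_empty_output(self):
        out = ca.correct_pvalues(self._results([]))
        assert out.empty


class TestBoundPvalues:
    def test_no_unknowns_degenerate_range(self):
        _, p = chi2_goodness_of_fit(3, 20, 0.1)
        lo, hi = bound_pvalues(3, 20, 0, 0.1)
        assert lo == pytest.approx(float(p))
        assert hi == pytest.approx(float(p))

    def test_derived_extreme_tables(self):
        # 3 rare of 16 observed alleles plus 4 unknown, q = 0.1: the
        # extremes are counts 3/20 and 7/20
        lo, hi = bound_pvalues(3, 16, 4, 0.1)
        _, p_all_common = chi2_goodness_of_fit(3, 20, 0.1)
        _, p_all_rare = chi2_goodness_of_fit(7, 20, 0.1)
        assert lo == pytest.approx(float(min(p_all_common, p_all_rare)))
        assert hi >= max(float(p_all_common), float(p_all_rare))

    def test_upper_bound_below_one_when_all_rare_overshoots(self):
        # cohort frequency already at q: pushing every unknown allele to
        # rare moves the test away from the null in the other direction
        lo, hi = bound_pvalues(2, 20, 6, 0.1)
        assert hi <= 1.0
        _, p_overshoot = chi2_goodness_of_fit(8, 26, 0.1)
        assert lo <= float(p_overshoot)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        rare=st.integers(0, 30),
        extra=st.integers(0, 30),
        unknown=st.integers(0, 6),
        q=st.floats(0.01, 0.99),
    )
    def test_brackets_every_intermediate_allocation(self, rare, extra, unknown, q):
        """Exhaustive check: every allocation of <=6 unknown alleles yields
        a p-value inside the reported range."""
        total = rare + extra
        if total == 0:
            return
        lo, hi = bound_pvalues(rare, total, unknown, q)
        for j in range(unknown + 1):
            _, p = chi2_goodness_of_fit(rare + j, total + unknown, q)
            assert lo - 1e-12 <= float(p) <= hi + 1e-12

    def test_pipeline_reports_bounds_only_with_unknowns(self):
        freqs = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "pos": [100, 200],
                "rare_allele": ["G", "T"],
                "rare_count": [3, 5],
                "allele_total": [16, 20],
                "n_unknown_alleles": [4, 0],
                "freq": [3 / 16, 0.25],
                "freq_lower": [3 / 20, 0.25],
                "freq_upper": [7 / 20, 0.25],
                "untestable": [False, False],
            }
        )
        cat = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "pos": [100, 200],
                "snp_id": ["rs1", "rs2"],
                "ref_allele": ["A", "A"],
                "rare_allele": ["G", "T"],
                "rare_freq": [0.1, 0.1],
                "allele_number": [None, None],
                "source": ["pop", "pop"],
            }
        )
        out = ca.chi2_vs_catalogue(freqs, cat).set_index("pos")
        assert np.isfinite(out.loc[100, "p_raw_lower"])
        assert np.isfinite(out.loc[100, "p_raw_upper"])
        assert np.isnan(out.loc[200, "p_raw_lower"])
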