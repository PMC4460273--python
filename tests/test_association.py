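import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import multivariate_hypergeom

from genassoc.association import (
    EffectEstimate,
    Z975,
    fisher_exact_2x3,
    genotype_odds_ratios,
    read_summary_studies,
    se_from_ci,
    se_from_pvalue,
)
from genassoc.counts import GenotypeCountTable

positive_counts = st.tuples(
    st.integers(1, 200), st.integers(1, 200), st.integers(1, 200)
)


class TestGenotypeOddsRatios:
    def test_published_amd_table(self, leeds):
        ag, aa = genotype_odds_ratios(leeds)
        assert (round(ag.or_, 2), round(ag.ci_low, 2), round(ag.ci_high, 2)) == (1.07, 0.84, 1.36)
        assert (round(aa.or_, 2), round(aa.ci_low, 2), round(aa.ci_high, 2)) == (1.56, 0.91, 2.67)
        # printed AA p-value 0.11 is the Wald two-sided p
        assert aa.p == pytest.approx(0.108, abs=2e-3)
        assert aa.beta == pytest.approx(math.log(16 * 2574 / (115 * 230)), rel=1e-12)
        assert aa.se == pytest.approx(math.sqrt(1 / 16 + 1 / 115 + 1 / 230 + 1 / 2574), rel=1e-12)

    def test_identical_rows_give_null_effect(self):
        t = GenotypeCountTable("id", (50, 30, 10), (50, 30, 10))
        ag, aa = genotype_odds_ratios(t)
        assert ag.beta == pytest.approx(0.0, abs=1e-12)
        assert aa.or_ == pytest.approx(1.0, rel=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        t = GenotypeCountTable("z", (10, 5, 0), (10, 5, 5))
        _, aa = genotype_odds_ratios(t, zero_cell="haldane")
        # hand cross-product after adding 0.5 to the four AA-vs-GG cells
        assert aa.or_ == pytest.approx((0.5 * 10.5) / (5.5 * 10.5), rel=1e-12)

    def test_zero_cell_policy_none_raises(self):
        t = GenotypeCountTable("z", (10, 5, 0), (10, 5, 5))
        with pytest.raises(ValueError, match="zero cell"):
            genotype_odds_ratios(t, zero_cell="none")

    @given(case=positive_counts, control=positive_counts)
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_swapping_rows_negates_beta_preserves_se(self, case, control):
        t = GenotypeCountTable("a", case, control)
        s = GenotypeCountTable("a", control, case)
        for e1, e2 in zip(genotype_odds_ratios(t), genotype_odds_ratios(s)):
            assert e1.beta == pytest.approx(-e2.beta, rel=1e-12, abs=1e-12)
            assert e1.se == pytest.approx(e2.se, rel=1e-12)

    @given(case=positive_counts, control=positive_counts)
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_effect_estimate_invariants(self, case, control):
        t = GenotypeCountTable("a", case, control)
        for est in genotype_odds_ratios(t):
            assert est.or_ == pytest.approx(math.exp(est.beta), rel=1e-12)
            assert est.ci_low < est.or_ < est.ci_high
            # CI log-symmetric about the estimate
            assert math.log(est.ci_high) - math.log(est.or_) == pytest.approx(
                math.log(est.or_) - math.log(est.ci_low), abs=1e-9
            )
            # se recovered exactly from the unrounded CI
            assert se_from_ci(est.or_, est.ci_low, est.ci_high) == pytest.approx(est.se, rel=1e-9)


class TestWaldP:
    def test_monotone_decreasing_in_z(self):
        zs = np.linspace(0.1, 5, 30)
        ps = [EffectEstimate.from_beta_se("AA_vs_GG", z * 0.3, 0.3).p for z in zs]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestFisherExact2x3:
    def test_published_table_p(self, leeds):
        # frozen against R's fisher.test (0.2449897); prints as 0.25 at 2 dp
        assert fisher_exact_2x3(leeds) == pytest.approx(0.2449897, abs=1e-6)

    def test_two_attainable_tables_tie(self):
        t = GenotypeCountTable("t", (1, 0, 0), (0, 1, 0))
        assert fisher_exact_2x3(t) == pytest.approx(1.0)

    def test_matches_brute_force_oracle_on_small_tables(self):
        # oracle: direct summation of multivariate-hypergeometric pmfs over
        # every table with the observed margins, independent of the
        # log-factorial production path
        def oracle(table):
            cols = tuple(c + d for c, d in zip(table.case_counts, table.control_counts))
            n1 = sum(table.case_counts)
            p_obs = multivariate_hypergeom.pmf(table.case_counts, cols, n1)
            total = 0.0
            for a0 in range(min(cols[0], n1) + 1):
                for a1 in range(min(cols[1], n1 - a0) + 1):
                    a2 = n1 - a0 - a1
                    if 0 <= a2 <= cols[2]:
                        p = multivariate_hypergeom.pmf((a0, a1, a2), cols, n1)
                        if p <= p_obs * (1 + 1e-7):
                            total += p
            return total

        rng = np.random.default_rng(20130521)
        checked = 0
        while checked < 40:
            case = tuple(int(x) for x in rng.integers(0, 11, 3))
            ctrl = tuple(int(x) for x in rng.integers(0, 11, 3))
            if sum(case) == 0 or sum(ctrl) == 0:
                continue
            if any(case[j] + ctrl[j] == 0 for j in range(3)):
                continue
            t = GenotypeCountTable("r", case, ctrl)
            p = fisher_exact_2x3(t)
            assert 0.0 <= p <= 1.0
            assert p == pytest.approx(oracle(t), rel=1e-9, abs=1e-12)
            checked += 1

    def test_monte_carlo_fallback_tracks_enumeration(self, leeds):
        p_mc = fisher_exact_2x3(leeds, monte_carlo=True, n_mc=50_000, seed=1)
        assert p_mc == pytest.approx(fisher_exact_2x3(leeds), abs=0.01)

    def test_cell_budget_error_advises_fallback(self, leeds):
        with pytest.raises(ValueError, match="monte_carlo"):
            fisher_exact_2x3(leeds, max_cells=100)


class TestSeRecovery:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((1.56, 0.91, 2.67), 0.27459),  # printed AA CI; Woolf from counts is 0.27556
            ((3.03, 1.27, 7.23), 0.44368),
            ((1.0, 0.5, 2.0), math.log(2) / Z975),
        ],
    )
    def test_se_from_ci(self, args, expected):
        assert se_from_ci(*args) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "args, expected",
        [
            ((3.03, 0.01, "two-sided"), 0.43037),  # ln(3.03)/2.5758
            ((1.73, 0.005, "two-sided"), 0.19527),  # ln(1.73)/2.8070
            ((math.e, 0.3173, "two-sided"), 1.0),
        ],
    )
    def test_se_from_pvalue(self, args, expected):
        assert se_from_pvalue(*args) == pytest.approx(expected, abs=1e-3)

    def test_se_from_pvalue_rejects_null_or(self):
        with pytest.raises(ValueError):
            se_from_pvalue(1.0, 0.5)

    def test_se_from_ci_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            se_from_ci(-1.0, 0.5, 2.0)

    @given(beta=st.floats(-2, 2), se=st.floats(0.01, 2))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_ci_and_pvalue_round_trips(self, beta, se):
        est = EffectEstimate.from_beta_se("AA_vs_GG", beta, se)
        assert se_from_ci(est.or_, est.ci_low, est.ci_high) == pytest.approx(se, rel=1e-9)
        if abs(beta) > 1e-3 and est.p > 1e-300:
            assert se_from_pvalue(est.or_, est.p) == pytest.approx(se, rel=1e-6)


def test_read_summary_studies(tmp_path):
    path = tmp_path / "summ.tsv"
    path.write_text(
        "study_id\tcontrast\tor\tci_low\tci_high\tp\n"
        "s1\tAA_vs_GG\t3.03\t\t\t0.01\n"
        "s1\tAG_vs_GG\t1.06\t\t\t0.76\n"
        "s2\tAA_vs_GG\t1.56\t0.91\t2.67\t\n"
    )
    studies = read_summary_studies(path)
    assert studies["s1"]["AA_vs_GG"].se == pytest.approx(0.43037, abs=1e-4)
    assert studies["s2"]["AA_vs_GG"].se == pytest.approx(0.27459, abs=1e-4)
    assert studies["s1"]["AG_vs_GG"].or_ == pytest.approx(1.06)


def test_read_summary_studies_requires_ci_or_p(tmp_path):
    path = tmp_path / "summ.tsv"
    path.write_text("study_id\tcontrast\tor\tci_low\tci_high\tp\ns1\tAA_vs_GG\t3.03\t\t\t\n")
    with pytest.raises(ValueError, match="CI or a p-value"):
        read_summary_studies(path)
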