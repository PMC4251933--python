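from fractions import Fraction
from math import factorial

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from sexsnpscan.diffstats import (
    SiteStat,
    fisher_exact_2x2,
    site_fisher,
    site_fst,
    window_mean,
)
from sexsnpscan.pool_io import site_frequencies
from conftest import make_site


def oracle_fisher(a, b, c, d):
    """Independent brute force: enumerate every table with the observed
    margins, exact Fraction probabilities from the factorial formula, and
    sum those <= the observed table's probability."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        aa, bb, cc, dd = x, r1 - x, c1 - x, r2 - (c1 - x)
        if min(aa, bb, cc, dd) < 0:
            return None
        num = factorial(r1) * factorial(r2) * factorial(c1) * factorial(n - c1)
        den = (
            factorial(n)
            * factorial(aa)
            * factorial(bb)
            * factorial(cc)
            * factorial(dd)
        )
        return Fraction(num, den)

    p_obs = prob(a)
    return float(sum(p for x in range(0, c1 + 1) if (p := prob(x)) is not None and p <= p_obs))


class TestSiteFst:
    def test_identical_pools_zero(self):
        rec = make_site(male=(10, 10, 0, 0, 0, 0), female=(10, 10, 0, 0, 0, 0))
        assert site_fst(site_frequencies(rec)) == 0.0

    def test_fixed_difference_one(self):
        rec = make_site(male=(20, 0, 0, 0, 0, 0), female=(0, 20, 0, 0, 0, 0))
        assert site_fst(site_frequencies(rec)) == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # male 16:4, female 4:16, C=20 each:
        # pi_m = pi_f = (20/19)(1 - 0.8^2 - 0.2^2); pi_t = (40/39)(0.5)
        rec = make_site(male=(16, 4, 0, 0, 0, 0), female=(4, 16, 0, 0, 0, 0))
        assert site_fst(site_frequencies(rec)) == pytest.approx(0.3432, abs=1e-4)

    def test_monomorphic_undefined(self):
        rec = make_site(male=(20, 0, 0, 0, 0, 0), female=(20, 0, 0, 0, 0, 0))
        assert site_fst(site_frequencies(rec)) is None

    @pytest.mark.parametrize("male,female", [((1, 0, 0, 0, 0, 0), (10, 10, 0, 0, 0, 0)),
                                             ((10, 10, 0, 0, 0, 0), (0, 1, 0, 0, 0, 0))])
    def test_low_coverage_undefined(self, male, female):
        rec = make_site(male=male, female=female)
        assert site_fst(site_frequencies(rec)) is None

    def test_pool_swap_symmetry(self, random_sites):
        for rec in random_sites:
            swapped = make_site(
                pos=rec.pos, male=rec.counts_female, female=rec.counts_male
            )
            f1 = site_fst(site_frequencies(rec))
            f2 = site_fst(site_frequencies(swapped))
            if f1 is None:
                assert f2 is None
            else:
                assert f1 == pytest.approx(f2, abs=1e-12)

    def test_fst_in_unit_interval(self, random_sites):
        for rec in random_sites:
            f = site_fst(site_frequencies(rec))
            assert f is None or 0.0 <= f <= 1.0


class TestFisher:
    def test_identical_proportions_p_one(self):
        rec = make_site(male=(10, 10, 0, 0, 0, 0), female=(5, 5, 0, 0, 0, 0))
        assert site_fisher(rec) == pytest.approx(1.0)

    def test_worked_example_margins_10_10_by_15_5(self):
        # male A:5 T:5 vs female A:10 T:0 -> p = 2 * 3003 / 184756
        rec = make_site(male=(5, 5, 0, 0, 0, 0), female=(10, 0, 0, 0, 0, 0))
        assert site_fisher(rec) == pytest.approx(2 * 3003 / 184756, rel=1e-12)
        assert site_fisher(rec) == pytest.approx(0.03251, abs=5e-6)

    def test_two_table_support_p_one(self):
        # 1x1 margins: both tables have equal probability -> p = 1
        assert fisher_exact_2x2(1, 0, 0, 1) == pytest.approx(1.0)

    def test_zero_coverage_pool_skipped(self):
        rec = make_site(male=(5, 5, 0, 0, 0, 0), female=(0, 0, 0, 0, 2, 0))
        assert site_fisher(rec) is None

    def test_degenerate_row_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fisher_exact_2x2(0, 0, 3, 4)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_matches_independent_enumeration(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0:
            return
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            oracle_fisher(a, b, c, d), abs=1e-12
        )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_close_to_scipy(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0:
            return
        _, p = scipy_fisher([[a, b], [c, d]], alternative="two-sided")
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(p, abs=1e-7)

    def test_monotone_in_frequency_difference(self):
        # fixed margins (20, 20): moving male counts away from the female
        # proportion never increases p
        ps = [fisher_exact_2x2(10 + k, 10 - k, 10, 10) for k in range(0, 11)]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))


class TestWindowMean:
    def test_mean_within_window(self):
        stats = [SiteStat("LG1", 100, 0.2, None), SiteStat("LG1", 900, 0.4, None)]
        out = window_mean(stats, 1000)
        assert len(out) == 1
        assert out.loc[0, "mean_fst"] == pytest.approx(0.3)
        assert out.loc[0, "n_sites"] == 2

    def test_boundary_assignment(self):
        # [1..w] and [w+1..2w]
        stats = [SiteStat("LG1", 1000, 0.1, None), SiteStat("LG1", 1001, 0.5, None)]
        out = window_mean(stats, 1000)
        assert list(out["win_start"]) == [1, 1001]
        assert list(out["mean_fst"]) == [pytest.approx(0.1), pytest.approx(0.5)]

    def test_window_without_computable_stat_is_na(self):
        out = window_mean([SiteStat("LG1", 10, None, None)], 1000)
        assert out.loc[0, "n_sites"] == 1
        assert out.loc[0, "mean_fst"] != out.loc[0, "mean_fst"]  # NaN

    def test_unsorted_raises(self):
        stats = [SiteStat("LG1", 900, 0.2, None), SiteStat("LG1", 100, 0.4, None)]
        with pytest.raises(ValueError, match="sorted"):
            window_mean(stats, 1000)

    def test_bad_window_raises(self):
        with pytest.raises(ValueError):
            window_mean([], 0)
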