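"""Unit and property tests for the two-library Poisson exact test."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from esterscreen import dge

RATIOS = [Fraction(1, 3), Fraction(1, 2), Fraction(1), Fraction(2), Fraction(3)]


def libs_for(r: Fraction) -> tuple[int, int]:
    # n2/n1 == r with integer library sizes
    return (r.denominator * 600, r.numerator * 600)


class TestPoissonPmf:
    @pytest.mark.parametrize(
        "x, lam, expected",
        [
            (0, 0.0, 1.0),
            (0, 2.0, math.exp(-2)),
            (3, 2.0, math.exp(-2) * 8 / 6),
            (5, 0.0, 0.0),
        ],
    )
    def test_closed_form(self, x, lam, expected):
        assert dge.poisson_pmf(x, lam) == pytest.approx(expected, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            dge.poisson_pmf(-1, 2.0)
        with pytest.raises(ValueError):
            dge.poisson_pmf(1, -2.0)

    def test_large_count_no_overflow(self):
        # log-space contract: stays finite far beyond factorial overflow
        val = dge.poisson_pmf(10**6, 10**6)
        assert 0 < val < 1


class TestConditionalPmf:
    @pytest.mark.parametrize(
        "x, y, n1, n2, expected",
        [
            (0, 0, 1000, 1000, 0.5),
            (5, 5, 1000, 1000, 252 / 2048),
            (2, 3, 100, 200, 80 / 729),
        ],
    )
    def test_exact_values(self, x, y, n1, n2, expected):
        assert dge.ac_pmf(x, y, n1, n2) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("r", RATIOS)
    def test_matches_exact_rational_oracle(self, r):
        """Log-gamma pmf and cumulative vs arbitrary-precision rationals,
        relative error <= 1e-10 for all x, y <= 50."""
        n1, n2 = libs_for(r)
        ys = np.arange(51)
        for x in range(51):
            series = oracles.exact_pmf_series(x, 50, r)
            pmf = dge.ac_pmf(x, ys, n1, n2)
            cum = dge.ac_cumulative(x, ys, n1, n2)
            running = Fraction(0)
            for y in range(51):
                running += series[y]
                assert pmf[y] == pytest.approx(float(series[y]), rel=1e-10)
                assert cum[y] == pytest.approx(float(running), rel=1e-10)

    def test_normalises_to_one(self):
        """sum_y p(y|x) -> 1: adaptive tail cutoff, error < 1e-9 for x <= 100."""
        n1, n2 = 1000, 2000
        for x in range(0, 101, 5):
            # mean of the NB law is (x+1)*r; a generous multiple bounds the tail
            y_hi = int(20 * (x + 1) * (n2 / n1)) + 200
            total = dge.ac_pmf(x, np.arange(y_hi), n1, n2).sum()
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_no_overflow_at_huge_counts(self):
        val = dge.ac_pmf(5 * 10**6, 5 * 10**6, 10**7, 10**7)
        assert 0 < val < 1


class TestTwoSidedP:
    @pytest.mark.parametrize("x", [0, 1, 5, 17, 50])
    def test_equal_counts_equal_libs_give_exactly_one(self, x):
        assert dge.ac_two_sided_p(x, x, 1000, 1000) == 1.0

    def test_single_tail_doubling(self):
        assert dge.ac_two_sided_p(10, 0, 1000, 1000) == pytest.approx(2 / 2048, rel=1e-12)

    @pytest.mark.parametrize("r", RATIOS)
    def test_matches_exact_rational_oracle(self, r):
        n1, n2 = libs_for(r)
        for x in range(0, 51, 7):
            for y in range(0, 51, 7):
                expected = float(oracles.exact_two_sided(x, y, r))
                got = dge.ac_two_sided_p(x, y, n1, n2)
                if x == y and r == 1:
                    assert got == 1.0
                else:
                    assert got == pytest.approx(expected, rel=1e-9)

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_under_equal_libraries(self, x, y):
        p_xy = dge.ac_two_sided_p(x, y, 5000, 5000)
        p_yx = dge.ac_two_sided_p(y, x, 5000, 5000)
        assert p_xy == pytest.approx(p_yx, rel=1e-12)
        assert 0 < p_xy <= 1

    @pytest.mark.parametrize("x", [5, 40])
    def test_monotone_in_divergence(self, x):
        """p shrinks as y moves away from its conditional expectation."""
        n1 = n2 = 10_000
        up = [dge.ac_two_sided_p(x, y, n1, n2) for y in range(x, x + 30)]
        down = [dge.ac_two_sided_p(x, y, n1, n2) for y in range(x, -1, -1)]
        assert all(a >= b for a, b in zip(up, up[1:]))
        assert all(a >= b for a, b in zip(down, down[1:]))


class TestFoldChange:
    @pytest.mark.parametrize(
        "x, y, n1, n2, pc, expected",
        [
            (30, 10, 1000, 1000, 0.0, 3.0),
            (10, 10, 2000, 1000, 0.0, 0.5),
            (0, 10, 1000, 1000, 0.5, 0.5 / 10.5),
        ],
    )
    def test_normalised_ratio(self, x, y, n1, n2, pc, expected):
        assert dge.fold_change(x, y, n1, n2, pc) == pytest.approx(expected, rel=1e-12)

    def test_pseudocount_untouched_when_both_positive(self):
        # the zero-guard pseudocount must not shift well-observed genes
        assert dge.fold_change(30, 10, 1000, 1000, 0.5) == pytest.approx(3.0)

    def test_zero_count_zero_pseudocount_raises(self):
        with pytest.raises(ZeroDivisionError):
            dge.fold_change(0, 10, 1000, 1000, 0.0)


class TestBenjaminiHochberg:
    def test_single_p_identity(self):
        assert dge.benjamini_hochberg([0.05]) == pytest.approx([0.05])

    def test_stepup_with_monotone_pass(self):
        adj = dge.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        adj = dge.benjamini_hochberg([0.2] * 6)
        assert adj == pytest.approx([0.2] * 6)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_matches_textbook_stepup(self, ps):
        assert dge.benjamini_hochberg(ps) == pytest.approx(oracles.bh_stepup(ps))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dge.benjamini_hochberg([])


class TestTestLibrary:
    def test_calls_and_directions(self, small_counts):
        res = dge.test_library(small_counts, n1=100_000, n2=100_000)
        res = res.set_index("gene_id")
        assert res.loc["gA", "direction"] == "up"
        assert res.loc["gA", "is_de"]          # 3-fold, 300 vs 100 reads
        assert res.loc["gB", "direction"] == "down"
        assert res.loc["gB", "is_de"]
        assert not res.loc["gC", "is_de"]      # identical counts
        assert res.loc["gC", "p_two_sided"] == 1.0

    def test_exactly_twofold_is_not_de(self):
        counts = pd.DataFrame(
            {"gene_id": ["g"], "count_group1": [200], "count_group2": [100]}
        )
        res = dge.test_library(counts, n1=10_000, n2=10_000)
        assert res["fold_change"].iloc[0] == pytest.approx(2.0)
        assert not res["is_de"].iloc[0]

    def test_null_identity_table(self):
        counts = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "count_group1": [50] * 10,
                "count_group2": [50] * 10,
            }
        )
        res = dge.test_library(counts, n1=500, n2=500)
        assert not res["is_de"].any()
        assert (res["p_two_sided"] == 1.0).all()
        assert (res["direction"] == "none").all()

    def test_duplicate_gene_id_rejected(self):
        counts = pd.DataFrame(
            {"gene_id": ["g", "g"], "count_group1": [1, 2], "count_group2": [3, 4]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            dge.test_library(counts, n1=100, n2=100)

    def test_estimator_interface(self, small_counts):
        est = dge.AudicClaverieDE(alpha=0.01, n1=100_000, n2=100_000)
        assert est.get_params()["alpha"] == 0.01
        est.set_params(alpha=0.05).fit(small_counts)
        assert est.n1_ == 100_000
        assert list(est.results_.columns) == dge.RESULT_COLUMNS

    def test_fdr_off_uses_raw_p(self, small_counts):
        raw = dge.test_library(
            small_counts, 100_000, 100_000, dge.TestConfig(use_fdr=False, alpha=0.05)
        )
        # with only 5 genes FDR can flip borderline calls; raw-p mode
        # must gate on p_two_sided alone
        expect = (
            (raw["fold_change"] > 2) | (raw["fold_change"] < 0.5)
        ) & (raw["p_two_sided"] <= 0.05)
        assert (raw["is_de"] == expect).all()
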