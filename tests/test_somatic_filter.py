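"""Exact somatic test, germline-het qualification and category tallies."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from longclone.errors import UndefinedTestError
from longclone.somatic_filter import (
    fisher_somatic_test,
    flag_somatic,
    qualify_germline_het,
    tally_categories,
)
from longclone.types import Category, VariantRecord


def oracle_two_sided_p(ta, tr, na, nr):
    """Independent oracle: direct summation of the hypergeometric tail
    probabilities with exact rational arithmetic (fractions of comb counts)."""
    from fractions import Fraction

    r1, c1 = ta + tr, ta + na
    n = r1 + na + nr
    denom = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, ta) * math.comb(n - r1, c1 - ta), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        px = Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), denom)
        if px <= p_obs:
            total += px
    return float(total)


class TestFisherSomatic:
    def test_identical_proportions_not_somatic(self):
        res = fisher_somatic_test(50, 25, 50, 25)
        assert res.p_value == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)
        assert not res.is_somatic

    def test_tumor_only_alt_reads_somatic(self):
        # oracle: hypergeometric tail for the 2x2 table
        res = fisher_somatic_test(70, 30, 100, 0)
        assert res.p_value == pytest.approx(oracle_two_sided_p(30, 70, 0, 100), abs=1e-12)
        assert res.p_value < 0.02
        assert res.odds_ratio > 5.0
        assert res.is_somatic

    def test_no_alt_reads_uses_continuity_correction(self):
        res = fisher_somatic_test(50, 0, 50, 0)
        assert res.odds_ratio == pytest.approx(1.0)  # (0.5*50.5)/(50.5*0.5)
        assert not res.is_somatic

    def test_all_zero_table_raises(self):
        with pytest.raises(UndefinedTestError):
            fisher_somatic_test(0, 0, 0, 0)

    def test_odds_ratio_oriented_to_tumor_enrichment(self):
        enriched = fisher_somatic_test(50, 50, 90, 10)
        depleted = fisher_somatic_test(90, 10, 50, 50)
        assert enriched.odds_ratio > 1 > depleted.odds_ratio

    @pytest.mark.parametrize(
        "table",
        [(5, 3, 6, 1), (10, 0, 3, 7), (1, 1, 1, 1), (20, 10, 15, 15), (0, 9, 9, 0)],
    )
    def test_agrees_with_enumeration_oracle(self, table):
        tr, ta, nr, na = table
        res = fisher_somatic_test(tr, ta, nr, na)
        assert res.p_value == pytest.approx(oracle_two_sided_p(ta, tr, na, nr), abs=1e-12)

    def test_agrees_with_scipy_cross_check(self):
        # independent second route through scipy's implementation
        for tr, ta, nr, na in [(70, 30, 100, 0), (12, 8, 19, 1), (40, 5, 38, 7)]:
            res = fisher_somatic_test(tr, ta, nr, na)
            _, p = stats.fisher_exact([[ta, tr], [na, nr]])
            assert res.p_value == pytest.approx(p, abs=1e-10)

    @settings(max_examples=60, deadline=None)
    @given(
        tumor_depth=st.integers(10, 200),
        normal=st.tuples(st.integers(0, 150), st.integers(0, 30)),
        alts=st.tuples(st.integers(0, 100), st.integers(0, 100)),
    )
    def test_p_nonincreasing_in_tumor_alt(self, tumor_depth, normal, alts):
        """At fixed normal counts and tumor depth, more alt reads never
        weaken the evidence (above the normal's alt proportion)."""
        nr, na = normal
        if nr + na == 0:
            nr = 1
        a1, a2 = sorted(min(a, tumor_depth) for a in alts)
        base = math.ceil(tumor_depth * (na / (nr + na)))
        a1, a2 = max(a1, base), max(a2, base)
        p1 = fisher_somatic_test(tumor_depth - a1, a1, nr, na).p_value
        p2 = fisher_somatic_test(tumor_depth - a2, a2, nr, na).p_value
        assert p2 <= p1 + 1e-12


class TestGermlineHet:
    @pytest.mark.parametrize(
        "vaf,expected",
        [(0.5, True), (0.29, False), (0.3, True), (0.70, True), (0.71, False), (0.0, False)],
    )
    def test_band_bounds_inclusive(self, vaf, expected):
        assert qualify_germline_het(vaf) is expected


def _somatic_variant(pos, category, somatic_in):
    rec = VariantRecord(
        chrom="chr1", pos=pos, ref="A", alt="T",
        counts={"T1": (50, 50), "N1": (100, 0)}, category=category,
    )
    for s, flag in somatic_in.items():
        rec.is_somatic[s] = flag
    return rec


class TestTally:
    def test_empty_list_all_zero(self):
        assert all(v == 0 for v in tally_categories([], "T1").values())

    def test_counts_by_category(self):
        variants = [
            _somatic_variant(i, Category.MISSENSE, {"T1": True}) for i in range(1, 4)
        ] + [_somatic_variant(10, Category.FRAMESHIFT, {"T1": True})]
        tally = tally_categories(variants, "T1")
        assert tally[Category.MISSENSE] == 3
        assert tally[Category.FRAMESHIFT] == 1
        assert sum(tally.values()) == 4

    def test_non_somatic_excluded(self):
        variants = [
            _somatic_variant(1, Category.MISSENSE, {"T1": True}),
            _somatic_variant(2, Category.MISSENSE, {"T1": False}),
        ]
        assert tally_categories(variants, "T1")[Category.MISSENSE] == 1

    def test_unknown_sample_raises(self):
        variants = [_somatic_variant(1, Category.MISSENSE, {"T1": True})]
        with pytest.raises(KeyError):
            tally_categories(variants, "T9")


class TestFlagSomatic:
    def test_germline_het_never_flagged(self):
        # strong tumor alt enrichment, but the normal carries the allele
        rec = VariantRecord(
            chrom="chr1", pos=5, ref="A", alt="T",
            counts={"T1": (20, 80), "N1": (75, 75)},
        )
        flag_somatic([rec], "T1", "N1")
        assert rec.is_somatic["T1"] is False

    def test_true_somatic_flagged(self):
        rec = VariantRecord(
            chrom="chr1", pos=5, ref="A", alt="T",
            counts={"T1": (100, 50), "N1": (150, 0)},
        )
        flag_somatic([rec], "T1", "N1")
        assert rec.is_somatic["T1"] is True

    def test_zero_depth_not_somatic(self):
        rec = VariantRecord(
            chrom="chr1", pos=5, ref="A", alt="T",
            counts={"T1": (0, 0), "N1": (150, 0)},
        )
        flag_somatic([rec], "T1", "N1")
        assert rec.is_somatic["T1"] is False
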