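"""Tumor-normal somatic variant test and mutation-category bookkeeping.

A candidate site is called somatic when the two-sided Fisher exact test on
the 2x2 table of (ref, alt) read counts in tumor vs normal gives
p < 0.02 *and* the tumor-vs-normal odds ratio for the alternate allele
exceeds 5.0.  The two-sided p combined with the directional odds-ratio
requirement enforces tumor enrichment without guessing the sidedness of the
original test.  The odds ratio uses the Haldane-Anscombe +0.5 correction
when any cell is zero; the p-value is always exact and uncorrected.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Sequence

from .errors import ParameterError, UndefinedTestError
from .types import Category, FisherResult, VariantRecord

P_THRESHOLD = 0.02
OR_THRESHOLD = 5.0
GERMLINE_HET_LOW = 0.3
GERMLINE_HET_HIGH = 0.7


def _two_sided_exact_p(ta: int, tr: int, na: int, nr: int) -> float:
    """Two-sided Fisher p for the table [[ta, tr], [na, nr]].

    Conditions on the margins and sums the hypergeometric probabilities of
    every table at most as likely as the observed one.  All comparisons
    are between exact integers (numerators over the common denominator
    C(n, c1)), so ties are handled exactly with no floating-point
    tolerance.
    """
    r1 = ta + tr  # tumor depth
    c1 = ta + na  # total alt reads
    n = r1 + na + nr
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    obs = math.comb(r1, ta) * math.comb(n - r1, c1 - ta)
    total = 0
    for x in range(lo, hi + 1):
        w = math.comb(r1, x) * math.comb(n - r1, c1 - x)
        if w <= obs:
            total += w
    return min(1.0, total / math.comb(n, c1))


def fisher_somatic_test(
    tumor_ref: int,
    tumor_alt: int,
    normal_ref: int,
    normal_alt: int,
    p_threshold: float = P_THRESHOLD,
    or_threshold: float = OR_THRESHOLD,
) -> FisherResult:
    """Exact test of alt-allele enrichment in tumor over normal.

    Parameters are the four cells of the 2x2 read-count table.  The odds
    ratio is oriented so that values > 1 mean the tumor is enriched for the
    alternate allele.  Raises :class:`UndefinedTestError` when a sample has
    no reads at all.
    """
    for c in (tumor_ref, tumor_alt, normal_ref, normal_alt):
        if c < 0:
            raise ParameterError(f"negative count {c}")
    if tumor_ref + tumor_alt == 0 or normal_ref + normal_alt == 0:
        raise UndefinedTestError("a sample has zero total reads at the site")

    p = _two_sided_exact_p(tumor_alt, tumor_ref, normal_alt, normal_ref)
    if min(tumor_ref, tumor_alt, normal_ref, normal_alt) == 0:
        # Haldane-Anscombe correction for the odds ratio only; p stays exact
        odds = ((tumor_alt + 0.5) * (normal_ref + 0.5)) / (
            (tumor_ref + 0.5) * (normal_alt + 0.5)
        )
    else:
        odds = (tumor_alt * normal_ref) / (tumor_ref * normal_alt)
    is_somatic = (p < p_threshold) and (odds > or_threshold)
    return FisherResult(p_value=float(p), odds_ratio=float(odds), is_somatic=is_somatic)


def qualify_germline_het(normal_vaf: float) -> bool:
    """True when the normal-sample VAF is in the germline-het band [0.3, 0.7]."""
    if not (0.0 <= normal_vaf <= 1.0) or math.isnan(normal_vaf):
        raise ParameterError(f"VAF must be in [0, 1], got {normal_vaf}")
    return GERMLINE_HET_LOW <= normal_vaf <= GERMLINE_HET_HIGH


def flag_somatic(
    variants: Iterable[VariantRecord],
    tumor_sample: str,
    normal_sample: str,
    p_threshold: float = P_THRESHOLD,
    or_threshold: float = OR_THRESHOLD,
    max_normal_vaf: float = GERMLINE_HET_LOW,
) -> list[VariantRecord]:
    """Apply the exact test to every variant, setting per-sample somatic flags.

    Sites with appreciable alternate support in the normal
    (VAF >= ``max_normal_vaf``) are germline and never somatic, regardless
    of the tumor counts — a deleted germline het can otherwise look
    tumor-enriched.  Sites where either sample has zero depth are flagged
    not-somatic (the test is undefined there and absence cannot be
    asserted either way).
    """
    out = []
    for rec in variants:
        tr, ta = rec.counts.get(tumor_sample, (0, 0))
        nr, na = rec.counts.get(normal_sample, (0, 0))
        if tr + ta == 0 or nr + na == 0:
            rec.is_somatic[tumor_sample] = False
        elif na / (nr + na) >= max_normal_vaf:
            rec.is_somatic[tumor_sample] = False
        else:
            res = fisher_somatic_test(tr, ta, nr, na, p_threshold, or_threshold)
            rec.is_somatic[tumor_sample] = res.is_somatic
        out.append(rec)
    return out


def tally_categories(
    variants: Sequence[VariantRecord], sample_id: str
) -> dict[Category, int]:
    """Count somatic variants per consequence category for one sample."""
    known = {s for v in variants for s in v.counts} | {
        s for v in variants for s in v.is_somatic
    }
    if variants and sample_id not in known:
        raise KeyError(f"unknown sample {sample_id!r}")
    counts: Counter[Category] = Counter()
    for v in variants:
        if v.is_somatic.get(sample_id, False):
            counts[v.category] += 1
    return {cat: counts.get(cat, 0) for cat in Category}
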