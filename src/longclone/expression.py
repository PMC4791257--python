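"""RPKM quantification, fold-change DEG selection, and gene-set overlap.

Expression is quantified as RPKM (reads per kilobase of transcript per
million mapped reads).  Differentially expressed genes (DEGs) between the
low- and high-grade samples are selected by ``|log2 fold change| > 3`` on
pseudocounted RPKM.  DEG lists are then scored against a gene-set
collection (GMT, MSigDB C2-style) by hypergeometric overlap: for a set
with K genes in the expression universe of N genes and a query of n DEGs,
k of which fall in the set, the enrichment p-value is the upper tail
P(X >= k) of Hypergeometric(N, K, n), with Benjamini-Hochberg FDR across
sets.  The overlap ratio k/K follows the MSigDB reporting convention.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .types import GeneExpressionRecord, GeneSet, GeneSetOverlap

log = logging.getLogger(__name__)

DEG_LOG2FC_CUTOFF = 3.0
DEG_PSEUDOCOUNT = 1.0


def rpkm(count: float, gene_length: int, library_size: float) -> float:
    """RPKM = count * 1e9 / (gene_length * library_size)."""
    if gene_length <= 0 or library_size <= 0:
        raise ParameterError("gene_length and library_size must be > 0")
    if count < 0:
        raise ParameterError("count must be >= 0")
    return count * 1e9 / (gene_length * library_size)


def quantify_rpkm(
    records: Sequence[GeneExpressionRecord],
) -> list[GeneExpressionRecord]:
    """Fill per-sample RPKM on each record; library size = total counts."""
    samples = sorted({s for r in records for s in r.counts})
    libsize = {s: float(sum(r.counts.get(s, 0) for r in records)) for s in samples}
    for s, n in libsize.items():
        if n <= 0:
            raise ParameterError(f"sample {s} has zero mapped reads")
    for r in records:
        r.rpkm = {s: rpkm(r.counts.get(s, 0), r.length_bp, libsize[s]) for s in samples}
    return list(records)


def select_degs(
    records: Sequence[GeneExpressionRecord],
    low_sample: str,
    high_sample: str,
    cutoff: float = DEG_LOG2FC_CUTOFF,
    pseudocount: float = DEG_PSEUDOCOUNT,
) -> list[GeneExpressionRecord]:
    """Flag DEGs by |log2((high + c)/(low + c))| > cutoff on RPKM.

    The pseudocount c guards the ratio against zero RPKM; the sign of
    log2fc records the direction (positive = up in high grade).  Returns
    the same records with ``log2fc`` and ``is_deg`` filled.
    """
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be > 0")
    for r in records:
        lo = r.rpkm[low_sample]
        hi = r.rpkm[high_sample]
        r.log2fc = math.log2((hi + pseudocount) / (lo + pseudocount))
        r.is_deg = abs(r.log2fc) > cutoff
    return list(records)


def overlap_stats(
    query: Iterable[str], gene_set: GeneSet, universe: Iterable[str]
) -> GeneSetOverlap:
    """Hypergeometric overlap of a query gene list with one gene set.

    K counts the set's members inside the universe; k the query genes in
    the set.  p = P(X >= k) for X ~ Hypergeometric(N=|universe|, K, n=|query|).
    """
    universe = frozenset(universe)
    if not universe:
        raise ParameterError("empty gene universe")
    query = frozenset(query)
    if not query <= universe:
        log.warning(
            "query has %d genes outside the universe; intersecting",
            len(query - universe),
        )
        query &= universe
    members = gene_set.members
    if not members <= universe:
        log.warning(
            "gene set %s has %d members outside the universe; intersecting",
            gene_set.name,
            len(members - universe),
        )
        members = members & universe
    N, K, n = len(universe), len(members), len(query)
    k = len(query & members)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    ratio = k / K if K > 0 else 0.0
    return GeneSetOverlap(set_name=gene_set.name, K=K, k=k, ratio=ratio, p_value=p)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must be in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def overlap_table(
    query: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
) -> list[GeneSetOverlap]:
    """Score a query list against every gene set, with BH FDR across sets.

    Sorted by ascending p-value (ties by name).
    """
    universe = frozenset(universe)
    results = [overlap_stats(query, gs, universe) for gs in gene_sets]
    qvals = bh_fdr([r.p_value for r in results])
    results = [
        GeneSetOverlap(
            set_name=r.set_name, K=r.K, k=r.k, ratio=r.ratio,
            p_value=r.p_value, q_value=q, es=r.es,
        )
        for r, q in zip(results, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def deg_gene_lists(
    records: Sequence[GeneExpressionRecord],
) -> tuple[list[str], list[str]]:
    """Split flagged DEGs into (up-regulated, down-regulated) gene lists."""
    up = [r.gene_id for r in records if r.is_deg and (r.log2fc or 0) > 0]
    down = [r.gene_id for r in records if r.is_deg and (r.log2fc or 0) < 0]
    return up, down


def expression_universe(records: Sequence[GeneExpressionRecord]) -> list[str]:
    """The enrichment universe: all genes with positive length in the table."""
    return [r.gene_id for r in records if r.length_bp > 0]
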