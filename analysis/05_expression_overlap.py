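#!/usr/bin/env python
"""Expression fold-change analysis and gene-set overlap statistics.

Quantifies RPKM from the simulated counts, selects DEGs at
|log2 fold change| > 3 (pseudocount 1), builds a small synthetic gene-set
collection over the simulated gene universe (one set seeded with true
up-regulated genes, one with downs, plus background sets), and scores the
DEG list by hypergeometric overlap with BH FDR — the K / k / k-over-K
bookkeeping.

Reads results/cohort/; writes results/expression_genes.tsv,
results/synthetic_c2.gmt and results/gene_set_overlap.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from longclone import expression
from longclone.io_formats import (
    read_expression,
    read_gene_sets,
    read_sample_meta,
    write_gene_sets,
)
from longclone.types import GeneSet, Role

BASE = Path(__file__).resolve().parent.parent / "results"


def synthetic_gene_sets(universe, truth_lfc, seed=13):
    """Gene sets over the simulated universe: two seeded with the genes that
    truly move (up/down), two random background sets.  Synthetic stand-in
    for a curated collection."""
    import random

    rnd = random.Random(seed)
    ups = [g for g, l in truth_lfc.items() if l > 3]
    downs = [g for g, l in truth_lfc.items() if l < -3]
    rest = [g for g in universe if abs(truth_lfc.get(g, 0.0)) <= 3]
    sets = [
        GeneSet("UP_PROGRAM", frozenset(ups + rnd.sample(rest, 60))),
        GeneSet("DOWN_PROGRAM", frozenset(downs + rnd.sample(rest, 40))),
        GeneSet("BACKGROUND_A", frozenset(rnd.sample(rest, 150))),
        GeneSet("BACKGROUND_B", frozenset(rnd.sample(rest, 80))),
    ]
    return sets


def main() -> None:
    metas = read_sample_meta(BASE / "cohort" / "samples.tsv")
    low = next(m.sample_id for m in metas if m.role is Role.LOW_GRADE)
    high = next(m.sample_id for m in metas if m.role is Role.HIGH_GRADE)
    records = read_expression(BASE / "cohort" / "expression.tsv")
    expression.quantify_rpkm(records)
    expression.select_degs(records, low, high)
    degs = [r.gene_id for r in records if r.is_deg]
    up, down = expression.deg_gene_lists(records)
    print(f"{len(degs)} DEGs at |log2FC| > 3 ({len(up)} up, {len(down)} down) "
          f"out of {len(records)} genes")
    pd.DataFrame(
        [{"gene_id": r.gene_id, "rpkm_low": r.rpkm[low], "rpkm_high": r.rpkm[high],
          "log2fc": r.log2fc, "is_deg": r.is_deg} for r in records]
    ).to_csv(BASE / "expression_genes.tsv", sep="\t", index=False)

    truth_lfc = json.loads((BASE / "cohort" / "truth.json").read_text())["gene_log2fc"]
    universe = expression.expression_universe(records)
    write_gene_sets(
        synthetic_gene_sets(universe, truth_lfc), BASE / "synthetic_c2.gmt"
    )
    sets = read_gene_sets(BASE / "synthetic_c2.gmt")
    results = expression.overlap_table(degs, sets, universe)
    print(f"{'set':<14} {'K':>5} {'k':>4} {'k/K':>7} {'p':>10} {'q':>10}")
    for r in results:
        print(f"{r.set_name:<14} {r.K:>5} {r.k:>4} {r.ratio:>7.4f} "
              f"{r.p_value:>10.2e} {r.q_value:>10.2e}")
    pd.DataFrame(
        [{"set_name": r.set_name, "K": r.K, "k": r.k, "ratio": r.ratio,
          "p_value": r.p_value, "q_value": r.q_value} for r in results]
    ).to_csv(BASE / "gene_set_overlap.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
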