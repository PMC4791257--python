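#!/usr/bin/env python
"""Estimate subclone fractions from heterozygous deletions and somatic SNVs.

For each tumor sample: select het-deletion segments > 10 Mb, estimate the
fraction of tumor cells carrying each deletion from the normalized depth
ratio and from the folded BAF of germline het SNPs, combine the two, and
cluster segments (and, separately, SNV cancer-cell fractions) into subclone
groups.  Compares the deletion-based and SNV-based fraction estimates per
group — the robustness check on the clonal architecture.

Reads results/cohort/ and results/variants_flagged.tsv (run 02 first);
writes results/segment_fractions.tsv, results/subclone_groups.tsv and
results/scna_vs_snv_fractions.tsv.
"""

from pathlib import Path

import pandas as pd

from longclone import clonality
from longclone.io_formats import read_sample_meta, read_segments, read_variants
from longclone.types import CopyState, Role

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    metas = read_sample_meta(BASE / "cohort" / "samples.tsv")
    normal = next(m.sample_id for m in metas if m.role is Role.NORMAL)
    low = next(m.sample_id for m in metas if m.role is Role.LOW_GRADE)
    high = next(m.sample_id for m in metas if m.role is Role.HIGH_GRADE)
    alpha = {m.sample_id: m.purity for m in metas}
    variants = read_variants(BASE / "variants_flagged.tsv")

    fractions: dict[str, dict[str, float]] = {}
    seg_tables = {}
    rows = []
    for sample in (low, high):
        segs = read_segments(BASE / "cohort" / f"segments_{sample}.tsv")
        seg_tables[sample] = segs
        for seg in clonality.estimate_segment_fractions(
            segs, variants, sample, normal, alpha[sample]
        ):
            fractions.setdefault(seg.key, {})[sample] = seg.f_combined
            rows.append({
                "sample_id": sample, "segment": seg.key, "R": seg.depth_ratio,
                "M": seg.baf_major, "n_het_snps": seg.n_het_snps,
                "f_depth": seg.f_depth, "f_baf": seg.f_baf,
                "f_combined": seg.f_combined, "discordant": seg.discordant,
            })
    pd.DataFrame(rows).to_csv(BASE / "segment_fractions.tsv", sep="\t", index=False)

    seg_groups = clonality.cluster_fractions(sorted(fractions.items()), sort_sample=high)
    named = clonality.name_groups(
        clonality.prune_absent_fractions(seg_groups), [low, high]
    )
    print("subclone groups from SCNAs:")
    grows = []
    for g in named:
        lo = g.fraction_by_sample.get(low)
        hi = g.fraction_by_sample.get(high)
        print(f"  {g.group_id}: low={'-' if lo is None else f'{lo:.0%}'} "
              f"high={'-' if hi is None else f'{hi:.0%}'} "
              f"({len(g.member_segments)} segments)")
        grows.append({"group": g.group_id, "fraction_low": lo, "fraction_high": hi,
                      "segments": ";".join(g.member_segments)})
    pd.DataFrame(grows).to_csv(BASE / "subclone_groups.tsv", sep="\t", index=False)

    # SNV cancer-cell fractions on diploid / het-deletion loci
    snv_items = []
    for rec in variants:
        if not any(rec.is_somatic.get(t, False) for t in (low, high)):
            continue
        ccfs = {}
        for sample in (low, high):
            host = next(
                (s for s in seg_tables[sample] if s.contains(rec.chrom, rec.pos)), None
            )
            if host is None:
                continue
            vaf = rec.vaf(sample)
            if vaf != vaf:
                continue
            ccf = clonality.snv_ccf(
                vaf, alpha[sample], host.copy_state,
                fractions.get(host.key, {}).get(sample, 0.0)
                if host.copy_state is CopyState.HET_DELETION else None,
            )
            if ccf is not None:
                ccfs[sample] = ccf
        if ccfs:
            snv_items.append((rec.key, ccfs))
    snv_groups = clonality.cluster_fractions(snv_items, sort_sample=high)
    pooled = clonality.snv_fraction_by_group(named, snv_groups)
    crows = []
    print("deletion-based vs SNV-based fractions per group:")
    for g in named:
        centroid, n = pooled.get(g.group_id, ({}, 0))
        crows.append({
            "group": g.group_id,
            "fraction_low_scna": g.fraction_by_sample.get(low),
            "fraction_high_scna": g.fraction_by_sample.get(high),
            "fraction_low_snv": centroid.get(low),
            "fraction_high_snv": centroid.get(high),
            "n_snvs": n,
        })
        print(f"  {g.group_id}: " + ", ".join(
            f"{s}: scna={g.fraction_by_sample.get(s, 0):.2f} snv={centroid.get(s, 0):.2f}"
            for s in (low, high)
        ) + f" [{n} SNVs]")
    pd.DataFrame(crows).to_csv(BASE / "scna_vs_snv_fractions.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
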