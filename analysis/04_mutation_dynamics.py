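#!/usr/bin/env python
"""Classify mutation fates across timepoints and build the evolution model.

Matches somatic calls between the low- and high-grade samples, classifies
each mutation as preserved / newly developed / disappeared (absence only
asserted at >= 10x local depth), verifies the bookkeeping identities, and
assembles the clonal-evolution model (trunk / extinct / emergent roles with
fraction nesting) from the subclone groups of step 03.

Reads results/variants_flagged.tsv and results/subclone_groups.tsv; writes
results/dynamics.tsv, results/dynamics_summary.tsv and
results/evolution_model.json.
"""

import json
from pathlib import Path

import pandas as pd

from longclone import dynamics
from longclone.io_formats import read_sample_meta, read_variants
from longclone.types import Role, SubcloneGroup

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    metas = read_sample_meta(BASE / "cohort" / "samples.tsv")
    low = next(m.sample_id for m in metas if m.role is Role.LOW_GRADE)
    high = next(m.sample_id for m in metas if m.role is Role.HIGH_GRADE)
    variants = read_variants(BASE / "variants_flagged.tsv")

    low_calls = [v for v in variants if v.is_somatic.get(low, False)]
    high_calls = [v for v in variants if v.is_somatic.get(high, False)]
    pairs = dynamics.match_variants(low_calls, high_calls, low, high)
    records = [dynamics.classify_dynamics(p) for p in pairs]
    summary = dynamics.dynamics_summary(records)
    print("mutation dynamics:", summary)
    kept, gone, new = (
        summary["preserved"], summary["disappeared"], summary["newly_developed"]
    )
    print(f"  identities: preserved+disappeared={kept + gone} "
          f"(low-grade calls: {len(low_calls)}), "
          f"preserved+newly={kept + new} (high-grade calls: {len(high_calls)})")

    pd.DataFrame(
        [{"chrom": r.key[0], "pos": r.key[1], "status": r.status.value}
         for r in records]
    ).to_csv(BASE / "dynamics.tsv", sep="\t", index=False)
    pd.DataFrame([summary]).to_csv(BASE / "dynamics_summary.tsv", sep="\t", index=False)

    groups_df = pd.read_csv(BASE / "subclone_groups.tsv", sep="\t")
    groups = []
    for row in groups_df.itertuples(index=False):
        fr = {}
        if row.fraction_low == row.fraction_low:
            fr[low] = float(row.fraction_low)
        if row.fraction_high == row.fraction_high:
            fr[high] = float(row.fraction_high)
        groups.append(SubcloneGroup(
            group_id=row.group, member_segments=str(row.segments).split(";"),
            fraction_by_sample=fr,
        ))
    model = dynamics.build_evolution_model(groups, [low, high])
    print("clonal evolution model:")
    for c in model.clones:
        print(f"  {c.group_id}: {c.role.value}"
              + (f" (nested in {c.parent})" if c.parent else " (root)"))
    if model.violations:
        print("  pigeonhole violations:", model.violations)
    (BASE / "evolution_model.json").write_text(json.dumps({
        "clones": [
            {"group": c.group_id, "role": c.role.value, "parent": c.parent,
             "fractions": c.fraction_by_sample}
            for c in model.clones
        ],
        "violations": model.violations,
    }, indent=1))


if __name__ == "__main__":
    main()
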