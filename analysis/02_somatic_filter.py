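#!/usr/bin/env python
"""Flag somatic variants in each tumor sample and tally mutation categories.

Applies the tumor-normal exact test (p < 0.02, odds ratio > 5) to every
variant against the matched normal, then counts somatic calls per
consequence category — the per-sample mutation bookkeeping table.
Reads results/cohort/, writes results/mutation_tally.tsv and
results/variants_flagged.tsv.
"""

from pathlib import Path

import pandas as pd

from longclone import somatic_filter
from longclone.io_formats import read_sample_meta, read_variants, write_variants
from longclone.types import Role

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    metas = read_sample_meta(BASE / "cohort" / "samples.tsv")
    normal = next(m.sample_id for m in metas if m.role is Role.NORMAL)
    tumors = [m.sample_id for m in metas if m.role is not Role.NORMAL]
    variants = read_variants(BASE / "cohort" / "variants.tsv")

    rows = []
    for tumor in tumors:
        somatic_filter.flag_somatic(variants, tumor, normal)
        tally = somatic_filter.tally_categories(variants, tumor)
        total = sum(tally.values())
        print(f"{tumor}: {total} somatic calls "
              + str({k.value: v for k, v in tally.items() if v}))
        for cat, n in tally.items():
            rows.append({"sample_id": tumor, "category": cat.value, "n": n})

    write_variants(variants, BASE / "variants_flagged.tsv")
    pd.DataFrame(rows).to_csv(BASE / "mutation_tally.tsv", sep="\t", index=False)
    print(f"wrote {BASE / 'mutation_tally.tsv'}")


if __name__ == "__main__":
    main()
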