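#!/usr/bin/env python
"""Generate the study-condition synthetic patient used by the later steps.

Writes a paired low-grade / high-grade tumor cohort with matched normal to
``results/cohort/``: WES-style variant read counts at 150x, copy-number
segment tables with subclonal heterozygous deletions > 10 Mb, germline het
SNPs, clone-private somatic SNVs, an RNA count table with large-fold-change
genes, and the ground truth (truth.json).
"""

import sys
from pathlib import Path

from longclone.siminput import SimConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main(seed: int = 1) -> None:
    config = SimConfig(seed=seed)
    cohort = simulate_cohort(config)
    cohort.write(OUT)
    n_somatic = len(cohort.truth.snv_ccf)
    n_germline = len(cohort.variants) - n_somatic
    print(f"cohort written to {OUT}")
    print(f"  samples: {[m.sample_id for m in cohort.samples]}")
    print(f"  purities: low={config.purity_low}, high={config.purity_high}")
    print(f"  variants: {n_germline} germline het SNPs, {n_somatic} somatic SNVs")
    print(f"  clones: " + ", ".join(
        f"{c.clone_id}(low={c.fraction_low}, high={c.fraction_high})"
        for c in config.clones
    ))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
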