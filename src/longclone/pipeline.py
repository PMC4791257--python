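"""End-to-end orchestration: somatic filter -> clonality -> dynamics -> expression.

Every stage hands off through files in the run directory; outputs carry the
configuration hash so any threshold change is visible in the artefacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from . import clonality, dynamics, expression, somatic_filter
from .errors import ConfigError, StageError
from .io_formats import (
    read_expression,
    read_gene_sets,
    read_sample_meta,
    read_segments,
    read_variants,
    write_variants,
)
from .types import CopyState, Role, SampleMeta, VariantRecord

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run.

    Threshold defaults are the study values: Fisher p < 0.02 with odds
    ratio > 5, germline-het band [0.3, 0.7], candidate deletions > 10 Mb,
    fraction merge threshold 0.10, DEG |log2FC| > 3 with pseudocount 1,
    absence assessable at >= 10x local depth.
    """

    variants: str
    samples: str
    segments_by_sample: dict[str, str]
    out_dir: str
    expression_counts: str | None = None
    gene_sets: str | None = None
    p_threshold: float = somatic_filter.P_THRESHOLD
    or_threshold: float = somatic_filter.OR_THRESHOLD
    min_segment_length: int = clonality.MIN_SEGMENT_LENGTH
    merge_threshold: float = clonality.MERGE_THRESHOLD
    discordance_threshold: float = clonality.DISCORDANCE_THRESHOLD
    presence_min: float = 0.05
    min_absence_depth: int = dynamics.MIN_ABSENCE_DEPTH
    containment_tolerance: float = 0.05
    deg_cutoff: float = expression.DEG_LOG2FC_CUTOFF
    deg_pseudocount: float = expression.DEG_PSEUDOCOUNT
    seed: int = 0

    _PATH_FIELDS = (
        "variants", "samples", "segments_by_sample", "out_dir",
        "expression_counts", "gene_sets",
    )

    def config_hash(self) -> str:
        """Hash of the analysis parameters (thresholds and seed, not paths)."""
        payload = json.dumps(
            {
                k: v
                for k, v in dataclasses.asdict(self).items()
                if k not in self._PATH_FIELDS
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _roles(metas: list[SampleMeta]) -> dict[Role, SampleMeta]:
    by_role = {m.role: m for m in metas}
    for role in (Role.NORMAL, Role.LOW_GRADE, Role.HIGH_GRADE):
        if role not in by_role:
            raise ConfigError(f"no sample with role {role.value}")
    for m in metas:
        if m.role is not Role.NORMAL and not (0 < m.purity <= 1):
            raise ConfigError(f"missing/invalid purity for tumor sample {m.sample_id}")
    return by_role


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    chash = config.config_hash()

    def stage(name):
        def wrap(fn, *args, **kw):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kw)
            except Exception as exc:
                raise StageError(f"stage {name} failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0
            log.info("stage %s: done in %.2fs", name, timings[name])
            return result
        return wrap

    metas = read_sample_meta(config.samples)
    by_role = _roles(metas)
    normal = by_role[Role.NORMAL].sample_id
    low = by_role[Role.LOW_GRADE].sample_id
    high = by_role[Role.HIGH_GRADE].sample_id
    tumor_samples = [low, high]
    alpha = {m.sample_id: m.purity for m in metas}

    variants = read_variants(config.variants, dialect="tsv")

    # ---- somatic filter ----
    def _somatic() -> list[VariantRecord]:
        for tumor in tumor_samples:
            somatic_filter.flag_somatic(
                variants, tumor, normal, config.p_threshold, config.or_threshold
            )
        write_variants(variants, out / "variants_flagged.tsv")
        rows = []
        for tumor in tumor_samples:
            tally = somatic_filter.tally_categories(variants, tumor)
            for cat, n in tally.items():
                rows.append({"sample_id": tumor, "category": cat.value, "n": n})
        pd.DataFrame(rows).assign(config_hash=chash).to_csv(
            out / "mutation_tally.tsv", sep="\t", index=False
        )
        return variants

    stage("somatic_filter")(_somatic)

    # ---- clonality ----
    def _clonality():
        seg_tables = {}
        for sample, path in config.segments_by_sample.items():
            seg_tables[sample] = read_segments(path)
        frac_by_key: dict[str, dict[str, float]] = {}
        seg_rows = []
        for sample in tumor_samples:
            est = clonality.estimate_segment_fractions(
                seg_tables[sample], variants, sample, normal, alpha[sample],
                config.min_segment_length, config.discordance_threshold,
            )
            for seg in est:
                frac_by_key.setdefault(seg.key, {})[sample] = seg.f_combined
                seg_rows.append(
                    {
                        "sample_id": sample, "segment": seg.key,
                        "depth_ratio": seg.depth_ratio, "baf_major": seg.baf_major,
                        "n_het_snps": seg.n_het_snps, "f_depth": seg.f_depth,
                        "f_baf": seg.f_baf, "f_combined": seg.f_combined,
                        "discordant": seg.discordant,
                    }
                )
        pd.DataFrame(seg_rows).assign(config_hash=chash).to_csv(
            out / "segment_fractions.tsv", sep="\t", index=False
        )
        items = sorted(frac_by_key.items())
        seg_groups = clonality.cluster_fractions(
            items, config.merge_threshold, sort_sample=high
        )
        seg_groups = clonality.prune_absent_fractions(seg_groups, config.presence_min)
        seg_groups = clonality.name_groups(seg_groups, tumor_samples)
        grows = []
        for g in seg_groups:
            grows.append(
                {
                    "group": g.group_id,
                    "fraction_low": g.fraction_by_sample.get(low),
                    "fraction_high": g.fraction_by_sample.get(high),
                    "segments": ";".join(g.member_segments),
                }
            )
        pd.DataFrame(grows).assign(config_hash=chash).to_csv(
            out / "subclone_groups.tsv", sep="\t", index=False
        )

        # SNV cancer-cell fractions on diploid / het-deletion loci
        snv_rows = []
        snv_items = []
        for rec in variants:
            if not any(rec.is_somatic.get(t, False) for t in tumor_samples):
                continue
            ccf_by_sample = {}
            for sample in tumor_samples:
                host = next(
                    (s for s in seg_tables[sample] if s.contains(rec.chrom, rec.pos)),
                    None,
                )
                if host is None or sample not in rec.counts:
                    continue
                vaf = rec.vaf(sample)
                if vaf != vaf:
                    continue
                f_del = frac_by_key.get(host.key, {}).get(sample, 0.0)
                state = host.copy_state
                if state is CopyState.HET_DELETION and host.key not in frac_by_key:
                    continue  # candidate too short to estimate; CCF undefined
                ccf = clonality.snv_ccf(
                    vaf, alpha[sample], state,
                    f_del if state is CopyState.HET_DELETION else None,
                )
                if ccf is not None:
                    ccf_by_sample[sample] = ccf
                    rec.ccf[sample] = ccf
            for sample, ccf in ccf_by_sample.items():
                snv_rows.append(
                    {
                        "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                        "alt": rec.alt, "sample_id": sample,
                        "somatic": rec.is_somatic.get(sample, False), "ccf": ccf,
                    }
                )
            if ccf_by_sample:
                snv_items.append((rec.key, ccf_by_sample))
        pd.DataFrame(snv_rows).assign(config_hash=chash).to_csv(
            out / "snv_ccf.tsv", sep="\t", index=False
        )
        snv_groups_raw = clonality.cluster_fractions(
            snv_items, config.merge_threshold, sort_sample=high
        )
        # SCNA-based vs SNV-based fraction estimates per subclone
        pooled = clonality.snv_fraction_by_group(seg_groups, snv_groups_raw)
        crows = []
        for g in seg_groups:
            centroid, n = pooled.get(g.group_id, ({}, 0))
            crows.append(
                {
                    "group": g.group_id,
                    "fraction_low_scna": g.fraction_by_sample.get(low),
                    "fraction_high_scna": g.fraction_by_sample.get(high),
                    "fraction_low_snv": centroid.get(low),
                    "fraction_high_snv": centroid.get(high),
                    "n_snvs": n,
                }
            )
        pd.DataFrame(crows).assign(config_hash=chash).to_csv(
            out / "scna_vs_snv_fractions.tsv", sep="\t", index=False
        )
        snv_groups = clonality.prune_absent_fractions(snv_groups_raw, config.presence_min)
        snv_groups = clonality.name_groups(snv_groups, tumor_samples)
        return seg_groups, snv_groups

    seg_groups, snv_groups = stage("clonality")(_clonality)

    # ---- dynamics ----
    def _dynamics():
        low_calls = [v for v in variants if v.is_somatic.get(low, False)]
        high_calls = [v for v in variants if v.is_somatic.get(high, False)]
        pairs = dynamics.match_variants(low_calls, high_calls, low, high)
        # placeholders need the other sample's depth: all records carry all samples
        for p in pairs:
            rec = next(v for v in variants if v.key == p.key)
            if p.low_depth is None and low in rec.counts:
                p.low_depth = rec.depth(low)
            if p.high_depth is None and high in rec.counts:
                p.high_depth = rec.depth(high)
        records = [
            dynamics.classify_dynamics(p, config.min_absence_depth) for p in pairs
        ]
        summary = dynamics.dynamics_summary(records)
        pd.DataFrame(
            [
                {"chrom": r.key[0], "pos": r.key[1], "ref": r.key[2],
                 "alt": r.key[3], "status": r.status.value}
                for r in records
            ]
        ).assign(config_hash=chash).to_csv(out / "dynamics.tsv", sep="\t", index=False)
        pd.DataFrame([summary]).assign(config_hash=chash).to_csv(
            out / "dynamics_summary.tsv", sep="\t", index=False
        )
        model = dynamics.build_evolution_model(
            seg_groups, tumor_samples, config.containment_tolerance
        )
        (out / "evolution_model.json").write_text(
            json.dumps(
                {
                    "config_hash": chash,
                    "clones": [
                        {
                            "group": c.group_id, "role": c.role.value,
                            "parent": c.parent,
                            "fractions": c.fraction_by_sample,
                        }
                        for c in model.clones
                    ],
                    "violations": model.violations,
                },
                indent=1,
            )
        )
        return summary, model

    summary, model = stage("dynamics")(_dynamics)

    # ---- expression ----
    overlaps = []
    if config.expression_counts:
        def _expression():
            records = read_expression(config.expression_counts)
            expression.quantify_rpkm(records)
            expression.select_degs(
                records, low, high, config.deg_cutoff, config.deg_pseudocount
            )
            pd.DataFrame(
                [
                    {
                        "gene_id": r.gene_id, "length_bp": r.length_bp,
                        "rpkm_low": r.rpkm[low], "rpkm_high": r.rpkm[high],
                        "log2fc": r.log2fc, "is_deg": r.is_deg,
                    }
                    for r in records
                ]
            ).assign(config_hash=chash).to_csv(
                out / "expression_genes.tsv", sep="\t", index=False
            )
            results = []
            if config.gene_sets:
                sets = read_gene_sets(config.gene_sets)
                universe = expression.expression_universe(records)
                degs = [r.gene_id for r in records if r.is_deg]
                results = expression.overlap_table(degs, sets, universe)
                pd.DataFrame(
                    [
                        {
                            "set_name": r.set_name, "K": r.K, "k": r.k,
                            "ratio": r.ratio, "p_value": r.p_value,
                            "q_value": r.q_value,
                        }
                        for r in results
                    ]
                ).assign(config_hash=chash).to_csv(
                    out / "gene_set_overlap.tsv", sep="\t", index=False
                )
            return results

        overlaps = stage("expression")(_expression)

    manifest = {
        "package": "longclone",
        "version": __version__,
        "config_hash": chash,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stage_seconds": timings,
        "n_variants": len(read_variants(config.variants)),
        "n_segment_groups": len(seg_groups),
        "n_snv_groups": len(snv_groups),
        "dynamics_summary": summary,
        "n_overlap_sets": len(overlaps),
        "model_violations": model.violations,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
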