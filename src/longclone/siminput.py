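"""Synthetic paired tumor-normal cohort generator with ground truth.

The generator runs the clonality observation model forward to emulate the
study's inputs: a matched normal plus low-grade and high-grade tumor
samples from one patient, WES-style read counts at ~150x mean depth,
subclonal heterozygous deletions larger than 10 Mb, germline het SNPs,
clone-private somatic SNVs, and an RNA count table with a handful of
large-fold-change genes.

Read model: site depth ~ Poisson(mean_depth * local_copy / 2) where the
cell-averaged local copy number is ``2 - alpha * f`` on a segment deleted
in a fraction ``f`` of tumor cells; alt counts ~ Binomial(depth, expected
allele fraction).  The deleted haplotype is fixed per segment and each
SNP's alt allele lands on it with probability 1/2 (random phase), so the
folded BAF is the correct summary.  The normal sample has BAF centred at
0.5 and sequencing-error alternate reads at rate 1e-3 at somatic sites.
RNA counts are negative binomial (gamma-Poisson).

``noise_free=True`` replaces every random draw by its expectation
(germline allele fractions are emitted as exact rationals via integer
counts), which makes the depth- and BAF-inversions recover the configured
clone fractions to floating-point precision.

Defaults mirror the study conditions: purities inside the reported 62-91%
band, 150x depth, and a clone structure with a trunk clone present at both
timepoints plus two nested high-grade-only subclones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from .errors import ConfigError, ParameterError
from .io_formats import (
    write_expression,
    write_sample_meta,
    write_segments,
    write_variants,
)
from .types import (
    Category,
    CopyState,
    GeneExpressionRecord,
    Role,
    SampleMeta,
    SegmentRecord,
    VariantRecord,
)

_CHROM_LENGTH = 120_000_000  # synthetic chr1..chr22
_CATEGORY_WEIGHTS = {
    Category.MISSENSE: 0.75,
    Category.FRAMESHIFT: 0.12,
    Category.STOP_GAIN: 0.06,
    Category.CODON_INDEL: 0.03,
    Category.STOP_LOSS: 0.02,
    Category.START_LOST: 0.02,
}


@dataclass
class CloneSpec:
    """One subclone: its tumor-cell fraction per timepoint and its lesions.

    ``fraction_low``/``fraction_high`` are fractions of tumor cells
    (0 or None = absent at that timepoint).  ``parent`` declares nesting
    for feasibility checking.
    """

    clone_id: str
    fraction_low: float | None
    fraction_high: float | None
    n_segments: int = 2
    segment_length: int = 25_000_000
    n_private_snvs: int = 15
    frac_snvs_on_deletion: float = 0.2
    parent: str | None = None

    def fraction(self, role: Role) -> float:
        f = self.fraction_low if role is Role.LOW_GRADE else self.fraction_high
        return 0.0 if f is None else float(f)


@dataclass
class SimConfig:
    """Study-condition parameters for one simulated patient."""

    seed: int = 0
    patient_id: str = "sim_case"
    purity_low: float = 0.70
    purity_high: float = 0.85
    mean_depth: float = 150.0
    clones: list[CloneSpec] = field(default_factory=lambda: [
        CloneSpec("trunk", 0.60, 0.89, parent=None),
        CloneSpec("emergent_major", None, 0.88, parent="trunk"),
        CloneSpec("emergent_minor", None, 0.52, parent="emergent_major"),
        # SNV-only subclone that vanishes at recurrence ("disappeared" class)
        CloneSpec("extinct_minor", 0.35, None, n_segments=0,
                  n_private_snvs=10, parent="trunk"),
    ])
    n_germline_snps_per_mb: float = 25.0
    n_reference_segments: int = 8
    reference_segment_length: int = 30_000_000
    targets_per_mb: float = 20.0  # exome target density for segment read totals
    sequencing_error: float = 1e-3
    overdispersion: float = 0.0  # beta-binomial rho for allele counts; 0 = binomial
    n_genes: int = 2000
    n_deg_genes: int = 40
    deg_log2fc: float = 5.0
    rna_library_size: float = 2e6  # mapped reads per sample
    rna_dispersion: float = 0.1
    noise_free: bool = False

    def validate(self) -> None:
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if self.n_deg_genes > self.n_genes:
            raise ConfigError("n_deg_genes cannot exceed n_genes")
        for p in (self.purity_low, self.purity_high):
            if not (0 < p <= 1):
                raise ConfigError(f"purity {p} outside (0, 1]")
        by_id = {c.clone_id: c for c in self.clones}
        for c in self.clones:
            for f in (c.fraction_low, c.fraction_high):
                if f is not None and not (0 <= f <= 1):
                    raise ConfigError(f"clone {c.clone_id} fraction {f} outside [0, 1]")
            if c.parent is not None:
                if c.parent not in by_id:
                    raise ConfigError(f"clone {c.clone_id} has unknown parent {c.parent}")
                parent = by_id[c.parent]
                for role in (Role.LOW_GRADE, Role.HIGH_GRADE):
                    if c.fraction(role) > parent.fraction(role) + 1e-9:
                        raise ConfigError(
                            f"infeasible nesting: clone {c.clone_id} exceeds parent "
                            f"{c.parent} at {role.value}"
                        )


@dataclass
class SimTruth:
    """Ground truth sufficient to score every downstream estimate."""

    segment_fraction: dict[str, dict[str, float]]  # seg key -> sample -> f
    segment_clone: dict[str, str]
    snv_ccf: dict[str, dict[str, float]]  # variant key string -> sample -> CCF
    snv_clone: dict[str, str]
    snv_category: dict[str, str]
    gene_log2fc: dict[str, float]
    config: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


@dataclass
class SimCohort:
    samples: list[SampleMeta]
    variants: list[VariantRecord]
    segments_by_sample: dict[str, list[SegmentRecord]]
    expression: list[GeneExpressionRecord]
    truth: SimTruth

    def sample_id(self, role: Role) -> str:
        for m in self.samples:
            if m.role is role:
                return m.sample_id
        raise KeyError(role)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sample_meta(self.samples, outdir / "samples.tsv")
        write_variants(self.variants, outdir / "variants.tsv")
        for sample, segs in self.segments_by_sample.items():
            write_segments(segs, outdir / f"segments_{sample}.tsv")
        write_expression(self.expression, outdir / "expression.tsv")
        self.truth.to_json(outdir / "truth.json")


def _poisson(rng: np.random.Generator, lam: float, noise_free: bool) -> int:
    return int(round(lam)) if noise_free else int(rng.poisson(lam))


def _binomial(
    rng: np.random.Generator, n: int, p: float, noise_free: bool, rho: float = 0.0
) -> int:
    if noise_free:
        return int(round(n * p))
    if rho > 0:  # beta-binomial with intraclass correlation rho
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        p = rng.beta(a, b)
    return int(rng.binomial(n, p))


def _exact_fraction_counts(p: Fraction, min_depth: int) -> tuple[int, int]:
    """Integer (ref, alt) with alt/(ref+alt) exactly p and depth >= min_depth."""
    scale = max(1, -(-min_depth // p.denominator))  # ceil division
    depth = p.denominator * scale
    alt = p.numerator * scale
    return depth - alt, alt


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate one patient's paired tumor-normal inputs plus ground truth.

    Deterministic for a given config (identical seed -> identical cohort).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pid = config.patient_id
    normal_id, low_id, high_id = f"{pid}_N", f"{pid}_L", f"{pid}_H"
    samples = [
        SampleMeta(normal_id, pid, Role.NORMAL, purity=1.0, mean_depth=config.mean_depth),
        SampleMeta(low_id, pid, Role.LOW_GRADE, purity=config.purity_low,
                   mean_depth=config.mean_depth),
        SampleMeta(high_id, pid, Role.HIGH_GRADE, purity=config.purity_high,
                   mean_depth=config.mean_depth),
    ]
    alpha = {low_id: config.purity_low, high_id: config.purity_high}
    role_of = {low_id: Role.LOW_GRADE, high_id: Role.HIGH_GRADE}

    # --- lay out segments: clone deletions first, then diploid reference ---
    chrom_cursor = 1
    regions: list[tuple[SegmentRecord, CloneSpec | None]] = []
    for clone in config.clones:
        for _ in range(clone.n_segments):
            if chrom_cursor > 22:
                raise ConfigError("too many segments for 22 synthetic chromosomes")
            seg = SegmentRecord(
                chrom=f"chr{chrom_cursor}",
                start=5_000_001,
                end=5_000_000 + clone.segment_length,
                copy_state=CopyState.HET_DELETION,
            )
            if seg.end > _CHROM_LENGTH:
                raise ConfigError("segment longer than synthetic chromosome")
            regions.append((seg, clone))
            chrom_cursor += 1
    for _ in range(config.n_reference_segments):
        if chrom_cursor > 22:
            raise ConfigError("too many segments for 22 synthetic chromosomes")
        seg = SegmentRecord(
            chrom=f"chr{chrom_cursor}",
            start=5_000_001,
            end=5_000_000 + config.reference_segment_length,
            copy_state=CopyState.DIPLOID,
        )
        regions.append((seg, None))
        chrom_cursor += 1

    # --- per-sample segment read totals ---
    segments_by_sample: dict[str, list[SegmentRecord]] = {low_id: [], high_id: []}
    truth_seg_fraction: dict[str, dict[str, float]] = {}
    truth_seg_clone: dict[str, str] = {}
    for seg, clone in regions:
        n_targets = seg.length / 1e6 * config.targets_per_mb
        for sample in (low_id, high_id):
            f = clone.fraction(role_of[sample]) if clone else 0.0
            copy = 2.0 - alpha[sample] * f
            tumor_reads = _poisson(
                rng, n_targets * config.mean_depth * copy / 2.0, config.noise_free
            )
            normal_reads = _poisson(rng, n_targets * config.mean_depth, config.noise_free)
            seg_s = SegmentRecord(
                chrom=seg.chrom, start=seg.start, end=seg.end,
                copy_state=seg.copy_state,
                tumor_reads=float(tumor_reads), normal_reads=float(normal_reads),
            )
            if config.noise_free:
                # expectation, not a Poisson draw: keep the exact ratio
                seg_s.tumor_reads = n_targets * config.mean_depth * copy / 2.0
                seg_s.normal_reads = n_targets * config.mean_depth
            segments_by_sample[sample].append(seg_s)
            truth_seg_fraction.setdefault(seg.key, {})[sample] = f
        truth_seg_clone[seg.key] = clone.clone_id if clone else "none"

    variants: list[VariantRecord] = []

    # --- germline het SNPs on every segment ---
    for seg, clone in regions:
        n_snps = int(round(seg.length / 1e6 * config.n_germline_snps_per_mb))
        positions = np.sort(
            rng.choice(np.arange(seg.start, seg.end + 1), size=n_snps, replace=False)
        )
        for pos in positions:
            counts: dict[str, tuple[int, int]] = {}
            dn = _poisson(rng, config.mean_depth, config.noise_free)
            alt_n = dn // 2 if config.noise_free else _binomial(rng, dn, 0.5, False)
            counts[normal_id] = (dn - alt_n, alt_n)
            alt_on_deleted = bool(rng.random() < 0.5)  # random phase per SNP
            for sample in (low_id, high_id):
                f = clone.fraction(role_of[sample]) if clone else 0.0
                a = alpha[sample]
                copy = 2.0 - a * f
                if config.noise_free:
                    p = 1 / (2 - Fraction(str(a)) * Fraction(str(f)))
                    if alt_on_deleted:
                        p = 1 - p
                    r, alt = _exact_fraction_counts(p, int(config.mean_depth))
                else:
                    baf = (copy - 1.0) / copy if alt_on_deleted else 1.0 / copy
                    d = _poisson(rng, config.mean_depth * copy / 2.0, False)
                    alt = _binomial(rng, d, baf, False, config.overdispersion)
                    r = d - alt
                counts[sample] = (r, alt)
            variants.append(
                VariantRecord(
                    chrom=seg.chrom, pos=int(pos), ref="A", alt="G",
                    counts=counts, category=Category.OTHER,
                )
            )

    # --- clone-private somatic SNVs ---
    truth_ccf: dict[str, dict[str, float]] = {}
    truth_clone: dict[str, str] = {}
    truth_cat: dict[str, str] = {}
    diploid_regions = [seg for seg, cl in regions if cl is None]
    if not diploid_regions:
        raise ConfigError("need at least one diploid reference segment")
    cats = list(_CATEGORY_WEIGHTS)
    cat_p = np.array([_CATEGORY_WEIGHTS[c] for c in cats])
    cat_p = cat_p / cat_p.sum()
    used_positions: set[tuple[str, int]] = set()
    for clone in config.clones:
        own_segments = [seg for seg, cl in regions if cl is clone]
        n_on_del = int(round(clone.n_private_snvs * clone.frac_snvs_on_deletion))
        for i in range(clone.n_private_snvs):
            on_deletion = i < n_on_del and own_segments
            host = (
                own_segments[i % len(own_segments)]
                if on_deletion
                else diploid_regions[i % len(diploid_regions)]
            )
            while True:
                pos = int(rng.integers(host.start, host.end + 1))
                if (host.chrom, pos) not in used_positions:
                    used_positions.add((host.chrom, pos))
                    break
            category = cats[int(rng.choice(len(cats), p=cat_p))]
            counts = {}
            dn = _poisson(rng, config.mean_depth, config.noise_free)
            err_alt = 0 if config.noise_free else _binomial(
                rng, dn, config.sequencing_error, False
            )
            counts[normal_id] = (dn - err_alt, err_alt)
            key = f"{host.chrom}:{pos}:C:T"
            truth_ccf[key] = {}
            for sample in (low_id, high_id):
                f_clone = clone.fraction(role_of[sample])
                a = alpha[sample]
                f_del = f_clone if on_deletion else 0.0
                copy = 2.0 - a * f_del
                vaf = a * f_clone * 1.0 / copy  # multiplicity 1, retained allele
                d = _poisson(rng, config.mean_depth * copy / 2.0, config.noise_free)
                alt = _binomial(rng, d, vaf, config.noise_free, config.overdispersion)
                counts[sample] = (d - alt, alt)
                truth_ccf[key][sample] = f_clone
            variants.append(
                VariantRecord(
                    chrom=host.chrom, pos=pos, ref="C", alt="T",
                    counts=counts, category=category,
                )
            )
            truth_clone[key] = clone.clone_id
            truth_cat[key] = category.value

    # --- RNA counts with configured fold changes ---
    expression: list[GeneExpressionRecord] = []
    gene_log2fc: dict[str, float] = {}
    lengths = np.clip(rng.lognormal(7.6, 0.6, config.n_genes), 200, 30000).astype(int)
    base = rng.lognormal(0.0, 1.0, config.n_genes)
    deg_idx = rng.choice(config.n_genes, size=config.n_deg_genes, replace=False)
    lfc = np.zeros(config.n_genes)
    signs = np.where(rng.random(config.n_deg_genes) < 0.75, 1.0, -1.0)
    lfc[deg_idx] = signs * (config.deg_log2fc + rng.normal(0, 0.5, config.n_deg_genes))
    rel_low = base * lengths / 1000.0  # expected reads scale with length
    rel_high = rel_low * 2.0 ** lfc
    for i in range(config.n_genes):
        gid = f"GENE{i:04d}"
        counts = {}
        for sample, rel, total in (
            (low_id, rel_low, rel_low.sum()),
            (high_id, rel_high, rel_high.sum()),
        ):
            lam = rel[i] / total * config.rna_library_size
            if config.noise_free:
                counts[sample] = int(round(lam))
            elif config.rna_dispersion > 0:
                shape = 1.0 / config.rna_dispersion
                counts[sample] = int(rng.poisson(rng.gamma(shape, lam / shape)))
            else:
                counts[sample] = int(rng.poisson(lam))
        expression.append(
            GeneExpressionRecord(gene_id=gid, length_bp=int(lengths[i]), counts=counts)
        )
        gene_log2fc[gid] = float(lfc[i])

    truth = SimTruth(
        segment_fraction=truth_seg_fraction,
        segment_clone=truth_seg_clone,
        snv_ccf=truth_ccf,
        snv_clone=truth_clone,
        snv_category=truth_cat,
        gene_log2fc=gene_log2fc,
        config={
            k: v for k, v in dataclasses.asdict(config).items() if k != "clones"
        } | {"clones": [dataclasses.asdict(c) for c in config.clones]},
    )
    return SimCohort(
        samples=samples,
        variants=variants,
        segments_by_sample=segments_by_sample,
        expression=expression,
        truth=truth,
    )


def spike_null_sites(
    n: int, depth: float = 150.0, vaf: float = 0.5, seed: int = 0
) -> list[VariantRecord]:
    """Truth-negative sites: tumor and normal alt counts from one binomial.

    Used to measure the somatic filter's empirical false-positive rate.
    """
    if n <= 0:
        raise ParameterError("n must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        counts = {}
        for sample in ("tumor", "normal"):
            d = int(rng.poisson(depth))
            a = int(rng.binomial(d, vaf)) if d > 0 else 0
            counts[sample] = (d - a, a)
        records.append(
            VariantRecord(
                chrom="chr1", pos=1000 + i, ref="A", alt="T",
                counts=counts, category=Category.OTHER,
            )
        )
    return records
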