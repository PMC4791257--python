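"""Readers and writers for the formats the pipeline touches.

Formats:

* variants — either VCF 4.x with per-sample ``AD`` ref/alt depths (read via
  pysam) or a flat TSV dialect with columns ``chrom, pos, ref, alt,
  sample_id, ref_count, alt_count, category`` and one row per
  sample-variant (optional ``is_somatic`` and ``ccf`` columns are carried
  through for pipeline hand-offs);
* copy-number segments — SEG-like TSV with columns ``chrom, start, end,
  copy_state`` plus optional ``tumor_reads``/``normal_reads`` coverage
  totals;
* gene sets — standard GMT (name, description, members);
* expression — TSV with ``gene_id, length_bp`` and one counts column per
  sample.

Coordinates are 1-based inclusive everywhere.  Chromosome names are
normalized to the ``chr`` prefix on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

from .errors import ParseError, SchemaError, ValidationError
from .types import (
    Category,
    CopyState,
    GeneExpressionRecord,
    GeneSet,
    Role,
    SampleMeta,
    SegmentRecord,
    VariantRecord,
    normalize_chrom,
)

log = logging.getLogger(__name__)

_CATEGORY_ALIASES = {
    "missense": Category.MISSENSE,
    "missense_variant": Category.MISSENSE,
    "start_lost": Category.START_LOST,
    "start lost": Category.START_LOST,
    "stop_gain": Category.STOP_GAIN,
    "stop_gained": Category.STOP_GAIN,
    "stop gain": Category.STOP_GAIN,
    "stop_loss": Category.STOP_LOSS,
    "stop_lost": Category.STOP_LOSS,
    "stop loss": Category.STOP_LOSS,
    "codon_indel": Category.CODON_INDEL,
    "codon indel": Category.CODON_INDEL,
    "inframe_indel": Category.CODON_INDEL,
    "frameshift": Category.FRAMESHIFT,
    "frame_shift": Category.FRAMESHIFT,
    "frame shift": Category.FRAMESHIFT,
    "other": Category.OTHER,
}


def parse_category(text: str) -> Category:
    """Map a consequence string to a category; unknown strings warn -> OTHER."""
    key = str(text).strip().lower()
    if key in _CATEGORY_ALIASES:
        return _CATEGORY_ALIASES[key]
    log.warning("unknown consequence category %r mapped to 'other'", text)
    return Category.OTHER


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (int(body), "") if body.isdigit() else (10**6, body)


def sort_variants(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    return sorted(records, key=lambda v: (_chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))


# ---------------------------------------------------------------------------
# variants


def _parse_bool(x) -> bool:
    return str(x).strip().lower() in {"1", "true", "yes"}


def read_variants(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read a variant table; records are sorted by genomic position.

    ``dialect='tsv'`` reads the flat per-sample-row dialect; ``'vcf'`` reads
    VCF with per-sample AD depths.  Rows for the same (chrom, pos, ref, alt)
    key are merged into one :class:`VariantRecord` with per-sample counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown variant dialect {dialect!r}")


_VAR_REQUIRED = ["chrom", "pos", "ref", "alt", "sample_id", "ref_count", "alt_count"]


def _read_variants_tsv(path: Path) -> list[VariantRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _VAR_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records: dict[tuple[str, int, str, str], VariantRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            pos = int(row.pos)
            r, a = int(row.ref_count), int(row.alt_count)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {i}: non-integer field ({exc})") from exc
        if r < 0 or a < 0:
            raise SchemaError(f"{path}: line {i}: negative read count ({r}, {a})")
        chrom = normalize_chrom(row.chrom)
        key = (chrom, pos, str(row.ref), str(row.alt))
        rec = records.get(key)
        if rec is None:
            cat = parse_category(row.category) if hasattr(row, "category") else Category.OTHER
            rec = VariantRecord(chrom=chrom, pos=pos, ref=key[2], alt=key[3], category=cat)
            records[key] = rec
        sample = str(row.sample_id)
        rec.counts[sample] = (r, a)
        if hasattr(row, "is_somatic") and not pd.isna(row.is_somatic):
            rec.is_somatic[sample] = _parse_bool(row.is_somatic)
        if hasattr(row, "ccf") and not pd.isna(row.ccf) and str(row.ccf) != "":
            rec.ccf[sample] = float(row.ccf)
    return sort_variants(records.values())


def write_variants(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write the flat TSV dialect, one row per sample-variant."""
    rows = []
    for rec in sort_variants(records):
        for sample in sorted(rec.counts):
            r, a = rec.counts[sample]
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "sample_id": sample,
                    "ref_count": r,
                    "alt_count": a,
                    "category": rec.category.value,
                    "is_somatic": (
                        str(rec.is_somatic[sample]).lower()
                        if sample in rec.is_somatic
                        else ""
                    ),
                    "ccf": (
                        f"{rec.ccf[sample]:.6g}" if sample in rec.ccf else ""
                    ),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "sample_id",
            "ref_count", "alt_count", "category", "is_somatic", "ccf",
        ],
    ).to_csv(path, sep="\t", index=False)


def _read_variants_vcf(path: Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for line_no, rec in enumerate(vf.fetch() if vf.index else vf, start=1):
            for alt_i, alt in enumerate(rec.alts or ()):  # decompose multi-allelic
                counts: dict[str, tuple[int, int]] = {}
                for s in samples:
                    ad = rec.samples[s].get("AD")
                    if ad is None or ad[0] is None:
                        raise SchemaError(
                            f"{path}: record {rec.chrom}:{rec.pos} sample {s}: "
                            "missing AD field"
                        )
                    counts[s] = (int(ad[0]), int(ad[alt_i + 1]))
                cat = rec.info.get("CATEGORY")
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        counts=counts,
                        category=parse_category(cat) if cat else Category.OTHER,
                    )
                )
    return sort_variants(records)


def write_variants_vcf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write a minimal VCF 4.2 with per-sample AD depths."""
    records = sort_variants(records)
    samples = sorted({s for rec in records for s in rec.counts})
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CATEGORY,Number=1,Type=String,Description="Consequence category">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    chroms = []
    for rec in records:
        if rec.chrom not in chroms:
            chroms.append(rec.chrom)
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for rec in records:
        fields = [
            rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".", ".",
            f"CATEGORY={rec.category.value}", "AD",
        ]
        for s in samples:
            if s in rec.counts:
                r, a = rec.counts[s]
                fields.append(f"{r},{a}")
            else:
                fields.append(".,.")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# segments

_SEG_COLS = ["chrom", "start", "end", "copy_state"]


def read_segments(path: str | Path) -> list[SegmentRecord]:
    """Read a SEG-like TSV into validated, non-overlapping segments."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _SEG_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    segments: list[SegmentRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            seg = SegmentRecord(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                copy_state=CopyState(str(row.copy_state)),
                tumor_reads=float(row.tumor_reads) if hasattr(row, "tumor_reads") and not pd.isna(row.tumor_reads) else None,
                normal_reads=float(row.normal_reads) if hasattr(row, "normal_reads") and not pd.isna(row.normal_reads) else None,
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}: line {i}: {exc}") from exc
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
        segments.append(seg)
    segments.sort(key=lambda s: (_chrom_sort_key(s.chrom), s.start))
    for prev, cur in zip(segments, segments[1:]):
        if prev.chrom == cur.chrom and cur.start <= prev.end:
            raise ValidationError(
                f"{path}: overlapping segments {prev.key} and {cur.key}"
            )
    return segments


def write_segments(segments: Iterable[SegmentRecord], path: str | Path) -> None:
    rows = []
    for s in sorted(segments, key=lambda s: (_chrom_sort_key(s.chrom), s.start)):
        rows.append(
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "copy_state": s.copy_state.value,
                "tumor_reads": s.tumor_reads,
                "normal_reads": s.normal_reads,
            }
        )
    pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_state", "tumor_reads", "normal_reads"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name, description, then members, tab-separated.

    Duplicate members are deduplicated; sets left empty after dedup are
    dropped with a warning.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {i}: GMT line needs >= 3 fields, got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            members = {m.strip() for m in fields[2:] if m.strip()}
            if not members:
                log.warning("%s: line %d: empty gene set %r dropped", path, i, name)
                continue
            sets.append(GeneSet(name=name, members=frozenset(members), description=desc))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# expression counts


def read_expression(path: str | Path) -> list[GeneExpressionRecord]:
    """Read a counts TSV: gene_id, length_bp, one column per sample."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("gene_id", "length_bp"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("gene_id", "length_bp")]
    if not sample_cols:
        raise SchemaError(f"{path}: no sample count columns")
    records = []
    for row in df.itertuples(index=False):
        counts = {s: int(getattr(row, s)) for s in sample_cols}
        records.append(
            GeneExpressionRecord(
                gene_id=str(row.gene_id), length_bp=int(row.length_bp), counts=counts
            )
        )
    return records


def write_expression(records: Iterable[GeneExpressionRecord], path: str | Path) -> None:
    records = list(records)
    samples = sorted({s for r in records for s in r.counts})
    rows = [
        {"gene_id": r.gene_id, "length_bp": r.length_bp, **{s: r.counts.get(s, 0) for s in samples}}
        for r in records
    ]
    pd.DataFrame(rows, columns=["gene_id", "length_bp", *samples]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# sample metadata


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read a sample sheet TSV: sample_id, patient_id, role, purity, ploidy,
    mean_depth, optional norm_reads."""
    df = pd.read_csv(path, sep="\t")
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                patient_id=str(row.patient_id),
                role=Role(str(row.role)),
                purity=float(row.purity),
                ploidy=float(row.ploidy) if hasattr(row, "ploidy") else 2.0,
                mean_depth=float(row.mean_depth) if hasattr(row, "mean_depth") else 150.0,
                norm_reads=float(row.norm_reads) if hasattr(row, "norm_reads") and not pd.isna(row.norm_reads) else None,
            )
        )
    by_patient: dict[str, int] = {}
    for m in metas:
        if m.role is Role.NORMAL:
            by_patient[m.patient_id] = by_patient.get(m.patient_id, 0) + 1
    for patient, n in by_patient.items():
        if n != 1:
            raise ValidationError(f"patient {patient} has {n} normal samples (need 1)")
    return metas


def write_sample_meta(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "patient_id": m.patient_id,
            "role": m.role.value,
            "purity": m.purity,
            "ploidy": m.ploidy,
            "mean_depth": m.mean_depth,
            "norm_reads": m.norm_reads,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def segments_to_bed(segments: Iterable[SegmentRecord], path: str | Path) -> None:
    """Export segments as BED (0-based half-open at this boundary only)."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.copy_state.value}\n")
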