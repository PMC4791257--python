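"""Domain types shared across the pipeline.

The pipeline analyses paired low-grade / high-grade tumor samples with a
matched normal from the same patient.  Conventions used throughout:

* genomic coordinates are 1-based and inclusive on both ends;
* ``purity`` (alpha) is the fraction of cells in a tumor sample that are
  cancer cells;
* cellular fractions ``f`` and cancer-cell fractions (CCF) are fractions of
  *tumor* cells, not of all cells — purity enters the observation model
  instead;
* mirrored (folded) B-allele frequency maps a germline-het VAF ``v`` to
  ``max(v, 1 - v)`` in ``[0.5, 1]``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .errors import ParameterError, SchemaError


class Role(str, enum.Enum):
    """Timepoint role of a sample within a patient."""

    NORMAL = "normal"
    LOW_GRADE = "low_grade"
    HIGH_GRADE = "high_grade"


class Category(str, enum.Enum):
    """Nonsynonymous consequence categories tallied per sample."""

    MISSENSE = "missense"
    START_LOST = "start_lost"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    CODON_INDEL = "codon_indel"
    FRAMESHIFT = "frameshift"
    OTHER = "other"


class CopyState(str, enum.Enum):
    """Allele-specific copy state of a segment."""

    DIPLOID = "diploid"
    HET_DELETION = "het_deletion"
    OTHER = "other"


def normalize_chrom(chrom: str) -> str:
    """Normalize chromosome names to the ``chr``-prefixed convention."""
    chrom = str(chrom).strip()
    if not chrom:
        raise SchemaError("empty chromosome name")
    return chrom if chrom.lower().startswith("chr") else f"chr{chrom}"


@dataclass
class SampleMeta:
    """Per-sample metadata: identity, timepoint role, purity and ploidy.

    ``purity`` is the ASCAT-style tumor purity alpha in (0, 1]; ``ploidy``
    the genome-average copy number.  ``norm_reads`` optionally carries the
    library-size normalization total (autosomal reads outside candidate
    deletion segments) used for depth ratios.
    """

    sample_id: str
    patient_id: str
    role: Role
    purity: float
    ploidy: float = 2.0
    mean_depth: float = 150.0
    norm_reads: float | None = None

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        if not (0.0 < self.purity <= 1.0):
            raise ParameterError(
                f"purity must be in (0, 1], got {self.purity} for {self.sample_id}"
            )
        if self.ploidy <= 0:
            raise ParameterError(f"ploidy must be > 0, got {self.ploidy}")
        if self.mean_depth <= 0:
            raise ParameterError(f"mean_depth must be > 0, got {self.mean_depth}")


@dataclass
class VariantRecord:
    """One bi-allelic variant with per-sample read support.

    ``counts`` maps sample_id to ``(ref_count, alt_count)``.  ``is_somatic``
    and ``ccf`` are per-tumor-sample; CCF is defined only for somatic
    variants on diploid or het-deletion segments.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    category: Category = Category.OTHER
    is_somatic: dict[str, bool] = field(default_factory=dict)
    ccf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.pos = int(self.pos)
        if self.pos < 1:
            raise SchemaError(f"position must be 1-based positive, got {self.pos}")
        self.category = Category(self.category)
        for sample, (r, a) in self.counts.items():
            if r < 0 or a < 0:
                raise SchemaError(
                    f"negative read count ({r}, {a}) for sample {sample} "
                    f"at {self.chrom}:{self.pos}"
                )
            self.counts[sample] = (int(r), int(a))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def depth(self, sample_id: str) -> int:
        r, a = self.counts[sample_id]
        return r + a

    def vaf(self, sample_id: str) -> float:
        """Variant allele fraction alt/(ref+alt); NaN at zero depth."""
        r, a = self.counts[sample_id]
        return a / (r + a) if (r + a) > 0 else math.nan


@dataclass
class SegmentRecord:
    """A copy-number segment with its deleted-clone fraction estimates.

    ``depth_ratio`` is the library-size-normalized tumor/normal coverage
    ratio R within the segment; ``baf_major`` the median folded BAF M of
    qualified germline het SNPs.  ``f_depth``/``f_baf``/``f_combined`` are
    the tumor-cell fractions carrying the deletion inferred from each
    information source and their combination.
    """

    chrom: str
    start: int
    end: int
    copy_state: CopyState
    depth_ratio: float | None = None
    baf_major: float | None = None
    n_het_snps: int = 0
    f_depth: float | None = None
    f_baf: float | None = None
    f_combined: float | None = None
    discordant: bool = False
    group_id: str | None = None
    tumor_reads: float | None = None
    normal_reads: float | None = None

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start < 1:
            raise SchemaError(f"start must be 1-based positive, got {self.start}")
        if self.end < self.start:
            raise SchemaError(
                f"segment end < start: {self.chrom}:{self.start}-{self.end}"
            )
        self.copy_state = CopyState(self.copy_state)
        if self.baf_major is not None and not (0.5 <= self.baf_major <= 1.0):
            raise SchemaError(f"baf_major must be in [0.5, 1], got {self.baf_major}")

    @property
    def length(self) -> int:
        """Segment length in bp (1-based inclusive coordinates)."""
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == normalize_chrom(chrom) and self.start <= pos <= self.end


@dataclass
class GeneExpressionRecord:
    """One gene's counts, RPKM values and fold-change call."""

    gene_id: str
    length_bp: int
    counts: dict[str, int] = field(default_factory=dict)
    rpkm: dict[str, float] = field(default_factory=dict)
    log2fc: float | None = None
    is_deg: bool = False

    def __post_init__(self) -> None:
        self.length_bp = int(self.length_bp)
        if self.length_bp <= 0:
            raise SchemaError(f"gene length must be > 0 for {self.gene_id}")
        for sample, c in self.counts.items():
            if c < 0:
                raise SchemaError(f"negative count for {self.gene_id}/{sample}")
            self.counts[sample] = int(c)


@dataclass
class GeneSet:
    """A named collection of gene identifiers (GMT row)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise SchemaError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class FisherResult:
    """Outcome of the tumor-normal exact somatic test."""

    p_value: float
    odds_ratio: float
    is_somatic: bool


@dataclass
class SubcloneGroup:
    """A cluster of segments and/or SNVs sharing a cellular fraction.

    ``fraction_by_sample`` maps sample_id to the group centroid fraction;
    samples where the lesion is absent are simply missing from the mapping.
    """

    group_id: str
    member_segments: list[str] = field(default_factory=list)
    member_snvs: list[tuple[str, int, str, str]] = field(default_factory=list)
    fraction_by_sample: dict[str, float] = field(default_factory=dict)

    @property
    def members(self) -> list:
        return list(self.member_segments) + list(self.member_snvs)


class DynStatus(str, enum.Enum):
    """Fate of a somatic mutation between the two tumor timepoints."""

    NEWLY_DEVELOPED = "newly_developed"
    DISAPPEARED = "disappeared"
    PRESERVED = "preserved"
    UNASSESSABLE = "unassessable"


@dataclass(frozen=True)
class DynamicsRecord:
    """Per-variant longitudinal classification."""

    key: tuple[str, int, str, str]
    status: DynStatus


class CloneRole(str, enum.Enum):
    """Longitudinal role of a subclone."""

    TRUNK = "trunk"  # present at both timepoints
    EXTINCT = "extinct"  # low-grade only
    EMERGENT = "emergent"  # high-grade only


@dataclass
class CloneNode:
    group_id: str
    role: CloneRole
    fraction_by_sample: dict[str, float]
    parent: str | None = None


@dataclass
class EvolutionModel:
    """Clonal-evolution model: clone roles plus a containment partial order.

    ``violations`` lists pigeonhole problems (sibling fractions summing
    above 1, or a child exceeding its parent) that were detected but not
    silently repaired.
    """

    clones: list[CloneNode]
    violations: list[str] = field(default_factory=list)

    def clone(self, group_id: str) -> CloneNode:
        for c in self.clones:
            if c.group_id == group_id:
                return c
        raise KeyError(group_id)


@dataclass(frozen=True)
class GeneSetOverlap:
    """One gene set's overlap statistics with a query gene list."""

    set_name: str
    K: int
    k: int
    ratio: float
    p_value: float
    q_value: float | None = None
    es: float | None = None  # pass-through metadata when present in input
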