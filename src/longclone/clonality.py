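"""Subclonal fraction inference from heterozygous deletions and somatic SNVs.

Observation model
-----------------
A heterozygous deletion carried by a fraction ``f`` of tumor cells in a
sample of purity ``alpha`` leaves the locus with expected mean copy number

    c = 2 - alpha * f

(normal cells and unaffected tumor cells contribute 2 copies, deleted tumor
cells 1).  Two observable consequences, each inverted for ``f``:

* the library-size-normalized tumor/normal depth ratio is ``R = c / 2``,
  so ``f = 2 (1 - R) / alpha``;
* a germline het SNP on the segment has retained-allele frequency
  ``M = 1 / c`` (the deleted allele mirrors to ``1 - M``), so
  ``f = (2 M - 1) / (alpha * M)``.

For a somatic SNV present in a tumor-cell fraction ``CCF`` with mutation
multiplicity 1, the expected VAF is ``alpha * CCF / c``; on diploid loci
``c = 2`` giving ``CCF = 2 v / alpha``, and on het-deletion segments with
the mutation on the retained allele ``CCF = v (2 - alpha f_del) / alpha``.

All fractions are of *tumor* cells and are clipped to [0, 1].

Grouping
--------
Segments (and, separately, SNVs) are clustered on their per-sample fraction
vectors by average-linkage agglomeration with a chord distance of
``max |delta f|`` over shared samples; items with disjoint sample support
never merge.  Merging stops when the closest pair of clusters is farther
apart than ``merge_threshold`` (default 0.10).  Groups are named
``S<pattern>.<rank>`` where the pattern indexes timepoint presence
(1 = both timepoints, 2 = low-grade only, 3 = high-grade only) and the rank
orders groups within a pattern by descending fraction.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InsufficientDataError, ParameterError
from .somatic_filter import qualify_germline_het
from .types import CopyState, SegmentRecord, SubcloneGroup, VariantRecord

MIN_SEGMENT_LENGTH = 10_000_000  # bp; "greater than" is strict
MERGE_THRESHOLD = 0.10
DISCORDANCE_THRESHOLD = 0.2

_SEX_CHROMS = {"chrX", "chrY"}


def select_hetdel_segments(
    segments: Iterable[SegmentRecord], min_length: int = MIN_SEGMENT_LENGTH
) -> list[SegmentRecord]:
    """Keep heterozygous-deletion segments strictly longer than ``min_length``."""
    return [
        s
        for s in segments
        if s.copy_state is CopyState.HET_DELETION and s.length > min_length
    ]


def depth_ratio(
    tumor_count: float, normal_count: float, tumor_norm: float, normal_norm: float
) -> float:
    """Library-size-normalized tumor/normal coverage ratio within a segment.

    ``tumor_norm``/``normal_norm`` are total reads over autosomal reference
    regions (regions not overlapping any candidate deletion segment).
    R = 1 under no copy change; R < 1 indicates copy loss.
    """
    if min(tumor_count, normal_count, tumor_norm, normal_norm) <= 0:
        raise ParameterError("all read counts must be positive")
    return (tumor_count / tumor_norm) / (normal_count / normal_norm)


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha <= 1.0):
        raise ParameterError(f"purity must be in (0, 1], got {alpha}")


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def fraction_from_depth(R: float, alpha: float) -> float:
    """Deleted-clone fraction from the depth ratio: f = 2(1 - R)/alpha."""
    if R <= 0:
        raise ParameterError(f"depth ratio must be > 0, got {R}")
    _check_alpha(alpha)
    return _clip01(2.0 * (1.0 - R) / alpha)


def mirrored_baf(het_snp_vafs: Sequence[float]) -> float:
    """Median folded BAF, max(v, 1-v), of germline het SNPs on a segment."""
    vafs = [v for v in het_snp_vafs if v == v]  # drop NaN (zero-depth sites)
    if not vafs:
        raise InsufficientDataError("no informative het SNPs on segment")
    if any(not (0.0 <= v <= 1.0) for v in vafs):
        raise ParameterError("VAFs must be in [0, 1]")
    return statistics.median(max(v, 1.0 - v) for v in vafs)


def debias_folded_median(M: float, sigma: float, n_snps: int | None = None) -> float:
    """Remove the binomial-noise bias from a folded-BAF median.

    Folding VAFs at 0.5 inflates the median when the true allelic
    imbalance delta = M_true - 0.5 is comparable to the per-SNP noise
    sigma: for a balanced segment (delta = 0) the folded median sits at
    0.5 + 0.674 sigma, not 0.5.  Given the observed folded median M and
    sigma, this inverts the folded-normal median relation

        P(|X| <= m) = 1/2,   X ~ Normal(delta, sigma)

    for delta and returns 0.5 + delta.  Monotone, deterministic, and the
    identity when sigma = 0.

    The inversion is steep near the noise floor, so small sampling
    fluctuations of the median would otherwise map to sizeable spurious
    imbalances.  When ``n_snps`` is given, a detection limit is applied:
    medians within three standard errors (1.2533 sigma / sqrt(n)) of the
    balanced-segment floor are reported as no imbalance (0.5).
    """
    from scipy import optimize, stats  # local: keep module import light

    if sigma <= 0:
        return M
    m = M - 0.5
    floor = 0.6745 * sigma
    if n_snps is not None:
        floor += 3.0 * 1.2533 * sigma / math.sqrt(n_snps)
        if m <= floor:
            return 0.5

    def half_mass(delta: float) -> float:
        return (
            stats.norm.cdf((m - delta) / sigma)
            - stats.norm.cdf((-m - delta) / sigma)
            - 0.5
        )

    # half_mass is decreasing in delta; delta=0 gives max mass
    if half_mass(0.0) <= 0.0:  # observed median within pure-noise range
        return 0.5
    delta = optimize.brentq(half_mass, 0.0, m + 6 * sigma)
    return 0.5 + min(delta, 0.5)


def fraction_from_baf(M: float, alpha: float) -> float:
    """Deleted-clone fraction from folded BAF: f = (2M - 1)/(alpha M)."""
    if not (0.5 <= M <= 1.0):
        raise ParameterError(f"folded BAF must be in [0.5, 1], got {M}")
    _check_alpha(alpha)
    return _clip01((2.0 * M - 1.0) / (alpha * M))


def combine_fractions(
    f_depth: float,
    f_baf: float | None,
    discordance_threshold: float = DISCORDANCE_THRESHOLD,
) -> tuple[float, bool]:
    """Average the depth- and BAF-based estimates; flag large disagreement.

    Returns ``(f_combined, discordant)``.  When the BAF estimate is
    unavailable the depth estimate is used alone and never flagged.
    """
    if f_baf is None:
        return f_depth, False
    return (f_depth + f_baf) / 2.0, abs(f_depth - f_baf) > discordance_threshold


def snv_ccf(
    vaf: float,
    alpha: float,
    copy_state: CopyState,
    f_del: float | None = None,
    on_deleted_allele: bool = False,
) -> float | None:
    """Cancer-cell fraction of a somatic SNV given the local copy state.

    Only diploid and het-deletion loci are evaluated; any other copy state
    returns None (CCF undefined).  On het-deletion segments the mutation is
    assumed on the retained haplotype with multiplicity 1 unless
    ``on_deleted_allele`` is set, in which case cells carrying the deletion
    are assumed to have lost the mutant copy.
    """
    if not (0.0 <= vaf <= 1.0):
        raise ParameterError(f"VAF must be in [0, 1], got {vaf}")
    _check_alpha(alpha)
    if copy_state is CopyState.DIPLOID:
        return _clip01(2.0 * vaf / alpha)
    if copy_state is CopyState.HET_DELETION:
        if f_del is None:
            raise ParameterError("f_del required for het-deletion loci")
        c = 2.0 - alpha * f_del
        if on_deleted_allele:
            return _clip01(vaf * c / alpha + f_del)
        return _clip01(vaf * c / alpha)
    return None


# ---------------------------------------------------------------------------
# segment-level estimation driver


def reference_read_totals(
    segments: Sequence[SegmentRecord],
) -> tuple[float, float]:
    """Sum tumor/normal reads over autosomal non-candidate (diploid) segments.

    Sex chromosomes are excluded because their baseline copy number differs.
    """
    candidates = {s.key for s in select_hetdel_segments(segments)}
    t = n = 0.0
    for s in segments:
        if s.key in candidates or s.chrom in _SEX_CHROMS:
            continue
        if s.copy_state is CopyState.DIPLOID and s.tumor_reads and s.normal_reads:
            t += s.tumor_reads
            n += s.normal_reads
    if t <= 0 or n <= 0:
        raise InsufficientDataError("no reference regions with read counts")
    return t, n


def segment_het_vafs(
    segment: SegmentRecord,
    variants: Iterable[VariantRecord],
    tumor_sample: str,
    normal_sample: str,
) -> list[tuple[float, int]]:
    """Tumor (VAF, depth) of qualified germline-het SNPs inside a segment.

    A SNP qualifies when its normal-sample VAF lies in [0.3, 0.7] and it is
    not flagged somatic in the tumor.
    """
    vafs = []
    for v in variants:
        if v.is_somatic.get(tumor_sample, False):
            continue
        if normal_sample not in v.counts or tumor_sample not in v.counts:
            continue
        if not segment.contains(v.chrom, v.pos):
            continue
        nvaf = v.vaf(normal_sample)
        if nvaf != nvaf or not qualify_germline_het(nvaf):
            continue
        tvaf = v.vaf(tumor_sample)
        if tvaf == tvaf:
            vafs.append((tvaf, v.depth(tumor_sample)))
    return vafs


def estimate_segment_fractions(
    segments: Sequence[SegmentRecord],
    variants: Sequence[VariantRecord],
    tumor_sample: str,
    normal_sample: str,
    alpha: float,
    min_length: int = MIN_SEGMENT_LENGTH,
    discordance_threshold: float = DISCORDANCE_THRESHOLD,
) -> list[SegmentRecord]:
    """Estimate the deleted-clone fraction for each candidate segment.

    Fills ``depth_ratio``, ``baf_major``, ``n_het_snps``, ``f_depth``,
    ``f_baf``, ``f_combined`` and ``discordant`` in place on the selected
    het-deletion segments and returns them.
    """
    selected = select_hetdel_segments(segments, min_length)
    tumor_norm, normal_norm = reference_read_totals(segments)
    for seg in selected:
        if seg.tumor_reads is None or seg.normal_reads is None:
            raise InsufficientDataError(f"segment {seg.key} lacks read counts")
        seg.depth_ratio = depth_ratio(
            seg.tumor_reads, seg.normal_reads, tumor_norm, normal_norm
        )
        seg.f_depth = fraction_from_depth(seg.depth_ratio, alpha)
        pairs = segment_het_vafs(seg, variants, tumor_sample, normal_sample)
        seg.n_het_snps = len(pairs)
        try:
            raw_m = mirrored_baf([v for v, _ in pairs])
            depths = [d for _, d in pairs if d > 0]
            sigma = (
                math.sqrt(raw_m * (1 - raw_m) * sum(1 / d for d in depths) / len(depths))
                if depths
                else 0.0
            )
            seg.baf_major = debias_folded_median(raw_m, sigma, n_snps=len(depths))
            seg.f_baf = fraction_from_baf(seg.baf_major, alpha)
        except InsufficientDataError:
            seg.baf_major = None
            seg.f_baf = None
        seg.f_combined, seg.discordant = combine_fractions(
            seg.f_depth, seg.f_baf, discordance_threshold
        )
    return selected


# ---------------------------------------------------------------------------
# clustering


@dataclass
class _Cluster:
    keys: list
    fractions: list[Mapping[str, float]]


def _item_distance(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    shared = set(a) & set(b)
    if not shared:
        return float("inf")
    return max(abs(a[s] - b[s]) for s in shared)


def cluster_fractions(
    items: Sequence[tuple[object, Mapping[str, float]]],
    merge_threshold: float = MERGE_THRESHOLD,
    sort_sample: str | None = None,
) -> list[SubcloneGroup]:
    """Group items (segments or SNVs) by their per-sample cellular fractions.

    ``items`` are ``(key, {sample_id: fraction})`` pairs; fractions are
    defined only in samples where the lesion is present.  Average-linkage
    agglomeration with distance ``max |delta f|`` over shared samples; pairs
    with disjoint sample support are at infinite distance and never merge.
    Merging stops when the minimum inter-cluster distance exceeds
    ``merge_threshold``.  The result is deterministic and independent of
    input order; groups are sorted by descending fraction in
    ``sort_sample`` (or descending maximum fraction when unset) and get
    provisional ids ``G1, G2, ...`` — use :func:`name_groups` for the
    presence-pattern naming.
    """
    if not items:
        return []
    for key, fr in items:
        if not fr:
            raise ParameterError(f"item {key!r} has no defined fractions")
        for s, f in fr.items():
            if not (0.0 <= f <= 1.0):
                raise ParameterError(f"fraction {f} for {key!r}/{s} outside [0, 1]")
    # canonical input order for determinism
    ordered = sorted(items, key=lambda kv: str(kv[0]))
    clusters = [_Cluster(keys=[k], fractions=[dict(f)]) for k, f in ordered]

    def linkage(ca: _Cluster, cb: _Cluster) -> float:
        ds = [_item_distance(a, b) for a in ca.fractions for b in cb.fractions]
        return sum(ds) / len(ds)  # inf pairs propagate: disjoint support never merges

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = linkage(clusters[i], clusters[j])
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        if best is None or best[0] > merge_threshold:
            break
        _, i, j = best
        clusters[i] = _Cluster(
            keys=clusters[i].keys + clusters[j].keys,
            fractions=clusters[i].fractions + clusters[j].fractions,
        )
        del clusters[j]

    groups = []
    for c in clusters:
        samples = sorted({s for f in c.fractions for s in f})
        centroid = {
            s: statistics.mean(f[s] for f in c.fractions if s in f) for s in samples
        }
        seg_keys = [k for k in c.keys if isinstance(k, str)]
        snv_keys = [k for k in c.keys if not isinstance(k, str)]
        groups.append(
            SubcloneGroup(
                group_id="",
                member_segments=sorted(seg_keys),
                member_snvs=sorted(snv_keys),
                fraction_by_sample=centroid,
            )
        )

    def sort_val(g: SubcloneGroup) -> float:
        if sort_sample is not None:
            return g.fraction_by_sample.get(sort_sample, -1.0)
        return max(g.fraction_by_sample.values())

    groups.sort(key=lambda g: (-sort_val(g), g.member_segments, g.member_snvs))
    for i, g in enumerate(groups, start=1):
        g.group_id = f"G{i}"
    return groups


def snv_fraction_by_group(
    seg_groups: Sequence[SubcloneGroup],
    snv_groups: Sequence[SubcloneGroup],
    max_distance: float = 0.25,
) -> dict[str, tuple[dict[str, float], int]]:
    """SNV-based fraction estimate for each segment-defined subclone group.

    Per-SNV CCFs at WES depth carry binomial noise comparable to the merge
    threshold, so threshold clustering fragments a clone's SNVs into
    several groups whose individual centroids are truncation-biased.
    Pooling repairs this: every SNV group is assigned to the segment group
    with the nearest centroid (Chebyshev distance over samples, absent
    fractions read as 0), and each segment group's SNV-based fraction is
    the size-weighted mean of its assigned SNV-group centroids — an
    unbiased per-clone estimate whose error shrinks with the SNV count.
    SNV groups farther than ``max_distance`` from every segment group are
    left unassigned: they are SNV-only subclones (no deletion lesions) and
    must not drag another clone's centroid.
    Returns ``{segment_group_id: (fraction_by_sample, n_snvs)}``.
    """
    def dist(a: Mapping[str, float], b: Mapping[str, float]) -> float:
        samples = set(a) | set(b)
        return max(abs(a.get(s, 0.0) - b.get(s, 0.0)) for s in samples)

    pooled: dict[str, list[SubcloneGroup]] = {g.group_id: [] for g in seg_groups}
    for sg in snv_groups:
        host = min(
            seg_groups,
            key=lambda g: (dist(g.fraction_by_sample, sg.fraction_by_sample), g.group_id),
        )
        if dist(host.fraction_by_sample, sg.fraction_by_sample) <= max_distance:
            pooled[host.group_id].append(sg)
    out: dict[str, tuple[dict[str, float], int]] = {}
    for g in seg_groups:
        members = pooled[g.group_id]
        n = sum(len(sg.member_snvs) for sg in members)
        if n == 0:
            continue
        samples = sorted({s for sg in members for s in sg.fraction_by_sample})
        centroid = {
            s: sum(
                sg.fraction_by_sample.get(s, 0.0) * len(sg.member_snvs)
                for sg in members
            )
            / n
            for s in samples
        }
        out[g.group_id] = (centroid, n)
    return out


def prune_absent_fractions(
    groups: Sequence[SubcloneGroup], presence_min: float = 0.05
) -> list[SubcloneGroup]:
    """Drop per-sample centroid fractions below ``presence_min``.

    Estimation assigns every segment a fraction in every tumor sample; a
    near-zero estimate means the lesion is absent there, which the naming
    convention and the evolution model encode as an undefined fraction.
    """
    for g in groups:
        g.fraction_by_sample = {
            s: f for s, f in g.fraction_by_sample.items() if f >= presence_min
        }
    return [g for g in groups if g.fraction_by_sample]


def name_groups(
    groups: Sequence[SubcloneGroup], timepoints: Sequence[str]
) -> list[SubcloneGroup]:
    """Assign deterministic ``S<pattern>.<rank>`` ids by timepoint presence.

    ``timepoints`` lists the tumor sample ids in chronological order (low
    grade first).  Patterns: present at every timepoint -> 1; first
    timepoint only -> 2; last timepoint only -> 3.  Rank orders groups in a
    pattern by descending fraction at the latest timepoint where present.
    Idempotent.
    """
    def pattern(g: SubcloneGroup) -> int:
        present = [t for t in timepoints if t in g.fraction_by_sample]
        if len(present) == len(timepoints):
            return 1
        if present == [timepoints[0]]:
            return 2
        return 3

    def last_fraction(g: SubcloneGroup) -> float:
        for t in reversed(timepoints):
            if t in g.fraction_by_sample:
                return g.fraction_by_sample[t]
        return 0.0

    named = list(groups)
    by_pattern: dict[int, list[SubcloneGroup]] = {}
    for g in named:
        by_pattern.setdefault(pattern(g), []).append(g)
    for pat, members in by_pattern.items():
        members.sort(key=lambda g: (-last_fraction(g), g.member_segments, g.member_snvs))
        for rank, g in enumerate(members, start=1):
            g.group_id = f"S{pat}.{rank}"
    named.sort(key=lambda g: g.group_id)
    return named
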