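"""Longitudinal mutation dynamics and the clonal-evolution model.

Each somatic mutation is classified by its fate between the low-grade and
high-grade timepoints: *preserved* (called somatic in both), *newly
developed* (absent from low grade, present in high grade), *disappeared*
(present in low grade, absent from high grade).  Absence is only asserted
when the site is covered by at least ``min_depth`` reads in the sample
where the call is missing; otherwise the mutation is *unassessable*.

Two bookkeeping identities hold by construction and are useful sanity
checks on any cohort:

    preserved + disappeared      = assessable low-grade somatic total
    preserved + newly_developed  = assessable high-grade somatic total

The evolution model assigns each subclone group a longitudinal role
(trunk / extinct / emergent) and nests clones by descending fraction under
the pigeonhole constraint (a child cannot exceed its parent; siblings
cannot sum above 1).  Violations are reported, never silently repaired.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError
from .types import (
    CloneNode,
    CloneRole,
    DynamicsRecord,
    DynStatus,
    EvolutionModel,
    SubcloneGroup,
    VariantRecord,
)

MIN_ABSENCE_DEPTH = 10


@dataclass
class MatchedVariant:
    """One variant key with its per-timepoint call and site depth."""

    key: tuple[str, int, str, str]
    low_called: bool
    high_called: bool
    low_depth: int | None
    high_depth: int | None


def _index(calls: Sequence[VariantRecord], sample: str) -> dict:
    idx: dict[tuple, VariantRecord] = {}
    for v in calls:
        if v.key in idx:
            raise ValidationError(f"duplicate variant key {v.key} in sample {sample}")
        idx[v.key] = v
    return idx


def match_variants(
    low_calls: Sequence[VariantRecord],
    high_calls: Sequence[VariantRecord],
    low_sample: str,
    high_sample: str,
) -> list[MatchedVariant]:
    """Pair somatic calls from the two timepoints on (chrom, pos, ref, alt).

    Unmatched entries are paired with absence placeholders carrying the
    other sample's depth at the site when that record holds counts for it
    (which lets the classifier decide whether absence is assessable).
    """
    low_idx = _index(low_calls, low_sample)
    high_idx = _index(high_calls, high_sample)

    def depth_at(rec: VariantRecord | None, sample: str) -> int | None:
        if rec is None or sample not in rec.counts:
            return None
        return rec.depth(sample)

    pairs = []
    for key in sorted(set(low_idx) | set(high_idx)):
        lo, hi = low_idx.get(key), high_idx.get(key)
        pairs.append(
            MatchedVariant(
                key=key,
                low_called=lo is not None and lo.is_somatic.get(low_sample, True),
                high_called=hi is not None and hi.is_somatic.get(high_sample, True),
                low_depth=depth_at(lo, low_sample) if lo is not None else depth_at(hi, low_sample),
                high_depth=depth_at(hi, high_sample) if hi is not None else depth_at(lo, high_sample),
            )
        )
    return pairs


def classify_dynamics(
    pair: MatchedVariant, min_depth: int = MIN_ABSENCE_DEPTH
) -> DynamicsRecord:
    """Classify one matched variant's fate between timepoints."""
    if pair.low_called and pair.high_called:
        status = DynStatus.PRESERVED
    elif pair.high_called:
        if pair.low_depth is not None and pair.low_depth >= min_depth:
            status = DynStatus.NEWLY_DEVELOPED
        else:
            status = DynStatus.UNASSESSABLE
    elif pair.low_called:
        if pair.high_depth is not None and pair.high_depth >= min_depth:
            status = DynStatus.DISAPPEARED
        else:
            status = DynStatus.UNASSESSABLE
    else:
        status = DynStatus.UNASSESSABLE
    return DynamicsRecord(key=pair.key, status=status)


def dynamics_summary(records: Sequence[DynamicsRecord]) -> dict[str, int]:
    """Count mutations per dynamics class."""
    c = Counter(r.status for r in records)
    return {s.value: c.get(s, 0) for s in DynStatus}


def build_evolution_model(
    groups: Sequence[SubcloneGroup],
    timepoints: Sequence[str],
    tolerance: float = 0.05,
) -> EvolutionModel:
    """Assemble the clonal-evolution model from named subclone groups.

    Roles: defined at both timepoints -> trunk; low-only -> extinct;
    high-only -> emergent.  Containment is built greedily: clones are
    nested by descending fraction, each under the smallest plausible parent
    satisfying child <= parent + tolerance at every shared timepoint.
    Pigeonhole violations (sibling fractions summing above 1 + tolerance at
    some timepoint, or no admissible parent among larger clones) are
    reported in ``model.violations``.
    """
    low, high = timepoints[0], timepoints[-1]
    nodes = []
    for g in groups:
        fr = g.fraction_by_sample
        if low in fr and high in fr:
            role = CloneRole.TRUNK
        elif low in fr:
            role = CloneRole.EXTINCT
        else:
            role = CloneRole.EMERGENT
        nodes.append(CloneNode(group_id=g.group_id, role=role, fraction_by_sample=dict(fr)))

    def size(n: CloneNode) -> float:
        return max(n.fraction_by_sample.values())

    nodes.sort(key=lambda n: (-size(n), n.group_id))
    violations: list[str] = []
    for i, node in enumerate(nodes):
        # smallest admissible parent among strictly larger clones
        parent = None
        for cand in reversed(nodes[:i]):
            ok = all(
                node.fraction_by_sample[t] <= cand.fraction_by_sample[t] + tolerance
                for t in node.fraction_by_sample
                if t in cand.fraction_by_sample
            )
            shares = any(t in cand.fraction_by_sample for t in node.fraction_by_sample)
            if ok and shares:
                parent = cand
                break
        node.parent = parent.group_id if parent else None

    # pigeonhole: siblings under one parent cannot sum above 1 at a timepoint
    by_parent: dict[str | None, list[CloneNode]] = {}
    for n in nodes:
        by_parent.setdefault(n.parent, []).append(n)
    for parent_id, sibs in by_parent.items():
        for t in timepoints:
            total = sum(n.fraction_by_sample.get(t, 0.0) for n in sibs)
            cap = 1.0 if parent_id is None else by_parent_cap(nodes, parent_id, t)
            if total > cap + tolerance:
                violations.append(
                    f"siblings under {parent_id or 'root'} sum to {total:.2f} "
                    f"> {cap:.2f} at {t}"
                )
    return EvolutionModel(clones=nodes, violations=violations)


def by_parent_cap(nodes: Sequence[CloneNode], parent_id: str, timepoint: str) -> float:
    for n in nodes:
        if n.group_id == parent_id:
            return n.fraction_by_sample.get(timepoint, 1.0)
    return 1.0
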