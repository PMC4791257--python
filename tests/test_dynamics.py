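"""Longitudinal mutation-fate classification and the evolution model."""

import pytest

from longclone import dynamics
from longclone.dynamics import MatchedVariant, classify_dynamics, match_variants
from longclone.errors import ValidationError
from longclone.types import (
    CloneRole,
    DynStatus,
    SubcloneGroup,
    VariantRecord,
)


def _call(pos, sample, depth=150):
    rec = VariantRecord(
        chrom="chr1", pos=pos, ref="A", alt="T",
        counts={sample: (depth - 10, 10)},
    )
    rec.is_somatic[sample] = True
    return rec


class TestMatching:
    def test_disjoint_lists(self):
        low = [_call(1, "L"), _call(2, "L")]
        high = [_call(10, "H"), _call(11, "H"), _call(12, "H")]
        pairs = match_variants(low, high, "L", "H")
        assert len(pairs) == 5
        assert not any(p.low_called and p.high_called for p in pairs)

    def test_identical_lists_all_matched(self):
        low = [_call(1, "L"), _call(2, "L")]
        high = [_call(1, "H"), _call(2, "H")]
        pairs = match_variants(low, high, "L", "H")
        assert len(pairs) == 2
        assert all(p.low_called and p.high_called for p in pairs)

    def test_partial_overlap(self):
        low = [_call(1, "L"), _call(2, "L"), _call(3, "L"), _call(4, "L")]
        high = [_call(3, "H"), _call(4, "H"), _call(5, "H"), _call(6, "H")]
        pairs = match_variants(low, high, "L", "H")
        matched = [p for p in pairs if p.low_called and p.high_called]
        assert len(pairs) == 6
        assert len(matched) == 2

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValidationError):
            match_variants([_call(1, "L"), _call(1, "L")], [], "L", "H")


class TestClassification:
    def test_called_in_both_preserved(self):
        pair = MatchedVariant(("chr1", 1, "A", "T"), True, True, 150, 150)
        assert classify_dynamics(pair).status is DynStatus.PRESERVED

    def test_newly_developed_with_covered_low(self):
        pair = MatchedVariant(("chr1", 1, "A", "T"), False, True, 120, 150)
        assert classify_dynamics(pair).status is DynStatus.NEWLY_DEVELOPED

    def test_shallow_absence_unassessable(self):
        pair = MatchedVariant(("chr1", 1, "A", "T"), True, False, 150, 4)
        assert classify_dynamics(pair).status is DynStatus.UNASSESSABLE

    def test_disappeared_with_covered_high(self):
        pair = MatchedVariant(("chr1", 1, "A", "T"), True, False, 150, 80)
        assert classify_dynamics(pair).status is DynStatus.DISAPPEARED

    @pytest.mark.parametrize(
        "low_called,high_called,low_depth,high_depth",
        [
            (True, True, 150, 150),
            (False, True, 120, 150),
            (True, False, 150, 80),
            (False, True, 4, 150),
        ],
    )
    def test_timepoint_swap_symmetry(self, low_called, high_called, low_depth, high_depth):
        """Swapping timepoints maps newly_developed <-> disappeared and
        fixes preserved/unassessable."""
        fwd = classify_dynamics(
            MatchedVariant(("chr1", 1, "A", "T"), low_called, high_called, low_depth, high_depth)
        ).status
        rev = classify_dynamics(
            MatchedVariant(("chr1", 1, "A", "T"), high_called, low_called, high_depth, low_depth)
        ).status
        swap = {
            DynStatus.NEWLY_DEVELOPED: DynStatus.DISAPPEARED,
            DynStatus.DISAPPEARED: DynStatus.NEWLY_DEVELOPED,
            DynStatus.PRESERVED: DynStatus.PRESERVED,
            DynStatus.UNASSESSABLE: DynStatus.UNASSESSABLE,
        }
        assert rev == swap[fwd]


class TestSummaryIdentities:
    def test_empty(self):
        counts = dynamics.dynamics_summary([])
        assert all(v == 0 for v in counts.values())

    def test_bookkeeping_identities(self):
        """preserved + disappeared = low total; preserved + newly = high total.

        With counts (newly=49, disappeared=14, preserved=16) the implied
        totals are 30 and 65; with (41, 2, 7) they are 9 and 48."""
        for newly, gone, kept in [(49, 14, 16), (41, 2, 7), (9, 7, 11)]:
            records = (
                [dynamics.DynamicsRecord(("chr1", i, "A", "T"), DynStatus.NEWLY_DEVELOPED)
                 for i in range(newly)]
                + [dynamics.DynamicsRecord(("chr2", i, "A", "T"), DynStatus.DISAPPEARED)
                   for i in range(gone)]
                + [dynamics.DynamicsRecord(("chr3", i, "A", "T"), DynStatus.PRESERVED)
                   for i in range(kept)]
            )
            c = dynamics.dynamics_summary(records)
            low_total = c["preserved"] + c["disappeared"]
            high_total = c["preserved"] + c["newly_developed"]
            assert low_total == kept + gone
            assert high_total == kept + newly


def _group(gid, fr):
    return SubcloneGroup(group_id=gid, member_segments=[gid], fraction_by_sample=fr)


class TestEvolutionModel:
    def test_trunk_role(self):
        model = dynamics.build_evolution_model(
            [_group("S1.1", {"L": 0.64, "H": 0.84})], ["L", "H"]
        )
        assert model.clone("S1.1").role is CloneRole.TRUNK
        assert not model.violations

    def test_emergent_nested_under_trunk(self):
        model = dynamics.build_evolution_model(
            [_group("S1.1", {"L": 0.64, "H": 0.84}), _group("S3.2", {"H": 0.52})],
            ["L", "H"],
        )
        emergent = model.clone("S3.2")
        assert emergent.role is CloneRole.EMERGENT
        assert emergent.parent == "S1.1"

    def test_extinct_role(self):
        model = dynamics.build_evolution_model(
            [_group("S1.1", {"L": 0.8, "H": 0.8}), _group("S2.1", {"L": 0.3})],
            ["L", "H"],
        )
        assert model.clone("S2.1").role is CloneRole.EXTINCT

    def test_pigeonhole_violation_reported(self):
        model = dynamics.build_evolution_model(
            [
                _group("P", {"L": 1.0, "H": 1.0}),
                _group("A", {"L": 0.7, "H": 0.2}),
                _group("B", {"L": 0.6, "H": 0.6}),
            ],
            ["L", "H"],
        )
        # B cannot nest inside A (0.6 > 0.2 at H), so A and B are siblings
        # under P and their low-grade fractions sum to 1.3 > 1
        assert model.violations

    def test_compatible_nesting_no_violation(self):
        model = dynamics.build_evolution_model(
            [
                _group("P", {"L": 1.0, "H": 1.0}),
                _group("A", {"L": 0.7, "H": 0.7}),
                _group("B", {"L": 0.6, "H": 0.6}),
            ],
            ["L", "H"],
        )
        # B fits inside A (within tolerance), so the chain P > A > B is valid
        assert model.clone("B").parent == "A"
        assert not model.violations
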