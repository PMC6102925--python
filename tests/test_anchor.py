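"""Flank anchoring, repeat measurement, classification and backbone binning."""

import numpy as np
import pytest

from repeatspan import (
    Anchors,
    BackboneSet,
    LongRead,
    assign_backbone,
    call_repeat_region,
    classify_allele,
    classify_spanning,
    find_flank_anchors,
    measure_repeat_from_alignment,
    nt_to_repeats,
    reverse_complement,
)
from repeatspan.anchor import (
    CLASS_EXPANDED,
    CLASS_UNASSIGNED,
    CLASS_WT_EXACT,
    CLASS_WT_NEAR,
    STATUS_LEFT_PARTIAL,
    STATUS_OFF_TARGET,
    STATUS_SPANNING,
)


class TestNtToRepeats:
    @pytest.mark.parametrize(
        "nt,expected",
        [(41, 7), (7941, 1324), (5471, 912), (178, 30), (48, 8), (12, 2), (0, 0)],
    )
    def test_half_up_rounding(self, nt, expected):
        assert nt_to_repeats(nt, 6) == expected

    @pytest.mark.parametrize("k", [0, 1, 2, 8, 30, 110, 774, 1324])
    @pytest.mark.parametrize("m", [1, 3, 6])
    def test_exact_multiples(self, k, m):
        assert nt_to_repeats(k * m, m) == k

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            nt_to_repeats(-1, 6)


class TestFlankAnchoring:
    @pytest.mark.parametrize("units", [2, 8, 30, 110, 774, 1324])
    def test_error_free_truth_recovered_exactly(self, locus, perfect_read_seq, units):
        read = LongRead("r", perfect_read_seq(units))
        call = call_repeat_region(read, locus)
        assert call.status == STATUS_SPANNING
        assert call.repeat_nt == units * 6
        assert call.repeat_units == units
        assert call.up_identity == 1.0 and call.down_identity == 1.0

    @pytest.mark.parametrize("units", [2, 110])
    def test_strand_invariance(self, locus, perfect_read_seq, units):
        fwd = LongRead("f", perfect_read_seq(units))
        rev = LongRead("r", reverse_complement(perfect_read_seq(units)))
        call_f = call_repeat_region(fwd, locus)
        call_r = call_repeat_region(rev, locus)
        assert call_f.strand == "forward" and call_r.strand == "reverse"
        assert (call_f.repeat_nt, call_f.repeat_units, call_f.status) == (
            call_r.repeat_nt,
            call_r.repeat_units,
            call_r.status,
        )

    def test_mutated_up_flank_drops_anchor(self, locus):
        # mutate 20 of 100 flank bases -> at most 80 matches, below 0.85
        rng = np.random.default_rng(0)
        flank = list(locus.flank_up)
        for i in rng.choice(len(flank), size=20, replace=False):
            flank[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[flank[i]]
        read = LongRead("r", "".join(flank) + locus.motif * 10 + locus.flank_down)
        anchors = find_flank_anchors(read, locus)
        assert anchors.up is None
        assert anchors.down is not None

    def test_truncated_read_is_left_partial_lower_bound(self, locus):
        # read ends 178 nt into the repeat after the upstream flank
        read = LongRead("r", locus.flank_up + (locus.motif * 30)[:178])
        call = call_repeat_region(read, locus)
        assert call.status == STATUS_LEFT_PARTIAL
        assert call.repeat_nt == 178
        assert call.repeat_units == 30

    def test_no_flanks_is_off_target(self, locus):
        rng = np.random.default_rng(42)
        read = LongRead("r", "".join(rng.choice(list("ACGT"), size=400)))
        call = call_repeat_region(read, locus)
        assert call.status == STATUS_OFF_TARGET
        assert call.repeat_nt == 0

    def test_swapped_flank_order_rejected(self, locus):
        read = LongRead("r", locus.flank_down + locus.motif * 5 + locus.flank_up)
        call = call_repeat_region(read, locus)
        assert call.status == STATUS_OFF_TARGET
        assert "anchor_order_conflict" in call.flags

    def test_overlapping_anchors_clamp_to_zero(self, locus):
        from repeatspan.align import AlignmentResult

        def fake(qs, qe):
            return AlignmentResult(200, qs, qe, 0, 100, 100, 0, 0, 0)

        anchors = Anchors(
            strand="forward",
            sequence=locus.flank_up + locus.flank_down,
            up=fake(0, 102),
            down=fake(100, 200),
            up_identity=1.0,
            down_identity=1.0,
        )
        call = call_repeat_region(
            LongRead("r", locus.flank_up + locus.flank_down), locus, anchors=anchors
        )
        assert call.status == STATUS_SPANNING
        assert call.repeat_nt == 0
        assert "anchor_overlap" in call.flags


class TestClassifyAllele:
    def _spanning_call(self, locus, repeat_nt):
        read = LongRead("r", locus.flank_up + "A" + locus.flank_down)
        call = call_repeat_region(read, locus)
        call.repeat_nt = repeat_nt
        call.status = STATUS_SPANNING
        return call

    @pytest.mark.parametrize(
        "repeat_nt,expected",
        [
            (12, CLASS_WT_EXACT),
            (17, CLASS_WT_NEAR),
            (18, CLASS_WT_NEAR),
            (7, CLASS_WT_NEAR),
            (19, CLASS_EXPANDED),
            (660, CLASS_EXPANDED),
        ],
    )
    def test_two_unit_wildtype_classes(self, locus, repeat_nt, expected):
        call = self._spanning_call(locus, repeat_nt)
        assert classify_allele(call, locus, wildtype_units=2) == expected

    def test_non_spanning_unassigned(self, locus, perfect_read_seq):
        read = LongRead("r", locus.flank_up + (locus.motif * 30)[:178])
        call = call_repeat_region(read, locus)
        assert classify_allele(call, locus, wildtype_units=2) == CLASS_UNASSIGNED


class TestClassifySpanning:
    def test_full_coverage(self, locus):
        span = (locus.repeat_start - 100, locus.repeat_end + 100)
        assert classify_spanning(span, locus) is True

    def test_ends_inside_repeat(self, locus):
        span = (locus.repeat_start - 100, locus.repeat_end - 1)
        assert classify_spanning(span, locus) is False

    def test_starts_inside_repeat(self, locus):
        span = (locus.repeat_start + 1, locus.repeat_end + 100)
        assert classify_spanning(span, locus) is False

    def test_one_base_margin_suffices(self, locus):
        span = (locus.repeat_start - 1, locus.repeat_end + 1)
        assert classify_spanning(span, locus) is True


class TestMeasureFromAlignment:
    def test_insertions_counted_deletions_not(self, locus):
        start, end = locus.repeat_start, locus.repeat_end  # 18 nt reference repeat
        # 12-nt truth with 2 deletions -> 10 bases counted
        pairs = []
        q = 0
        for offset in range(end - start):
            if offset in (3, 7):
                pairs.append((None, start + offset))  # deletion
            elif offset < 12:
                pairs.append((q, start + offset))
                q += 1
        counted = measure_repeat_from_alignment(pairs, locus)
        assert counted == 10

    def test_eight_unit_read_on_three_unit_reference(self, locus):
        # 48 read bases within an 18-nt reference interval: 18 aligned + 30 inserted
        start = locus.repeat_start
        pairs = [(q, start + q) for q in range(17)]
        pairs += [(17 + k, None) for k in range(30)]  # insertions inside
        pairs.append((47, start + 17))
        counted = measure_repeat_from_alignment(pairs, locus)
        assert counted == 48

    def test_non_overlapping_alignment_counts_zero(self, locus):
        pairs = [(q, q) for q in range(50)]  # far upstream of repeat_start=1000
        assert measure_repeat_from_alignment(pairs, locus) == 0

    def test_matches_independent_recount(self, locus):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pairs = []
            q = 0
            r = int(rng.integers(locus.repeat_start - 30, locus.repeat_start + 5))
            for _ in range(80):
                op = rng.random()
                if op < 0.7:
                    pairs.append((q, r)); q += 1; r += 1
                elif op < 0.85:
                    pairs.append((q, None)); q += 1
                else:
                    pairs.append((None, r)); r += 1
            # independent recount: scan columns tracking reference position
            expected = 0
            last_ref = None
            for qpos, rpos in pairs:
                if rpos is not None and qpos is not None:
                    if locus.repeat_start <= rpos < locus.repeat_end:
                        expected += 1
                if rpos is not None:
                    last_ref = rpos
                if rpos is None and qpos is not None and last_ref is not None:
                    if locus.repeat_start <= last_ref < locus.repeat_end:
                        expected += 1
            assert measure_repeat_from_alignment(pairs, locus) == expected


@pytest.fixture(scope="module")
def backbones():
    rng = np.random.default_rng(11)
    return BackboneSet(
        {f"bb{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(4)}
    )


class TestBackboneBinning:

    def test_exact_containment(self, backbones):
        rng = np.random.default_rng(1)
        pad = "".join(rng.choice(list("ACGT"), size=50))
        read = LongRead("r", pad + backbones.entries["bb2"] + pad)
        assert assign_backbone(read, backbones) == "bb2"

    def test_no_backbone_unassigned(self, backbones):
        rng = np.random.default_rng(2)
        read = LongRead("r", "".join(rng.choice(list("ACGT"), size=200)))
        assert assign_backbone(read, backbones) == "unassigned"

    def test_noisy_reads_assigned_correctly(self, backbones):
        # 10% uniform substitution noise, both strands; >=99% correct
        rng = np.random.default_rng(3)
        correct = total = 0
        for trial in range(60):
            name = f"bb{trial % 4}"
            tag = list(backbones.entries[name])
            for i in range(len(tag)):
                if rng.random() < 0.10:
                    tag[i] = "ACGT"[rng.integers(0, 4)]
            seq = "".join(rng.choice(list("ACGT"), size=40)) + "".join(tag)
            if trial % 2:
                seq = reverse_complement(seq)
            total += 1
            if assign_backbone(LongRead("r", seq), backbones) == name:
                correct += 1
        assert correct / total >= 0.99
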