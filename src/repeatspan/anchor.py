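"""Flank anchoring: locate, measure and classify the repeat region in reads.

The repeat region of a read is defined as the nucleotides between the
local alignments of the two ~100-nt flanking sequences. A read is
*spanning* when both flanks anchor; a single passing anchor yields a
partial call whose repeat length is a lower bound; no anchors means the
read is off target.

Anchor acceptance: a flank anchor passes when at least ``min_identity``
of the flank's bases are matched (n_match / flank_length >= threshold,
default 0.85). Measuring against the full flank length rather than the
local-alignment column count keeps the rule strict: trimming a noisy
alignment down to a clean sub-island cannot rescue a failing anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignmentResult, DEFAULT_SCORING, Scoring, local_align
from .core import BackboneSet, LongRead, RepeatLocus, reverse_complement

__all__ = [
    "Anchors",
    "RepeatCall",
    "find_flank_anchors",
    "call_repeat_region",
    "call_reads",
    "calls_to_table",
    "measure_repeat_from_alignment",
    "classify_spanning",
    "nt_to_repeats",
    "classify_allele",
    "assign_backbone",
]

STATUS_SPANNING = "spanning"
STATUS_LEFT_PARTIAL = "left_partial"
STATUS_RIGHT_PARTIAL = "right_partial"
STATUS_OFF_TARGET = "off_target"

CLASS_WT_EXACT = "wildtype_exact"
CLASS_WT_NEAR = "wildtype_near"
CLASS_EXPANDED = "expanded"
CLASS_UNASSIGNED = "unassigned"

DEFAULT_MIN_IDENTITY = 0.85
DEFAULT_SPAN_MARGIN = 100
DEFAULT_NEAR_WINDOW_NT = 6


def _anchor_identity(result: AlignmentResult | None, flank_len: int) -> float:
    """Fraction of flank bases matched by the anchor alignment."""
    if result is None or flank_len == 0:
        return 0.0
    return result.n_match / flank_len


@dataclass
class Anchors:
    """Both flank anchors for one read, in the chosen orientation.

    ``sequence`` is the read sequence oriented so that flank_up precedes
    flank_down; all anchor coordinates refer to this oriented sequence.
    ``up``/``down`` are None when the corresponding anchor failed the
    identity threshold.
    """

    strand: str
    sequence: str
    up: AlignmentResult | None
    down: AlignmentResult | None
    up_identity: float
    down_identity: float


def find_flank_anchors(
    read: LongRead,
    locus: RepeatLocus,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    scoring: Scoring = DEFAULT_SCORING,
) -> Anchors:
    """Locally align both flanks against the read in both orientations.

    The orientation with the greater total passing-anchor score wins;
    ties go to forward. Anchors failing the identity rule are reported
    absent (None).
    """
    candidates = []
    for strand, seq in (("forward", read.sequence), ("reverse", reverse_complement(read.sequence))):
        up = local_align(seq, locus.flank_up, scoring)
        down = local_align(seq, locus.flank_down, scoring)
        up_id = _anchor_identity(up, len(locus.flank_up))
        down_id = _anchor_identity(down, len(locus.flank_down))
        up_pass = up_id >= min_identity
        down_pass = down_id >= min_identity
        total = (up.score if up_pass else 0) + (down.score if down_pass else 0)
        candidates.append(
            (
                total,
                Anchors(
                    strand=strand,
                    sequence=seq,
                    up=up if up_pass else None,
                    down=down if down_pass else None,
                    up_identity=up_id,
                    down_identity=down_id,
                ),
            )
        )
    fwd, rev = candidates
    chosen = rev if rev[0] > fwd[0] else fwd
    return chosen[1]


@dataclass
class RepeatCall:
    """Per-read measurement of the repeat region."""

    read_id: str
    strand: str
    up_anchor: AlignmentResult | None
    down_anchor: AlignmentResult | None
    repeat_region: tuple[int, int] | None
    repeat_nt: int
    repeat_units: int
    status: str
    allele_class: str = CLASS_UNASSIGNED
    up_identity: float = 0.0
    down_identity: float = 0.0
    flags: tuple[str, ...] = ()


def nt_to_repeats(repeat_nt: int, motif_len: int) -> int:
    """Nucleotides -> repeat units, rounding half up (7941/6 -> 1324)."""
    if repeat_nt < 0:
        raise ValueError("repeat_nt must be non-negative")
    if motif_len < 1:
        raise ValueError("motif_len must be >= 1")
    return (2 * repeat_nt + motif_len) // (2 * motif_len)


def call_repeat_region(
    read: LongRead,
    locus: RepeatLocus,
    anchors: Anchors | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    scoring: Scoring = DEFAULT_SCORING,
) -> RepeatCall:
    """Measure the repeat region of one read from its flank anchors.

    Both anchors passing -> spanning call with the exact region between
    them; one anchor -> partial call whose repeat_nt (distance from the
    anchor's inner edge to the read end facing the repeat) is a lower
    bound; none -> off target. Anchors in inconsistent order (downstream
    before upstream) reject the call as off target; overlapping anchors
    clamp the region to zero nucleotides with a diagnostic flag.
    """
    if anchors is None:
        anchors = find_flank_anchors(read, locus, min_identity, scoring)
    up, down = anchors.up, anchors.down
    flags: list[str] = []
    read_len = len(anchors.sequence)
    m = locus.motif_len

    # Local alignments trim low-scoring ends, so an error just inside a
    # flank would otherwise leave a few flank bases inside the measured
    # region; project the trimmed inner flank bases back onto the read.
    def _up_edge(a: AlignmentResult) -> int:
        return min(a.query_end + (len(locus.flank_up) - a.target_end), read_len)

    def _down_edge(a: AlignmentResult) -> int:
        return max(a.query_start - a.target_start, 0)

    if up is not None and down is not None:
        if down.query_start < up.query_start:
            # downstream flank sits before upstream flank: not a repeat locus
            return RepeatCall(
                read.read_id, anchors.strand, up, down, None, 0, 0,
                STATUS_OFF_TARGET, up_identity=anchors.up_identity,
                down_identity=anchors.down_identity, flags=("anchor_order_conflict",),
            )
        start, end = _up_edge(up), _down_edge(down)
        if end < start:
            flags.append("anchor_overlap")
            end = start
        nt = end - start
        return RepeatCall(
            read.read_id, anchors.strand, up, down, (start, end), nt,
            nt_to_repeats(nt, m), STATUS_SPANNING,
            up_identity=anchors.up_identity, down_identity=anchors.down_identity,
            flags=tuple(flags),
        )
    if up is not None:
        nt = read_len - _up_edge(up)
        return RepeatCall(
            read.read_id, anchors.strand, up, None, None, nt, nt_to_repeats(nt, m),
            STATUS_LEFT_PARTIAL, up_identity=anchors.up_identity,
            down_identity=anchors.down_identity,
        )
    if down is not None:
        nt = _down_edge(down)
        return RepeatCall(
            read.read_id, anchors.strand, None, down, None, nt, nt_to_repeats(nt, m),
            STATUS_RIGHT_PARTIAL, up_identity=anchors.up_identity,
            down_identity=anchors.down_identity,
        )
    return RepeatCall(
        read.read_id, anchors.strand, None, None, None, 0, 0, STATUS_OFF_TARGET,
        up_identity=anchors.up_identity, down_identity=anchors.down_identity,
    )


def extract_repeat_region(
    read: LongRead,
    locus: RepeatLocus,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[RepeatCall, str | None]:
    """Call one read and return (call, oriented repeat-region sequence).

    The sequence is None unless the call is spanning with a non-empty
    region.
    """
    anchors = find_flank_anchors(read, locus, min_identity, scoring)
    call = call_repeat_region(read, locus, anchors=anchors, scoring=scoring)
    if call.status == STATUS_SPANNING and call.repeat_region is not None:
        start, end = call.repeat_region
        if end > start:
            return call, anchors.sequence[start:end]
    return call, None


def classify_allele(
    call: RepeatCall,
    locus: RepeatLocus,
    wildtype_units: int,
    near_window_nt: int = DEFAULT_NEAR_WINDOW_NT,
) -> str:
    """Assign spanning calls to wildtype_exact / wildtype_near / expanded.

    A spanning read measuring exactly ``wildtype_units`` motif copies is
    wildtype_exact; within ``near_window_nt`` nucleotides of that length,
    wildtype_near; longer than wild type plus the window, expanded.
    Non-spanning calls stay unassigned.
    """
    if call.status != STATUS_SPANNING:
        return CLASS_UNASSIGNED
    wt_nt = wildtype_units * locus.motif_len
    delta = call.repeat_nt - wt_nt
    if delta == 0:
        return CLASS_WT_EXACT
    if abs(delta) <= near_window_nt:
        return CLASS_WT_NEAR
    if delta > near_window_nt:
        return CLASS_EXPANDED
    return CLASS_UNASSIGNED  # spanning but shorter than wild type - window


def call_reads(
    reads: Iterable[LongRead],
    locus: RepeatLocus,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    wildtype_units: int | None = None,
    near_window_nt: int = DEFAULT_NEAR_WINDOW_NT,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[RepeatCall]:
    """Run anchoring + measurement (+ allele classification) over reads."""
    calls = []
    for read in reads:
        call = call_repeat_region(read, locus, min_identity=min_identity, scoring=scoring)
        if wildtype_units is not None:
            call.allele_class = classify_allele(call, locus, wildtype_units, near_window_nt)
        calls.append(call)
    return calls


def calls_to_table(calls: Sequence[RepeatCall]) -> pd.DataFrame:
    """Per-read calls as a tidy table (one row per read)."""
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in calls],
            "strand": [c.strand for c in calls],
            "status": [c.status for c in calls],
            "repeat_nt": [c.repeat_nt for c in calls],
            "repeat_units": [c.repeat_units for c in calls],
            "allele_class": [c.allele_class for c in calls],
            "up_identity": [round(c.up_identity, 4) for c in calls],
            "down_identity": [round(c.down_identity, 4) for c in calls],
            "flags": [",".join(c.flags) for c in calls],
        }
    )


def measure_repeat_from_alignment(
    aligned_pairs: Iterable[tuple[int | None, int | None]],
    locus: RepeatLocus,
) -> int:
    """Count read bases placed within the reference repeat interval.

    ``aligned_pairs`` follows the pysam convention: (query_pos, ref_pos)
    per alignment column, with None marking a gap on that side. Deletion
    columns contribute nothing; insertion columns (ref_pos None) count
    when they fall strictly inside the repeat interval, i.e. after an
    aligned reference position in [repeat_start, repeat_end - 1].
    """
    start, end = locus.repeat_start, locus.repeat_end
    count = 0
    last_ref: int | None = None
    for qpos, rpos in aligned_pairs:
        if rpos is not None:
            if qpos is not None and start <= rpos < end:
                count += 1
            last_ref = rpos
        elif qpos is not None and last_ref is not None and start <= last_ref < end:
            count += 1
    return count


def classify_spanning(
    alignment_span: tuple[int, int],
    locus: RepeatLocus,
    margin: int = DEFAULT_SPAN_MARGIN,
) -> bool:
    """True iff a reference-space alignment span covers sequence within
    ``margin`` nucleotides on both sides of the repeat region."""
    span_start, span_end = alignment_span
    if span_end <= span_start:
        return False
    before = (max(span_start, locus.repeat_start - margin) < min(span_end, locus.repeat_start))
    after = (max(span_start, locus.repeat_end) < min(span_end, locus.repeat_end + margin))
    return before and after


def assign_backbone(
    read: LongRead,
    backbones: BackboneSet,
    min_identity: float = 0.75,
    scoring: Scoring = DEFAULT_SCORING,
) -> str:
    """Bin a read by the backbone tag it carries, or 'unassigned'.

    Each identifying sequence is locally aligned against both orientations
    of the read; candidates matching at least ``min_identity`` of the tag
    compete on alignment score. No passing candidate, or a score tie
    between two backbones, yields 'unassigned'.
    """
    rc = reverse_complement(read.sequence)
    best: list[tuple[int, str]] = []
    for name, tag in backbones.entries.items():
        score = 0
        passed = False
        for seq in (read.sequence, rc):
            aln = local_align(seq, tag, scoring)
            if _anchor_identity(aln, len(tag)) >= min_identity:
                passed = True
                score = max(score, aln.score)
        if passed:
            best.append((score, name))
    if not best:
        return "unassigned"
    best.sort(key=lambda item: (-item[0], item[1]))
    if len(best) > 1 and best[0][0] == best[1][0]:
        return "unassigned"
    return best[0][1]
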