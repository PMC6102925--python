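"""Nucleotide content of extracted repeat regions.

GC content, exhaustive SSR tract scanning, per-unit (non-overlapping)
motif counting, Levenshtein collapsing to a canonical motif, per-read
error rates against an idealized repeat, and a phase-folded IUPAC
consensus motif.

Counting convention: an SSR "occurrence" is one motif copy, not one
tract — a tract of 100 uninterrupted GGGGCC units contributes 100
occurrences. This per-unit convention is load-bearing for the frequency
arithmetic downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import DEFAULT_SCORING, Scoring, error_rate, global_align, levenshtein

__all__ = [
    "MotifComposition",
    "PhaseConsensus",
    "gc_content",
    "canonical_rotation",
    "ssr_scan",
    "motif_frequencies",
    "collapse_frequencies",
    "collapse_motifs",
    "repeat_error_rate",
    "phase_consensus",
    "consensus_accuracy",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

IUPAC_CODES: Mapping[frozenset, str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); 0.0 for empty or all-N input."""
    seq = seq.upper()
    counts = Counter(seq)
    total = sum(counts[b] for b in _BASES)
    if total == 0:
        return 0.0
    return (counts["G"] + counts["C"]) / total


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest rotation of a motif."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _primitive(motif: str) -> bool:
    """True when the motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def ssr_scan(
    seq: str,
    min_unit_len: int = 1,
    max_unit_len: int = 6,
    min_tract_len: int = 12,
) -> list[tuple[str, int, int]]:
    """Maximal perfect tandem tracts, as (canonical_unit, start, end).

    Tracts of non-primitive units (e.g. a GG "dinucleotide" inside a
    poly-G run) are reported at their primitive period only. Overlapping
    tracts of different units are resolved longest-tract-first, ties by
    smaller start.
    """
    if max_unit_len < min_unit_len:
        raise ValueError("max_unit_len must be >= min_unit_len")
    seq = seq.upper()
    n = len(seq)
    raw: list[tuple[str, int, int]] = []
    for m in range(min_unit_len, max_unit_len + 1):
        i = 0
        while i + 2 * m <= n:
            if seq[i : i + m] != seq[i + m : i + 2 * m]:
                i += 1
                continue
            unit = seq[i : i + m]
            if not _primitive(unit):
                i += 1
                continue
            end = i + 2 * m
            while end < n and seq[end] == seq[end - m]:
                end += 1
            if end - i >= max(min_tract_len, 2 * m):
                raw.append((canonical_rotation(unit), i, end))
            i = end - m + 1
    raw.sort(key=lambda t: (-(t[2] - t[1]), t[1]))
    chosen: list[tuple[str, int, int]] = []
    covered = np.zeros(n, dtype=bool)
    for unit, start, end in raw:
        # trim to the uncovered runs inside [start, end); keep runs that
        # still hold at least two units and the minimum tract length
        m = len(unit)
        pos = start
        while pos < end:
            if covered[pos]:
                pos += 1
                continue
            run_end = pos
            while run_end < end and not covered[run_end]:
                run_end += 1
            if run_end - pos >= max(min_tract_len, 2 * m):
                covered[pos:run_end] = True
                chosen.append((unit, pos, run_end))
            pos = run_end
    chosen.sort(key=lambda t: t[1])
    return chosen


@dataclass
class MotifComposition:
    """Non-overlapping motif occurrence counts over a repeat region.

    ``collapsed_freqs`` is populated by :func:`collapse_motifs`.
    """

    motif_counts: dict[str, int]
    gc_fraction: float
    collapsed_freqs: dict[str, float] | None = None
    flags: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return sum(self.motif_counts.values())

    @property
    def motif_freqs(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {}
        return {m: c / total for m, c in self.motif_counts.items()}


def _count_exact(seq: str, motif: str) -> int:
    """Non-overlapping left-to-right occurrence count of one motif."""
    count = 0
    pos = seq.find(motif)
    while pos != -1:
        count += 1
        pos = seq.find(motif, pos + len(motif))
    return count


def _best_rotation(seq: str, canonical: str) -> str:
    """Rotation of a canonical unit with the most exact occurrences in seq.

    Reads normally enter the repeat in the phase set by the flank
    boundary; picking the dominant rotation keeps reported motif keys in
    that natural spelling (GGGGCC, not CCGGGG).
    """
    rotations = {canonical[i:] + canonical[:i] for i in range(len(canonical))}
    scored = []
    for rot in rotations:
        first = seq.find(rot)
        scored.append((-_count_exact(seq, rot), first if first != -1 else len(seq), rot))
    scored.sort()
    return scored[0][2]


def _edit_variants_at(seq: str, pos: int, motif: str, max_distance: int) -> str | None:
    """Longest substring at ``pos`` of length m±d within distance d of motif."""
    m = len(motif)
    for length in range(m + max_distance, m - max_distance - 1, -1):
        if length < 1 or pos + length > len(seq):
            continue
        sub = seq[pos : pos + length]
        if levenshtein(sub, motif) <= max_distance:
            return sub
    return None


def motif_frequencies(
    seq: str,
    motifs_of_interest: Sequence[str] | None = None,
    variant_distance: int = 1,
    max_unit_len: int = 6,
) -> MotifComposition:
    """Count non-overlapping motif occurrences, scanned left to right.

    When ``motifs_of_interest`` is None, the primary motif is discovered
    as the SSR unit covering the most sequence. At each position the scan
    first tries exact motifs (longest first), then — so that single-edit
    interruptions such as a lone GGGCC between GGGGCC tracts are counted
    rather than skipped — substrings within ``variant_distance`` edits of
    the primary motif. Unmatched positions are skipped one base at a time
    and contribute nothing.
    """
    seq = seq.upper()
    flags: list[str] = []
    if not seq:
        return MotifComposition({}, 0.0, flags=("empty",))
    if motifs_of_interest is None:
        tracts = ssr_scan(seq, max_unit_len=max_unit_len)
        if not tracts:
            return MotifComposition({}, gc_content(seq), flags=("no_ssr",))
        coverage: Counter = Counter()
        for unit, start, end in tracts:
            coverage[unit] += end - start
        primary_canon = max(coverage, key=lambda u: (coverage[u], -len(u)))
        motifs = [_best_rotation(seq, primary_canon)]
    else:
        motifs = [m.upper() for m in motifs_of_interest]
    motifs = sorted(set(motifs), key=lambda m: (-len(m), m))
    primary = motifs[0] if motifs_of_interest is None else max(motifs, key=len)
    counts: Counter = Counter()
    pos = 0
    n = len(seq)
    min_len = min(len(m) for m in motifs)
    while pos <= n - 1:
        matched = False
        for motif in motifs:
            if seq.startswith(motif, pos):
                counts[motif] += 1
                pos += len(motif)
                matched = True
                break
        if matched:
            continue
        if variant_distance > 0:
            var = _edit_variants_at(seq, pos, primary, variant_distance)
            if var is not None:
                counts[var] += 1
                pos += len(var)
                continue
        pos += 1
    if not counts:
        flags.append("no_motifs_counted")
    return MotifComposition(dict(counts), gc_content(seq), flags=tuple(flags))


def collapse_frequencies(
    freqs: Mapping[str, float],
    canonical: str,
    max_distance: int = 1,
) -> dict[str, float]:
    """Pool every motif within ``max_distance`` edits of ``canonical``.

    The total mass is preserved; remaining motifs pool into "other".
    """
    if not canonical:
        raise ValueError("canonical motif must be non-empty")
    canonical = canonical.upper()
    pooled = 0.0
    other = 0.0
    for motif, value in freqs.items():
        if levenshtein(motif.upper(), canonical) <= max_distance:
            pooled += value
        else:
            other += value
    out = {canonical: pooled}
    if other:
        out["other"] = other
    return out


def collapse_motifs(
    comp: MotifComposition,
    canonical: str,
    max_distance: int = 1,
) -> MotifComposition:
    """Return a copy of ``comp`` with ``collapsed_freqs`` filled in."""
    collapsed = collapse_frequencies(comp.motif_freqs, canonical, max_distance)
    return MotifComposition(
        dict(comp.motif_counts), comp.gc_fraction, collapsed_freqs=collapsed,
        flags=comp.flags,
    )


def _best_phase(region: str, motif: str) -> int:
    """Tiling offset (0..m-1) maximizing ungapped matches to the motif."""
    m = len(motif)
    arr = np.frombuffer(region.encode("ascii"), dtype=np.uint8)
    tile = np.frombuffer((motif * (len(region) // m + 2)).encode("ascii"), dtype=np.uint8)
    best_offset, best_matches = 0, -1
    for offset in range(m):
        matches = int((arr == tile[offset : offset + arr.size]).sum())
        if matches > best_matches:
            best_offset, best_matches = offset, matches
    return best_offset


def ideal_repeat(motif: str, length: int, phase: int = 0) -> str:
    """Motif tiled from ``phase`` and truncated to ``length`` nucleotides."""
    m = len(motif)
    reps = (length + phase) // m + 2
    return (motif * reps)[phase : phase + length]


def repeat_error_rate(
    repeat_seq: str,
    motif: str,
    scoring: Scoring = DEFAULT_SCORING,
) -> float:
    """Error rate of an extracted repeat region against an idealized repeat.

    The ideal repeat has the same nucleotide length as the measured
    region, tiled from the motif at the phase (of the m possible) that
    maximizes ungapped matches; the two are then globally aligned and
    the alignment error rate returned.
    """
    if not repeat_seq:
        raise ValueError("repeat_seq must be non-empty")
    phase = _best_phase(repeat_seq, motif)
    ideal = ideal_repeat(motif, len(repeat_seq), phase)
    return error_rate(global_align(repeat_seq, ideal, scoring))


@dataclass
class PhaseConsensus:
    """Phase-folded per-column base frequencies and the IUPAC motif."""

    frame_offset: int
    base_freqs: np.ndarray  # shape (m, 4), columns A,C,G,T
    iupac_motif: str
    n_frames: int = 0


def _fold_region(region: str, motif: str, counts: np.ndarray) -> tuple[int, int]:
    """Fold one region into motif-phase columns, re-syncing through indels.

    The region is globally aligned to an idealized repeat of the same
    length (tiled at the region's best phase); every aligned read base is
    assigned the motif column of its ideal-repeat position. Aligning —
    rather than slicing consecutive m-nt frames — keeps columns in phase
    across insertions and deletions, without which a handful of indels
    scrambles every downstream column.
    """
    m = len(motif)
    offset = _best_phase(region, motif)
    ideal = ideal_repeat(motif, len(region), offset)
    result = global_align(region, ideal)
    # replay the alignment column by column (same tie-break as traceback)
    from .align import _score_matrix  # shared DP core

    H = _score_matrix(region, ideal, DEFAULT_SCORING, local=False)
    i, j = len(ideal), len(region)
    gap = DEFAULT_SCORING.gap
    n_frames = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = DEFAULT_SCORING.match if region[j - 1] == ideal[i - 1] else DEFAULT_SCORING.mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                col = (offset + i - 1) % m
                idx = _BASE_INDEX.get(region[j - 1])
                if idx is not None:
                    counts[col, idx] += 1
                    if col == 0:
                        n_frames += 1
                i -= 1
                j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + gap:
            i -= 1
            continue
        j -= 1
    return offset, max(n_frames, 1)


def phase_consensus(
    repeat_regions: Iterable[str],
    motif: str,
    ambiguity_threshold: float = 0.2,
) -> PhaseConsensus:
    """Fold repeat regions into motif-phase columns and call an IUPAC motif.

    Each region is folded at its best phase; per-column base frequencies
    accumulate over all folded frames of all regions (see
    :func:`_fold_region` for how indels are re-synchronized). A column's
    IUPAC code covers exactly the bases whose frequency reaches
    ``ambiguity_threshold``.
    """
    m = len(motif)
    counts = np.zeros((m, 4), dtype=np.int64)
    offsets: Counter = Counter()
    n_frames = 0
    for region in repeat_regions:
        region = region.upper()
        if len(region) < m:
            continue
        offset, frames = _fold_region(region, motif, counts)
        offsets[offset] += 1
        n_frames += frames
    if n_frames == 0:
        raise ValueError("no region of at least motif length provided")
    col_totals = counts.sum(axis=1)
    freqs = counts / np.maximum(col_totals, 1)[:, None]
    code_chars = []
    for col in range(m):
        if col_totals[col] == 0:
            code_chars.append("N")
            continue
        bases = frozenset(_BASES[i] for i in range(4) if freqs[col, i] >= ambiguity_threshold)
        if not bases:
            bases = frozenset({_BASES[int(np.argmax(freqs[col]))]})
        code_chars.append(IUPAC_CODES[bases])
    return PhaseConsensus(
        frame_offset=offsets.most_common(1)[0][0],
        base_freqs=freqs,
        iupac_motif="".join(code_chars),
        n_frames=n_frames,
    )


def consensus_accuracy(
    consensus: str,
    truth: str,
    scoring: Scoring = DEFAULT_SCORING,
) -> float:
    """Global-alignment identity of a consensus against a concrete truth.

    IUPAC ambiguity symbols are compared literally: an ambiguous column
    counts as an error unless the symbol is exactly the truth base. This
    is deliberate — a consensus that can only say "G or A" has not called
    the base.
    """
    if not consensus or not truth:
        raise ValueError("consensus_accuracy requires non-empty sequences")
    result = global_align(consensus.upper(), truth.upper(), scoring)
    return result.identity
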