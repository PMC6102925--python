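"""Dynamic-programming alignment primitives.

Self-contained Smith-Waterman (local), Needleman-Wunsch (global) and
Levenshtein edit distance with linear gap costs. The scoring defaults
(match +2, mismatch -3, gap -4) only rank candidate alignments; the
accept/reject decision for flank anchors is an identity threshold, so the
exact scheme is not load-bearing as long as it is deterministic.

Conventions
-----------
* ``query`` is the read-side sequence, ``target`` the flank/reference side.
* An *insertion* column consumes a query base (extra base in the read);
  a *deletion* column consumes a target base (base missing from the read).
* ``identity`` = matches / total alignment columns, gap columns included.
* Tie-breaking is deterministic: among equal-score local end points the
  alignment with the smallest query_start, then target_start, is reported;
  traceback prefers diagonal over deletion over insertion moves.

The score recurrences are vectorized one row at a time; the horizontal
(linear-gap) dependency within a row is resolved with a running-maximum
scan, so a row costs a handful of numpy operations regardless of length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Scoring",
    "AlignmentResult",
    "local_align",
    "global_align",
    "levenshtein",
    "error_rate",
]

_NEG_INF = np.int64(-(2**40))


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap: int = -4

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap >= 0:
            raise ValueError("mismatch and gap penalties must be negative")


DEFAULT_SCORING = Scoring()


@dataclass
class AlignmentResult:
    """One pairwise alignment: score, spans (0-based half-open), op counts."""

    score: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    n_match: int
    n_mismatch: int
    n_ins: int
    n_del: int

    @property
    def columns(self) -> int:
        return self.n_match + self.n_mismatch + self.n_ins + self.n_del

    @property
    def identity(self) -> float:
        cols = self.columns
        return self.n_match / cols if cols else 0.0


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _score_matrix(query: str, target: str, scoring: Scoring, local: bool) -> np.ndarray:
    """Full DP matrix H of shape (len(target)+1, len(query)+1), int64."""
    q = _encode(query)
    t = _encode(target)
    n, m = q.size, t.size
    gap = np.int64(scoring.gap)
    H = np.empty((m + 1, n + 1), dtype=np.int64)
    j_idx = np.arange(n + 1, dtype=np.int64)
    if local:
        H[0, :] = 0
    else:
        H[0, :] = gap * j_idx
    cand = np.empty(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        prev = H[i - 1]
        subst = np.where(q == t[i - 1], scoring.match, scoring.mismatch)
        best_vert = np.maximum(prev[:-1] + subst, prev[1:] + gap)
        if local:
            cand[0] = 0
            cand[1:] = np.maximum(best_vert, 0)
        else:
            cand[0] = gap * i
            cand[1:] = best_vert
        # H[i, j] = max(cand[j], H[i, j-1] + gap) via running-max scan
        shifted = cand - gap * j_idx
        np.maximum.accumulate(shifted, out=shifted)
        H[i] = shifted + gap * j_idx
    return H


def _traceback(
    H: np.ndarray,
    query: str,
    target: str,
    scoring: Scoring,
    end: tuple[int, int],
    local: bool,
) -> AlignmentResult:
    q = _encode(query)
    t = _encode(target)
    gap = scoring.gap
    i, j = end
    n_match = n_mismatch = n_ins = n_del = 0
    score = int(H[i, j])
    while i > 0 or j > 0:
        h = H[i, j]
        if local and h == 0:
            break
        if i > 0 and j > 0:
            s = scoring.match if q[j - 1] == t[i - 1] else scoring.mismatch
            if h == H[i - 1, j - 1] + s:
                if q[j - 1] == t[i - 1]:
                    n_match += 1
                else:
                    n_mismatch += 1
                i -= 1
                j -= 1
                continue
        if i > 0 and h == H[i - 1, j] + gap:
            n_del += 1
            i -= 1
            continue
        if j > 0 and h == H[i, j - 1] + gap:
            n_ins += 1
            j -= 1
            continue
        raise AssertionError("traceback failed: inconsistent DP matrix")
    return AlignmentResult(
        score=score,
        query_start=j,
        query_end=end[1],
        target_start=i,
        target_end=end[0],
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_ins=n_ins,
        n_del=n_del,
    )


_MAX_TIED_ENDS = 256


def local_align(query: str, target: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment (score >= 0, linear gaps)."""
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    H = _score_matrix(query, target, scoring, local=True)
    best = int(H.max())
    if best == 0:
        # no positive-scoring island; report an empty alignment at origin
        return AlignmentResult(0, 0, 0, 0, 0, 0, 0, 0, 0)
    ends = np.argwhere(H == best)
    if len(ends) > _MAX_TIED_ENDS:
        ends = ends[:_MAX_TIED_ENDS]
    results = [
        _traceback(H, query, target, scoring, (int(i), int(j)), local=True)
        for i, j in ends
    ]
    results.sort(key=lambda r: (r.query_start, r.target_start, r.query_end, r.target_end))
    return results[0]


def global_align(query: str, target: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal Needleman-Wunsch end-to-end alignment (linear gaps)."""
    if not query or not target:
        raise ValueError("global_align requires non-empty sequences")
    H = _score_matrix(query, target, scoring, local=False)
    return _traceback(H, query, target, scoring, (len(target), len(query)), local=False)


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character edits transforming ``a`` into ``b``."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    qa = _encode(a)
    qb = _encode(b)
    n = qa.size
    j_idx = np.arange(n + 1, dtype=np.int64)
    prev = j_idx.copy()
    for i in range(1, qb.size + 1):
        subst = prev[:-1] + (qa != qb[i - 1])
        cand = np.empty(n + 1, dtype=np.int64)
        cand[0] = i
        cand[1:] = np.minimum(subst, prev[1:] + 1)
        # cand[j] then min with cand[j-1] + 1, resolved by a running-min scan
        shifted = cand - j_idx
        np.minimum.accumulate(shifted, out=shifted)
        prev = shifted + j_idx
    return int(prev[-1])


def error_rate(result: AlignmentResult) -> float:
    """(mismatches + insertions + deletions) / alignment columns."""
    cols = result.columns
    if cols == 0:
        raise ValueError("error rate undefined for an empty alignment")
    return (result.n_mismatch + result.n_ins + result.n_del) / cols
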