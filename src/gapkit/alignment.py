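"""Deterministic affine-gap global alignment (Gotoh's algorithm).

Scoring: match +1, mismatch -1, a gap of length k costs
|gap_open| + (k-1)*|gap_extend| (first gap column pays the open score).
For gap-mode queries the reference's end gaps can be made free
(semi-global: the query is aligned in full, reference overhangs cost
nothing and contribute no alignment columns).

Identity must be a deterministic function of the inputs even when several
alignments share the optimal score, so the dynamic programme optimises the
lexicographic objective (score, matches, -columns): among score-optimal
alignments it maximises match columns, then minimises total columns. The
triple is packed into a single int64 per cell (score * 2^25 +
matches * 2^13 + (2^12 - columns)), which keeps the recurrence a plain
integer max and allows a vectorised row sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_W2 = 1 << 13          # weight of the match count
_W1 = _W2 << 12        # weight of the score
_CMAX = 1 << 12        # column-count offset (columns are bounded by 2^12)
_NEG = -(1 << 61)


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _encode_deltas(match: int, mismatch: int, gap_open: int, gap_extend: int):
    return (
        match * _W1 + _W2 - 1,   # match column
        mismatch * _W1 - 1,      # mismatch column
        gap_open * _W1 - 1,      # first column of a gap
        gap_extend * _W1 - 1,    # each further gap column
    )


def global_align(
    query: str,
    ref: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -2,
    gap_extend: int = -1,
    free_ref_end_gaps: bool = False,
) -> AlignmentResult:
    """Align ``query`` against ``ref`` and return score/matches/columns.

    With ``free_ref_end_gaps`` the alignment may skip any reference prefix
    and suffix at no cost; those reference bases contribute no columns,
    which matches an identity denominator that excludes free end gaps.
    """
    if not query or not ref:
        raise ValueError("empty sequence in alignment")
    if len(query) + len(ref) >= _CMAX:
        raise ValueError("sequences too long for the packed DP encoding")
    d_match, d_mism, d_open, d_ext = _encode_deltas(
        match, mismatch, gap_open, gap_extend
    )
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    m, n = len(q), len(r)
    idx = np.arange(n + 1, dtype=np.int64)

    # state rows: M substitution column, X gap column consuming the query,
    # Y gap column consuming the reference
    M = np.full(n + 1, _NEG, dtype=np.int64)
    X = np.full(n + 1, _NEG, dtype=np.int64)
    Y = np.full(n + 1, _NEG, dtype=np.int64)
    if free_ref_end_gaps:
        M[:] = _CMAX  # alignment may start after any reference prefix
    else:
        M[0] = _CMAX
        if n:
            Y[1:] = _CMAX + d_open + (idx[1:] - 1) * d_ext

    ext_ramp = idx * d_ext
    for i in range(1, m + 1):
        sub = np.where(q[i - 1] == r, d_match, d_mism)
        newX = np.maximum(M + d_open, X + d_ext)
        diag = np.maximum(np.maximum(M[:-1], X[:-1]), Y[:-1])
        newM = np.full(n + 1, _NEG, dtype=np.int64)
        newM[1:] = diag + sub
        # Y opens only from M within the row: running max via the ramp trick
        newY = np.full(n + 1, _NEG, dtype=np.int64)
        if n:
            ramped = np.maximum.accumulate(newM[:-1] - ext_ramp[:-1])
            newY[1:] = ramped + d_open + (idx[1:] - 1) * d_ext
        M, X, Y = newM, newX, newY

    if free_ref_end_gaps:
        best = int(max(M.max(), X.max(), Y.max()))
    else:
        best = int(max(M[n], X[n], Y[n]))
    return _decode(best)


def _decode(value: int) -> AlignmentResult:
    score, low = divmod(value, _W1)
    matches, rem = divmod(low, _W2)
    return AlignmentResult(score=int(score), matches=int(matches),
                           columns=int(_CMAX - rem))
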