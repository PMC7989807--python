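"""Per-read quality processing shared by the assembly and gap pipelines.

Three steps, applied in order: 3' quality trimming (the cutadapt/BWA
partial-sum algorithm at Q15), fixed-length truncation, then expected-error
and ambiguous-base filtering. Expected errors are computed on the truncated
read, matching the semantics of the DADA2 ``filterAndTrim`` step the
pipeline mirrors (maxEE = 2 per mate, maxN = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .formats_io import PairedRead

Mode = Literal["assembly", "gap"]

#: Rejection reasons reported by :func:`filter_and_truncate`.
REASONS = ("too_short", "max_ee", "max_n")


@dataclass(frozen=True)
class QCParams:
    """Quality-control parameters.

    trim_q : Phred threshold for 3' quality trimming (default 15).
    max_ee : maximum expected errors per mate; a read with EE exactly at
        the threshold is kept (default 2.0).
    max_n : maximum number of N bases per mate (default 0).
    trunc_len : fixed truncation length per mate in assembly mode (229,
        chosen so two truncated 300-bp mates overlap by 10 bases on a
        448-bp amplicon).
    min_len : minimum/truncation length; 229 in assembly mode, 200 in gap
        mode (gap-mode mates are truncated to exactly this length so the
        concatenated product has a fixed gap-junction coordinate).
    primer_trim : optional (fwd, rev) fixed-length 5' prefixes to remove
        before any other processing; off by default.
    """

    trim_q: int = 15
    max_ee: float = 2.0
    max_n: int = 0
    trunc_len: int | None = 229
    min_len: int = 229
    primer_trim: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.trim_q < 0:
            raise ValueError("trim_q must be >= 0")
        if self.max_ee <= 0:
            raise ValueError("max_ee must be > 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.trunc_len is not None and self.trunc_len < self.min_len:
            raise ValueError("trunc_len must be >= min_len")


#: Defaults used by each pipeline mode.
ASSEMBLY_QC = QCParams(trunc_len=229, min_len=229)
GAP_QC = QCParams(trunc_len=None, min_len=200)


def quality_trim_3prime(seq: str, quals: Sequence[int],
                        trim_q: int) -> tuple[str, tuple[int, ...]]:
    """Trim low-quality 3' tails by the BWA/cutadapt partial-sum rule.

    Subtract ``trim_q`` from each quality, accumulate running sums from the
    3' end, and cut at the position minimising the running sum (keeping the
    5' prefix). Never lengthens the read; may return an empty read.
    """
    if len(seq) != len(quals):
        raise ValueError("seq/qual length mismatch")
    n = len(seq)
    if n == 0:
        return "", ()
    best_pos, best_sum, running = n, 0.0, 0.0
    for k in range(n - 1, -1, -1):
        running += quals[k] - trim_q
        if running < best_sum:  # strict: ties keep the longer read
            best_sum, best_pos = running, k
    return seq[:best_pos], tuple(quals[:best_pos])


def expected_errors(quals: Sequence[int]) -> float:
    """Expected number of erroneous bases, sum of 10^(-Q/10)."""
    if len(quals) == 0:
        return 0.0
    q = np.asarray(quals, dtype=float)
    return float(np.sum(10.0 ** (-q / 10.0)))


@dataclass(frozen=True)
class ProcessedPair:
    read_id: str
    fwd_seq: str
    fwd_qual: tuple[int, ...]
    rev_seq: str
    rev_qual: tuple[int, ...]


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


def _trim_pair(pair: PairedRead, params: QCParams) -> PairedRead:
    fs, fq = pair.fwd_seq, pair.fwd_qual
    rs, rq = pair.rev_seq, pair.rev_qual
    if params.primer_trim is not None:
        pf, pr = params.primer_trim
        fs, fq = fs[pf:], fq[pf:]
        rs, rq = rs[pr:], rq[pr:]
    fs, fq = quality_trim_3prime(fs, fq, params.trim_q)
    rs, rq = quality_trim_3prime(rs, rq, params.trim_q)
    return replace(pair, fwd_seq=fs, fwd_qual=fq, rev_seq=rs, rev_qual=rq)


def filter_and_truncate(pair: PairedRead, params: QCParams,
                        mode: Mode) -> ProcessedPair | Rejection:
    """Length-select, truncate and filter a quality-trimmed read pair.

    Assembly mode rejects pairs with a mate shorter than ``trunc_len`` and
    truncates both mates to exactly ``trunc_len``; gap mode does the same
    with ``min_len``. Expected-error (> max_ee rejects) and N-count tests
    run on the truncated mates. Returns a :class:`Rejection` with reason
    ``too_short``, ``max_ee`` or ``max_n`` when the pair fails.
    """
    if mode == "assembly":
        if params.trunc_len is None:
            raise ValueError("assembly mode requires trunc_len")
        cut = params.trunc_len
    elif mode == "gap":
        cut = params.min_len
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if len(pair.fwd_seq) < cut or len(pair.rev_seq) < cut:
        return Rejection(pair.read_id, "too_short")
    fs, fq = pair.fwd_seq[:cut], pair.fwd_qual[:cut]
    rs, rq = pair.rev_seq[:cut], pair.rev_qual[:cut]
    if expected_errors(fq) > params.max_ee or expected_errors(rq) > params.max_ee:
        return Rejection(pair.read_id, "max_ee")
    if fs.count("N") > params.max_n or rs.count("N") > params.max_n:
        return Rejection(pair.read_id, "max_n")
    return ProcessedPair(pair.read_id, fs, fq, rs, rq)


def qc_pair(pair: PairedRead, params: QCParams,
            mode: Mode) -> ProcessedPair | Rejection:
    """Full per-pair QC: trim then filter/truncate."""
    return filter_and_truncate(_trim_pair(pair, params), params, mode)
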