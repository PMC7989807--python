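"""The two read-joining strategies.

"Assembly": score the ungapped overlap between the forward read's 3' end
and the reverse-complemented reverse read's 5' end, merge at the best
overlap, then truncate the merged amplicon to a fixed length (448 by
default). "Gap": reverse-complement the reverse mate and concatenate it to
the forward mate, leaving the unsequenced centre of the amplicon out and
recording the junction coordinate as metadata (no placeholder characters
are inserted — they would corrupt identity computation downstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProcessedAmplicon:
    """A joined amplicon sequence from either pipeline.

    ``gap_junction`` is the 0-based index of the first base contributed by
    the reverse mate; present iff ``mode == "gap"``.
    """

    seq: str
    mode: str
    provenance: str = ""
    gap_junction: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "gap":
            if self.gap_junction is None or not (
                0 < self.gap_junction < len(self.seq)
            ):
                raise ValueError("gap mode requires 0 < gap_junction < len(seq)")
        elif self.mode == "assembly":
            if self.gap_junction is not None:
                raise ValueError("assembly mode must not carry a gap_junction")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class MergeFailure:
    reason: str = "no_overlap"


def merge_overlap(
    fwd: tuple[str, Sequence[int]],
    rev: tuple[str, Sequence[int]],
    min_overlap: int = 10,
    min_identity: float = 0.9,
) -> tuple[str, tuple[int, ...]] | MergeFailure:
    """Merge a read pair across the best-scoring ungapped 3'/5' overlap.

    The reverse mate is given as sequenced and reverse-complemented here.
    Candidate overlaps of length ``ov`` (min_overlap <= ov <= min mate
    length, i.e. no staggered/read-through layouts) are scored as
    matches - mismatches; the best-scoring candidate whose fractional
    identity is >= ``min_identity`` wins, ties going to the longer overlap.
    Within the overlap, mismatched positions take the base with the higher
    Phred score (keeping that quality) and matches keep the higher of the
    two qualities. Returns :class:`MergeFailure` when no candidate passes.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    fseq, fqual = fwd
    rseq_raw, rqual_raw = rev
    rseq = reverse_complement(rseq_raw)
    rqual = tuple(rqual_raw)[::-1]
    m, n = len(fseq), len(rseq)
    if min(m, n) < min_overlap:
        return MergeFailure()

    fa = np.frombuffer(fseq.encode(), dtype=np.uint8)
    ra = np.frombuffer(rseq.encode(), dtype=np.uint8)
    best: tuple[int, int] | None = None  # (score, ov)
    for ov in range(min_overlap, min(m, n) + 1):
        matches = int(np.count_nonzero(fa[m - ov:] == ra[:ov]))
        if matches / ov < min_identity:
            continue
        score = 2 * matches - ov  # matches - mismatches
        if best is None or (score, ov) > best:
            best = (score, ov)
    if best is None:
        return MergeFailure()
    _, ov = best

    mid_seq: list[str] = []
    mid_qual: list[int] = []
    for i in range(ov):
        bf, qf = fseq[m - ov + i], fqual[m - ov + i]
        br, qr = rseq[i], rqual[i]
        if bf == br:
            mid_seq.append(bf)
            mid_qual.append(max(qf, qr))
        elif qf >= qr:  # forward mate wins ties
            mid_seq.append(bf)
            mid_qual.append(qf)
        else:
            mid_seq.append(br)
            mid_qual.append(qr)
    seq = fseq[: m - ov] + "".join(mid_seq) + rseq[ov:]
    quals = tuple(fqual[: m - ov]) + tuple(mid_qual) + tuple(rqual[ov:])
    return seq, quals


def expected_overlap(trunc_len: int, amplicon_trunclen: int) -> int:
    """Paired-end overlap implied by per-mate and amplicon truncation
    lengths (2*229 - 448 = 10 under the assembly-pipeline defaults)."""
    return 2 * trunc_len - amplicon_trunclen


def truncate_amplicon(seq: str, trunclen: int = 448) -> str | None:
    """Cut a merged amplicon to exactly ``trunclen`` from the 5' end;
    shorter sequences are rejected (returns None)."""
    if len(seq) < trunclen:
        return None
    return seq[:trunclen]


def concat_gapped(fwd: str, rev: str, read_id: str = "") -> ProcessedAmplicon:
    """Concatenate the forward mate with the reverse-complemented reverse
    mate; the gap junction sits at ``len(fwd)``."""
    if not fwd or not rev:
        raise ValueError("empty mate in gapped concatenation")
    seq = fwd + reverse_complement(rev)
    return ProcessedAmplicon(seq=seq, mode="gap", provenance=read_id,
                             gap_junction=len(fwd))
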