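"""Dereplication, frame-aware stop-codon filtering and chimera/singleton
removal.

The denoising step deliberately reproduces only the two behaviours the
pipeline needs from an abundance-aware denoiser: a perfect two-parent
chimera model (a candidate is chimeric when two more-abundant uniques can
be spliced at some breakpoint to reconstruct it) and singleton removal.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from .pair_join import ProcessedAmplicon

logger = logging.getLogger("gapkit")


@dataclass(frozen=True)
class UniqueSequence:
    seq: str
    size: int
    mode: str = "assembly"
    gap_junction: int | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("size must be >= 1")


def dereplicate(amplicons: Sequence[ProcessedAmplicon]) -> list[UniqueSequence]:
    """Collapse identical sequences at 100% identity, keeping abundance.

    Output is sorted by size descending, ties broken lexicographically by
    sequence. All inputs must share a mode (and gap junction, in gap mode).
    """
    if not amplicons:
        return []
    modes = {a.mode for a in amplicons}
    if len(modes) > 1:
        raise ValueError(f"mixed pipeline modes in dereplication: {sorted(modes)}")
    junctions = {a.gap_junction for a in amplicons}
    if len(junctions) > 1:
        raise ValueError("mixed gap junctions in dereplication")
    mode, junction = modes.pop(), junctions.pop()
    counts = Counter(a.seq for a in amplicons)
    return [
        UniqueSequence(seq, size, mode=mode, gap_junction=junction)
        for seq, size in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def stop_codons(table_id: int = 1) -> frozenset[str]:
    """Stop codons of an NCBI translation table (default: standard code)."""
    return frozenset(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)


def _has_stop(segment: str, frame_offset: int, stops: frozenset[str]) -> bool:
    # trailing partial codon ignored; codons containing N are skipped
    for i in range(frame_offset, len(segment) - 2, 3):
        codon = segment[i : i + 3]
        if "N" in codon:
            logger.debug("codon with N skipped at offset %d", i)
            continue
        if codon in stops:
            return True
    return False


def translation_filter(
    unique: UniqueSequence,
    frame_offset: int = 0,
    rev_frame_offset: int = 0,
    table_id: int = 1,
) -> bool:
    """True if the unique survives the stop-codon filter.

    Assembly mode translates the whole sequence from ``frame_offset``. Gap
    mode translates the forward segment (up to the gap junction) and the
    reverse segment (from the junction, phase-shifted by
    ``rev_frame_offset``) independently, so no codon ever spans the
    junction; the unique is discarded if either segment contains a stop.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be in {0,1,2}")
    stops = stop_codons(table_id)
    if unique.mode == "gap":
        j = unique.gap_junction
        if j is None:
            raise ValueError("gap-mode unique lacks a gap_junction")
        fwd, rev = unique.seq[:j], unique.seq[j:]
        return not (
            _has_stop(fwd, frame_offset, stops)
            or _has_stop(rev, rev_frame_offset, stops)
        )
    return not _has_stop(unique.seq, frame_offset, stops)


def reverse_frame_offset(amplicon_len: int, seg_len: int,
                         frame_offset: int = 0) -> int:
    """Codon phase of the first base of a gap-mode reverse segment.

    The reverse segment covers template positions
    ``[amplicon_len - seg_len, amplicon_len)``; the returned offset shifts
    to the first complete codon of the frame defined by ``frame_offset``.
    """
    start = amplicon_len - seg_len
    return (frame_offset - start) % 3


def flag_chimeras(
    uniques: Sequence[UniqueSequence],
    skew: float = 2.0,
    max_diffs: int = 0,
) -> list[bool]:
    """Flag each unique as chimeric under the two-parent breakpoint model.

    A candidate is chimeric iff two earlier (more abundant by the ``skew``
    factor) uniques A and B of the same length admit a breakpoint b with
    A[:b] + B[b:] matching the candidate with at most ``max_diffs``
    mismatches; both parent orderings are tried. A candidate explained by
    a SINGLE earlier unique within ``max_diffs`` is never chimeric (the
    breakpoint model must genuinely need two parents). Input must be
    sorted by size descending.
    """
    sizes = [u.size for u in uniques]
    if sizes != sorted(sizes, reverse=True):
        raise ValueError("uniques must be sorted by size descending")
    arrs = [np.frombuffer(u.seq.encode(), dtype=np.uint8) for u in uniques]
    flags: list[bool] = []
    for idx, cand in enumerate(uniques):
        L = len(cand.seq)
        earlier = [p for p in range(idx) if len(uniques[p].seq) == L]
        if any(int(np.count_nonzero(arrs[idx] != arrs[p])) <= max_diffs
               for p in earlier):
            flags.append(False)
            continue
        parents = [
            p for p in earlier if uniques[p].size >= skew * cand.size
        ]
        flags.append(_is_chimera(arrs[idx], [arrs[p] for p in parents], max_diffs))
    return flags


def _is_chimera(cand: np.ndarray, parents: list[np.ndarray],
                max_diffs: int) -> bool:
    if len(parents) < 2:
        return False
    L = len(cand)
    # prefix[k] = mismatches of cand[:k] vs parent; suffix[k] = of cand[k:]
    prefix, suffix = [], []
    for p in parents:
        d = (cand != p).astype(np.int64)
        c = np.concatenate(([0], np.cumsum(d)))
        prefix.append(c)
        suffix.append(c[-1] - c)
    b = np.arange(1, L)  # breakpoints; both parents must contribute
    for i in range(len(parents)):
        for j in range(len(parents)):
            if i == j:
                continue
            total = prefix[i][b] + suffix[j][b]
            if total.min() <= max_diffs:
                return True
    return False


def remove_singletons(uniques: Iterable[UniqueSequence]) -> list[UniqueSequence]:
    """Drop uniques with abundance 1."""
    kept = [u for u in uniques if u.size > 1]
    if not kept:
        logger.warning("all uniques were singletons; nothing retained")
    return kept
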