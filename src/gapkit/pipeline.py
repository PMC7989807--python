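"""The two named pipelines, chained end to end.

Stage order is fixed: QC (trim, truncate, EE/N filter) -> join (overlap
merge or gapped concatenation) -> dereplication -> stop-codon filter ->
chimera flagging -> singleton removal. Every stage's input/kept/rejected
counts are recorded and telescope (a stage's input equals the previous
stage's kept count).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

from . import __version__
from .derep_denoise import (
    UniqueSequence,
    dereplicate,
    flag_chimeras,
    remove_singletons,
    translation_filter,
)
from .formats_io import PairedRead, SampleManifest, read_fastq_pairs
from .pair_join import (
    MergeFailure,
    ProcessedAmplicon,
    concat_gapped,
    merge_overlap,
    truncate_amplicon,
)
from .read_prep import ASSEMBLY_QC, GAP_QC, QCParams, Rejection, qc_pair


@dataclass
class StageCount:
    stage: str
    n_input: int
    n_kept: int
    rejected: dict[str, int] = field(default_factory=dict)

    #: for dereplication, kept counts uniques while abundance is conserved
    abundance_kept: int | None = None


@dataclass
class PipelineRunRecord:
    mode: str
    params: dict
    stages: list[StageCount] = field(default_factory=list)
    version: str = __version__
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    def validate_telescope(self) -> None:
        """Counts must telescope across the read-level stages."""
        for prev, cur in zip(self.stages, self.stages[1:]):
            expected = prev.n_kept if prev.abundance_kept is None \
                else prev.abundance_kept
            if cur.n_input not in (prev.n_kept, expected):
                raise AssertionError(
                    f"stage {cur.stage} input {cur.n_input} does not match "
                    f"previous kept {prev.n_kept}"
                )


@dataclass
class PipelineOptions:
    qc: QCParams | None = None
    min_overlap: int = 10
    min_identity: float = 0.9
    amplicon_trunclen: int = 448
    frame_offset: int = 0
    rev_frame_offset: int = 0
    translation_table: int = 1
    chimera_skew: float = 2.0
    chimera_max_diffs: int = 0
    remove_chimeras: bool = True
    drop_singletons: bool = True

    def qc_params(self, mode: str) -> QCParams:
        if self.qc is not None:
            return self.qc
        return ASSEMBLY_QC if mode == "assembly" else GAP_QC


def process_sample(
    reads: Iterable[PairedRead],
    mode: str,
    options: PipelineOptions | None = None,
) -> tuple[list[UniqueSequence], PipelineRunRecord]:
    """Run one sample's read pairs through the full pipeline."""
    if mode not in ("assembly", "gap"):
        raise ValueError(f"unknown mode {mode!r}")
    opts = options or PipelineOptions()
    params = opts.qc_params(mode)
    record = PipelineRunRecord(
        mode=mode,
        params={
            "trim_q": params.trim_q, "max_ee": params.max_ee,
            "max_n": params.max_n, "trunc_len": params.trunc_len,
            "min_len": params.min_len, "min_overlap": opts.min_overlap,
            "min_identity": opts.min_identity,
            "amplicon_trunclen": opts.amplicon_trunclen,
            "frame_offset": opts.frame_offset,
            "rev_frame_offset": opts.rev_frame_offset,
            "chimera_skew": opts.chimera_skew,
            "chimera_max_diffs": opts.chimera_max_diffs,
        },
        started=time.time(),
    )

    # stage 1: QC
    n_in = 0
    kept_pairs = []
    qc_rejects: dict[str, int] = {}
    for pair in reads:
        n_in += 1
        result = qc_pair(pair, params, mode)
        if isinstance(result, Rejection):
            qc_rejects[result.reason] = qc_rejects.get(result.reason, 0) + 1
        else:
            kept_pairs.append(result)
    record.stages.append(StageCount("qc", n_in, len(kept_pairs), qc_rejects))

    # stage 2: join
    amplicons: list[ProcessedAmplicon] = []
    join_rejects: dict[str, int] = {}
    if mode == "assembly":
        merge_cache: dict[tuple, ProcessedAmplicon | None] = {}
        for p in kept_pairs:
            key = (p.fwd_seq, bytes(p.fwd_qual), p.rev_seq, bytes(p.rev_qual))
            if key in merge_cache:
                hit = merge_cache[key]
                if hit is None:
                    reason = "no_overlap_or_short"
                    join_rejects[reason] = join_rejects.get(reason, 0) + 1
                else:
                    amplicons.append(ProcessedAmplicon(
                        hit.seq, "assembly", provenance=p.read_id))
                continue
            merged = merge_overlap(
                (p.fwd_seq, p.fwd_qual), (p.rev_seq, p.rev_qual),
                min_overlap=opts.min_overlap, min_identity=opts.min_identity,
            )
            amp = None
            if not isinstance(merged, MergeFailure):
                seq = truncate_amplicon(merged[0], opts.amplicon_trunclen)
                if seq is not None:
                    amp = ProcessedAmplicon(seq, "assembly",
                                            provenance=p.read_id)
            merge_cache[key] = amp
            if amp is None:
                reason = "no_overlap_or_short"
                join_rejects[reason] = join_rejects.get(reason, 0) + 1
            else:
                amplicons.append(amp)
    else:
        for p in kept_pairs:
            amplicons.append(concat_gapped(p.fwd_seq, p.rev_seq, p.read_id))
    record.stages.append(
        StageCount("join", len(kept_pairs), len(amplicons), join_rejects)
    )

    # stage 3: dereplication (abundance conserved)
    uniques = dereplicate(amplicons)
    record.stages.append(StageCount(
        "dereplicate", len(amplicons), len(uniques),
        abundance_kept=sum(u.size for u in uniques),
    ))

    # stage 4: stop-codon filter
    translated = [
        u for u in uniques
        if translation_filter(u, opts.frame_offset, opts.rev_frame_offset,
                              opts.translation_table)
    ]
    record.stages.append(StageCount(
        "translation_filter", len(uniques), len(translated),
        {"stop_codon": len(uniques) - len(translated)},
        abundance_kept=sum(u.size for u in translated),
    ))

    # stage 5: chimera removal
    if opts.remove_chimeras:
        flags = flag_chimeras(translated, skew=opts.chimera_skew,
                              max_diffs=opts.chimera_max_diffs)
        clean = [u for u, f in zip(translated, flags) if not f]
    else:
        clean = list(translated)
    record.stages.append(StageCount(
        "chimera", len(translated), len(clean),
        {"chimeric": len(translated) - len(clean)},
        abundance_kept=sum(u.size for u in clean),
    ))

    # stage 6: singleton removal
    if opts.drop_singletons:
        final = remove_singletons(clean)
    else:
        final = clean
    record.stages.append(StageCount(
        "singletons", len(clean), len(final),
        {"singleton": len(clean) - len(final)},
        abundance_kept=sum(u.size for u in final),
    ))
    record.finished = time.time()
    return final, record


def run_pipeline(
    manifest: SampleManifest,
    mode: str,
    options: PipelineOptions | None = None,
) -> dict[str, tuple[list[UniqueSequence], PipelineRunRecord]]:
    """Run every manifest sample through :func:`process_sample`."""
    if not manifest.samples:
        raise ValueError("empty manifest")
    out = {}
    for sample_id, fwd, rev in manifest.samples:
        try:
            reads = read_fastq_pairs(fwd, rev)
            out[sample_id] = process_sample(reads, mode, options)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for sample {sample_id!r}: {exc}"
            ) from exc
    return out
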