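"""Readers and writers for the toolkit's file formats.

FASTQ (4-line, Phred+33), FASTA with ``;size=N`` abundance annotations,
TSV sample manifests / environmental metadata, and the packaged strain
lineage table. Sequence I/O is delegated to Biopython's SeqIO; this module
adds the paired-read pairing checks, the abundance-annotation dialect and
the domain containers used throughout the pipeline.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("gapkit")

PHRED_OFFSET = 33
#: Characters above 'J' (Q41) essentially never occur in Phred+33 Illumina
#: data but are common in Phred+64; used by the encoding heuristic.
_PHRED64_SENTINEL = chr(ord("!") + 41)

ENV_COLUMNS = ("pH", "C", "N", "C:N", "moisture", "LOI", "vegetation")


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass(frozen=True)
class PairedRead:
    """A forward/reverse Illumina read pair with per-base Phred scores."""

    read_id: str
    fwd_seq: str
    fwd_qual: tuple[int, ...]
    rev_seq: str
    rev_qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual):
            raise ValueError(f"{self.read_id}: forward seq/qual length mismatch")
        if len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"{self.read_id}: reverse seq/qual length mismatch")
        for q in (*self.fwd_qual, *self.rev_qual):
            if not 0 <= q <= 60:
                raise ValueError(f"{self.read_id}: Phred score {q} outside [0, 60]")


@dataclass(frozen=True)
class ReferenceEntry:
    ref_id: str
    cluster_label: str
    sequence: str


@dataclass
class ReferenceDB:
    """Labelled reference sequences grouped into named phylogenetic clusters.

    ``frame_offset`` is the codon phase of position 1 of the amplicon
    (0 when the amplicon starts on a codon boundary). ``rev_frame_offset``
    is the phase of the first base of a gap-mode reverse segment and is
    specific to the truncation lengths the gap pipeline used.
    """

    entries: list[ReferenceEntry]
    frame_offset: int = 0
    rev_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be in {0,1,2}")
        ids = [e.ref_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("reference ids are not unique")
        for e in self.entries:
            if not e.cluster_label:
                raise ValueError(f"reference {e.ref_id} has an empty cluster label")
            if not e.sequence:
                raise ValueError(f"reference {e.ref_id} has an empty sequence")

    @property
    def cluster_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.cluster_label, None)
        return list(seen)


@dataclass(frozen=True)
class StrainRow:
    organism: str
    amoA_lineage: str
    rrna_lineage: str


@dataclass
class StrainTable:
    """Strain -> (amoA lineage, 16S rRNA lineage) affiliation table."""

    rows: list[StrainRow]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class SampleManifest:
    """Per-sample FASTQ paths plus optional environmental metadata."""

    samples: list[tuple[str, Path, Path]]
    env: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = [s for s, _, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids are not unique")
        if self.env is not None:
            missing = set(ids) - set(self.env.index)
            if missing:
                raise ValueError(
                    f"environmental table missing samples: {sorted(missing)}"
                )


def decode_phred(qual_string: str) -> tuple[int, ...]:
    """Decode an ASCII quality string assuming Phred+33."""
    quals = tuple(ord(c) - PHRED_OFFSET for c in qual_string)
    if any(q < 0 for q in quals):
        raise FormatError("quality character below '!' — not Phred+33")
    return quals


def encode_phred(quals: Sequence[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in quals)


def _looks_phred64(qual_strings: Sequence[str]) -> bool:
    # Phred+64 data has no characters below ';' (Q-5 in that encoding sits
    # at ASCII 59) and routinely uses characters above 'J'.
    low = chr(ord("!") + 31)
    has_low = any(c < low for s in qual_strings for c in s)
    has_high = any(c > _PHRED64_SENTINEL for s in qual_strings for c in s)
    return (not has_low) and has_high


def _base_id(record_id: str) -> str:
    # strip a trailing /1, /2 or space-delimited mate tag
    return re.sub(r"/[12]$", "", record_id)


def read_fastq_pairs(fwd_path: str | Path, rev_path: str | Path) -> Iterator[PairedRead]:
    """Stream matched read pairs from two FASTQ files.

    Records must appear in the same order with matching identifiers
    (ignoring a ``/1`` / ``/2`` mate suffix). Phred+64-looking input is
    rejected rather than silently mis-decoded.
    """
    fwd_path, rev_path = Path(fwd_path), Path(rev_path)
    for p in (fwd_path, rev_path):
        _check_fastq_shape(p)
    fwd_iter = SeqIO.parse(str(fwd_path), "fastq")
    rev_iter = SeqIO.parse(str(rev_path), "fastq")
    n = 0
    sniffed: list[str] = []
    while True:
        fwd = next(fwd_iter, None)
        rev = next(rev_iter, None)
        if fwd is None and rev is None:
            break
        if fwd is None or rev is None:
            raise FormatError(
                f"record count mismatch between {fwd_path.name} and "
                f"{rev_path.name} after {n} pairs"
            )
        if _base_id(fwd.id) != _base_id(rev.id):
            raise FormatError(
                f"identifier mismatch at record {n + 1}: "
                f"{fwd.id!r} vs {rev.id!r}"
            )
        fq = tuple(fwd.letter_annotations["phred_quality"])
        rq = tuple(rev.letter_annotations["phred_quality"])
        if len(sniffed) < 50:
            sniffed.append(encode_phred(fq))
            sniffed.append(encode_phred(rq))
            if _looks_phred64(sniffed) and max(max(fq), max(rq)) > 41:
                raise FormatError(
                    "quality strings look Phred+64 encoded; only Phred+33 "
                    "input is accepted"
                )
        n += 1
        yield PairedRead(_base_id(fwd.id), str(fwd.seq).upper(), fq,
                         str(rev.seq).upper(), rq)


def _check_fastq_shape(path: Path) -> None:
    with open(path) as fh:
        n_lines = sum(1 for line in fh if line.strip() or True)
    if n_lines % 4 != 0:
        raise FormatError(
            f"{path.name}: {n_lines} lines is not a multiple of 4 — "
            f"truncated FASTQ near line {n_lines}"
        )


def write_fastq(records: Sequence[tuple[str, str, Sequence[int]]],
                path: str | Path) -> None:
    """Write ``(read_id, seq, quals)`` records as 4-line Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for read_id, seq, quals in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{encode_phred(quals)}\n")


_SIZE_RE = re.compile(r";size=(\d+);?")


def write_fasta_sized(uniques: Sequence, path: str | Path) -> None:
    """Write unique sequences with ``;size=N`` abundance-annotated headers.

    Accepts ``(seq, size)`` tuples or any object with ``seq``/``size``
    attributes (e.g. :class:`~gapkit.derep_denoise.UniqueSequence`).
    """
    records = []
    for i, u in enumerate(uniques):
        seq, size = (u if isinstance(u, tuple) else (u.seq, u.size))
        if size < 1:
            raise ValueError(f"abundance must be >= 1, got {size}")
        records.append(SeqRecord(Seq(seq), id=f"Uniq{i + 1};size={size}",
                                 description=""))
    SeqIO.write(records, str(path), "fasta-2line")


def read_fasta_sized(path: str | Path) -> list[tuple[str, int]]:
    """Read a ``;size=N``-annotated FASTA back to ``(seq, size)`` pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _SIZE_RE.search(rec.id)
        if not m:
            raise FormatError(f"header {rec.id!r} lacks a ;size= annotation")
        out.append((str(rec.seq).upper(), int(m.group(1))))
    return out


def read_reference_fasta(path: str | Path, frame_offset: int = 0,
                         rev_frame_offset: int = 0) -> ReferenceDB:
    """Load references whose headers carry ``cluster=<label>`` tags."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = re.search(r"cluster=(\S+)", rec.description)
        if not m:
            raise FormatError(f"reference {rec.id!r} lacks a cluster= tag")
        entries.append(ReferenceEntry(rec.id, m.group(1), str(rec.seq).upper()))
    return ReferenceDB(entries, frame_offset=frame_offset,
                       rev_frame_offset=rev_frame_offset)


def write_reference_fasta(refdb: ReferenceDB, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.ref_id,
                  description=f"cluster={e.cluster_label}")
        for e in refdb.entries
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def load_strain_table(path: str | Path | None = None) -> StrainTable:
    """Load a 3-column strain lineage TSV (default: the packaged table).

    Columns: organism, amoA_lineage, rrna_lineage. Duplicate organism
    names are rejected; an empty table is accepted with a warning.
    """
    if path is None:
        path = resources.files("gapkit.data") / "table1_strain_lineages.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("organism", "amoA_lineage", "rrna_lineage"):
        if col not in df.columns:
            raise FormatError(f"strain table missing column {col!r}")
    if df.empty:
        logger.warning("strain table %s is empty", path)
        return StrainTable([])
    dup = df["organism"][df["organism"].duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicate organism name {dup.iloc[0]!r}")
    if df[["amoA_lineage", "rrna_lineage"]].isna().any().any():
        raise FormatError("strain table has empty lineage labels")
    rows = [StrainRow(r.organism, r.amoA_lineage, r.rrna_lineage)
            for r in df.itertuples(index=False)]
    return StrainTable(rows)


def load_manifest(manifest_path: str | Path,
                  env_path: str | Path | None = None) -> SampleManifest:
    """Load a sample manifest TSV (sample_id, fastq_fwd, fastq_rev) and an
    optional environmental metadata TSV indexed by sample_id."""
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    for col in ("sample_id", "fastq_fwd", "fastq_rev"):
        if col not in df.columns:
            raise FormatError(f"manifest missing column {col!r}")
    base = Path(manifest_path).parent
    samples = [
        (r.sample_id, base / r.fastq_fwd, base / r.fastq_rev)
        for r in df.itertuples(index=False)
    ]
    env = None
    if env_path is not None:
        env = load_env_table(env_path)
    return SampleManifest(samples, env)


def load_env_table(path: str | Path) -> pd.DataFrame:
    """Load environmental metadata TSV with a sample_id index column."""
    env = pd.read_csv(path, sep="\t", index_col=0)
    env.index = env.index.astype(str)
    return env


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a samples x clusters abundance matrix TSV."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
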