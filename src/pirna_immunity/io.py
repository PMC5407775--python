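"""Small-RNA read containers, preprocessing, and standard-format IO.

Preprocessing follows the library-construction conventions of the analysis:
3'-adapter clipping (reads without a detectable adapter are discarded),
a strict minimal length filter (>18 nt, i.e. length >= 19), and removal of
reads containing disallowed characters.  All internal coordinates are
0-based half-open; BED is native, SAM and GFF are converted on ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

log = logging.getLogger(__name__)

TISSUES = ("ovary", "embryo_0_2h")

_ALLOWED = frozenset("ACGT")


@dataclass(slots=True)
class SmallRNARead:
    """A clipped small-RNA read.  U is stored as T."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Library:
    """A strain+tissue collection of reads with a normalization depth.

    ``depth`` is the denominator used for RPM normalization.  By default it
    is set by the pipeline to the number of reads surviving clip+filter
    (``depth_mode='filtered'``); the genome-mapped alternative is available
    through :func:`pirna_immunity.mapping.genome_mapped_depth`.
    """

    strain: str
    tissue: str
    reads: list[SmallRNARead] = field(default_factory=list)
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def clip_adapter(
    reads: Iterable[SmallRNARead], adapter: str, min_overlap: int = 6
) -> list[SmallRNARead]:
    """Remove the 3' adapter from each read; discard reads without one.

    The 3'-most match of an adapter prefix of length >= ``min_overlap`` is
    removed: either a full adapter occurrence inside the read, or an adapter
    prefix aligned flush with the read's 3' end.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = adapter.upper().replace("U", "T")
    if min_overlap < 1 or min_overlap > len(adapter):
        raise ValueError("require 1 <= min_overlap <= len(adapter)")

    kept: list[SmallRNARead] = []
    n_in = 0
    for read in reads:
        n_in += 1
        cut = _adapter_cut(read.sequence, adapter, min_overlap)
        if cut is None:
            continue
        kept.append(SmallRNARead(read.id, read.sequence[:cut]))
    log.info("clip_adapter: %d/%d reads retained an adapter match", len(kept), n_in)
    return kept


def _adapter_cut(seq: str, adapter: str, min_overlap: int) -> int | None:
    # full adapter occurrences anywhere (read-through)
    best = -1
    i = seq.find(adapter)
    while i != -1:
        best = max(best, i)
        i = seq.find(adapter, i + 1)
    # adapter prefix flush with the 3' end
    for k in range(len(seq) - min_overlap, max(best, -1), -1):
        if seq.endswith(adapter[: len(seq) - k], k) and len(seq) - k >= min_overlap:
            if k > best:
                best = k
            break
    return best if best >= 0 else None


def filter_reads(
    reads: Iterable[SmallRNARead], min_len: int = 19, max_n_fraction: float = 0.0
) -> list[SmallRNARead]:
    """Keep reads with length >= ``min_len`` and an allowed alphabet.

    ``max_n_fraction`` is the tolerated fraction of N bases (default 0:
    any N discards the read).  Characters outside ACGTN always discard.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept: list[SmallRNARead] = []
    n_in = 0
    for read in reads:
        n_in += 1
        seq = read.sequence
        if len(seq) < min_len:
            continue
        n_count = seq.count("N")
        if n_count and n_count / len(seq) > max_n_fraction:
            continue
        if not set(seq) <= (_ALLOWED | {"N"}):
            continue
        kept.append(read)
    if n_in and not kept:
        log.warning("filter_reads: no reads survived filtering (input %d)", n_in)
    else:
        log.info("filter_reads: %d/%d reads kept", len(kept), n_in)
    return kept


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[SmallRNARead]:
    """Parse a FASTQ file into reads.  Malformed records name their line."""
    reads: list[SmallRNARead] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: truncated FASTQ (line count {len(lines)} not a multiple of 4)")
    for rec in range(0, len(lines), 4):
        header, seq, plus, qual = lines[rec : rec + 4]
        if not header.startswith("@"):
            raise ValueError(f"{path}: line {rec + 1}: expected '@' header, got {header[:20]!r}")
        if not plus.startswith("+"):
            raise ValueError(f"{path}: line {rec + 3}: expected '+' separator")
        if len(seq) != len(qual):
            raise ValueError(f"{path}: line {rec + 2}: sequence/quality length mismatch")
        reads.append(SmallRNARead(header[1:].split()[0], seq))
    return reads


def write_fastq(reads: Iterable[SmallRNARead], path: str | Path, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{quality * read.length}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse FASTA into an ordered {id: sequence} mapping (via Biopython)."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / GFF / SAM
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class BedInterval:
    """A BED6 record; 0-based half-open, as stored on disk."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


def read_bed(path: str | Path) -> list[BedInterval]:
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                iv = BedInterval(
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    parts[3] if len(parts) > 3 else ".",
                    float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0,
                    parts[5] if len(parts) > 5 else ".",
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_gff(path: str | Path) -> list[BedInterval]:
    """Load GFF3 features as BED-semantics intervals (1-based closed -> 0-based half-open)."""
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: line {lineno}: fewer than 9 GFF columns")
            chrom, _source, ftype, start, end, score, strand = parts[0:7]
            name = ftype
            for kv in parts[8].split(";"):
                if kv.startswith(("ID=", "Name=")):
                    name = kv.split("=", 1)[1]
                    break
            out.append(
                BedInterval(
                    chrom,
                    int(start) - 1,
                    int(end),
                    name,
                    0.0 if score == "." else float(score),
                    strand if strand in "+-" else ".",
                )
            )
    return out


@dataclass(slots=True)
class SamAlignment:
    """A mapped SAM record converted to internal conventions.

    FLAG 16 becomes strand '-'; 1-based POS becomes a 0-based start.
    """

    read_id: str
    chrom: str
    start: int
    strand: str
    sequence: str
    mapq: int


def read_sam(path: str | Path, reference_lengths: dict[str, int] | None = None) -> list[SamAlignment]:
    """Ingest mapped records from a SAM file (external-aligner escape hatch)."""
    import pysam

    out: list[SamAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            chrom = rec.reference_name
            start = rec.reference_start  # pysam is already 0-based
            seq = rec.query_sequence or ""
            if reference_lengths is not None:
                ref_len = reference_lengths.get(chrom)
                if ref_len is not None and start + len(seq) > ref_len:
                    raise ValueError(
                        f"{path}: read {rec.query_name} overflows reference {chrom} "
                        f"({start + len(seq)} > {ref_len})"
                    )
            out.append(
                SamAlignment(
                    read_id=rec.query_name,
                    chrom=chrom,
                    start=start,
                    strand="-" if rec.is_reverse else "+",
                    sequence=seq,
                    mapq=rec.mapping_quality,
                )
            )
    return out


def library_from_fastq(
    path: str | Path,
    strain: str,
    tissue: str,
    adapter: str | None = None,
    min_overlap: int = 6,
    min_len: int = 19,
) -> Library:
    """Load a FASTQ and apply the canonical clip -> filter chain.

    The stage order is fixed: clipping always precedes length filtering.
    ``depth`` is set to the surviving read count (``filtered`` depth mode).
    """
    reads = read_fastq(path)
    if adapter:
        reads = clip_adapter(reads, adapter, min_overlap)
    reads = filter_reads(reads, min_len=min_len)
    return Library(strain=strain, tissue=tissue, reads=reads, depth=len(reads))
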