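"""Reads (FASTA/FASTQ) and candidate alignments (SAM, transcript coordinates)."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .reference import TranscriptSet, _sanitize


class InputError(ValueError):
    """Malformed read or alignment input."""


@dataclass
class ReadRecord:
    """A single-end read or a read pair; qualities are Phred+33 strings."""

    id: str
    seq1: str
    qual1: Optional[str] = None
    seq2: Optional[str] = None
    qual2: Optional[str] = None

    def __post_init__(self):
        for seq, qual, mate in ((self.seq1, self.qual1, 1), (self.seq2, self.qual2, 2)):
            if qual is not None and seq is not None and len(qual) != len(seq):
                raise InputError(
                    f"read {self.id!r} mate {mate}: quality/sequence length mismatch"
                )

    @property
    def paired(self) -> bool:
        return self.seq2 is not None


@dataclass(frozen=True)
class Alignment:
    """One candidate placement of a read (pair) on a transcript.

    ``pos`` is 0-based: the fragment's leftmost base for paired reads, the
    read's leftmost base for single-end reads (for reverse-orientation SE
    reads the fragment start depends on the marginalized fragment length).
    ``reverse`` means mate 1 matches the antisense of the transcript.
    ``fragment_length`` is known for PE (rightmost mate end - leftmost mate
    start) and None for SE.
    """

    read_index: int
    tindex: int
    pos: int
    reverse: bool = False
    fragment_length: Optional[int] = None


@dataclass
class AlignmentSet:
    """Per-read candidate alignments plus filter flags.

    ``filtered[n]`` is None for usable reads or a reason
    ('too_many_alignments' | 'polya_like'). Unfiltered reads with no
    candidates are retained: they feed the noise component.
    """

    reads: list[ReadRecord]
    candidates: list[list[Alignment]]
    filtered: list[Optional[str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.filtered:
            self.filtered = [None] * len(self.reads)
        if not (len(self.reads) == len(self.candidates) == len(self.filtered)):
            raise InputError("reads/candidates/filtered length mismatch")

    @property
    def n_unfiltered(self) -> int:
        return sum(f is None for f in self.filtered)

    def unfiltered_indices(self) -> np.ndarray:
        return np.array(
            [n for n, f in enumerate(self.filtered) if f is None], dtype=np.int64
        )


def read_sequences(path, format: Optional[str] = None, mate2=None) -> list[ReadRecord]:
    """Load SE or PE reads from FASTA/FASTQ (format inferred from the first
    character when not given); paired files must align record-for-record."""
    from Bio import SeqIO

    def sniff(p):
        with open(p) as fh:
            first = fh.read(1)
        if first == ">":
            return "fasta"
        if first == "@":
            return "fastq"
        raise InputError(f"{p}: cannot determine FASTA/FASTQ format")

    fmt = format or sniff(path)

    def load(p):
        out = []
        for rec in SeqIO.parse(str(p), fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            out.append((rec.id, _sanitize(str(rec.seq)), qual))
        return out

    first = load(path)
    if mate2 is None:
        return [ReadRecord(rid, seq, qual) for rid, seq, qual in first]
    second = load(mate2)
    if len(first) != len(second):
        raise InputError(
            f"mate files differ in record count ({len(first)} vs {len(second)})"
        )
    return [
        ReadRecord(r1[0], r1[1], r1[2], seq2=r2[1], qual2=r2[2])
        for r1, r2 in zip(first, second)
    ]


def parse_sam(path, ts: TranscriptSet, reads: list[ReadRecord]) -> AlignmentSet:
    """Parse candidate alignments (SAM against transcript ids) for the given reads.

    All records of a read are candidates (upstream aligners are expected to
    report all valid alignments). SAM 1-based POS becomes 0-based; PE mates
    are joined by QNAME and mate coordinates, the fragment length derived from
    the mate span. Unmapped reads keep empty candidate lists.
    """
    import pysam

    read_index = {r.id: n for n, r in enumerate(reads)}
    candidates: list[list[Alignment]] = [[] for _ in reads]
    pending: dict[tuple, tuple] = {}  # PE mate joining
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.query_name not in read_index:
                raise InputError(f"SAM read {rec.query_name!r} not in read set")
            n = read_index[rec.query_name]
            if rec.is_unmapped:
                continue
            if rec.reference_name not in ts.gene_map and rec.reference_name not in ts.ids:
                raise InputError(
                    f"SAM reference {rec.reference_name!r} absent from transcript set"
                )
            tidx = ts.index_of(rec.reference_name)
            if not rec.is_paired:
                candidates[n].append(
                    Alignment(n, tidx, rec.reference_start, reverse=rec.is_reverse)
                )
                continue
            # mate joining: records of the two mates describing the same pair
            # share (qname, rname) with mirrored POS/PNEXT
            me = (rec.reference_start, rec.next_reference_start)
            key = (rec.query_name, rec.reference_name, min(me), max(me))
            mate_key = (key, rec.is_read2)
            other = pending.pop((key, not rec.is_read2), None)
            if other is None:
                pending[mate_key] = (n, tidx, rec)
                continue
            _, _, orec = other
            r1, r2 = (orec, rec) if rec.is_read2 else (rec, orec)
            left = min(r1.reference_start, r2.reference_start)
            right = max(r1.reference_end, r2.reference_end)
            candidates[n].append(
                Alignment(
                    n,
                    tidx,
                    left,
                    reverse=r1.is_reverse,
                    fragment_length=right - left,
                )
            )
    for (key, _), (n, _, rec) in pending.items():
        warnings.warn(f"PE record {rec.query_name!r} missing its mate; dropped")
    return AlignmentSet(reads=list(reads), candidates=candidates)


def is_polya_like(read: ReadRecord, polya_fraction: float = 0.9) -> bool:
    """True when any mate is >= polya_fraction A (or T, covering antisense)."""
    for seq in filter(None, (read.seq1, read.seq2)):
        thresh = polya_fraction * len(seq)
        if seq.count("A") >= thresh or seq.count("T") >= thresh:
            return True
    return False


def filter_reads(
    aset: AlignmentSet, max_alignments: int = 200, polya_fraction: float = 0.9
) -> AlignmentSet:
    """Apply the multiplicity and poly(A) read filters.

    Reads with >= max_alignments candidates are flagged too_many_alignments;
    A/T-dominated reads are flagged polya_like. Flagged reads are excluded
    from estimation (and from the unfiltered read count N).
    """
    if max_alignments <= 0 or polya_fraction <= 0:
        raise ValueError("filter thresholds must be positive")
    flags: list[Optional[str]] = []
    for read, cands in zip(aset.reads, aset.candidates):
        if is_polya_like(read, polya_fraction):
            flags.append("polya_like")
        elif len(cands) >= max_alignments:
            flags.append("too_many_alignments")
        else:
            flags.append(None)
    return AlignmentSet(reads=aset.reads, candidates=aset.candidates, filtered=flags)
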