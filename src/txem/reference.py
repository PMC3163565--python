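"""Reference transcript sets: loading, GTF extraction, poly(A) tails, effective lengths.

Transcript coordinates are 0-based half-open everywhere inside the package;
GTF (1-based inclusive) and SAM (1-based POS) are converted at the parse
boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .model import LengthDistribution

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
#: integer encoding shared by all array kernels: A,C,G,T,N -> 0..4
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_BASE = "ACGTN"


class ReferenceError(ValueError):
    """Raised for malformed reference inputs (duplicate ids, bad gene maps...)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array (A,C,G,T,N -> 0..4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(raw.size, 4, dtype=np.uint8)
    for base, code in BASE_CODE.items():
        out[raw == ord(base)] = code
    return out


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    if not set(seq) <= set("ACGTN"):
        # ambiguity codes collapse to N; they never match under the error models
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
    return seq


@dataclass
class Transcript:
    """A single reference transcript (post-poly(A) if a tail was appended)."""

    id: str
    gene_id: str
    sequence: str
    polya_appended: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ReferenceError(f"transcript {self.id!r} has empty sequence")


class TranscriptSet:
    """Ordered collection of transcripts with gene membership.

    Transcript order is stable and indexes the abundance vector positions
    1..M (position 0 is the noise component).
    """

    def __init__(self, transcripts: Iterable[Transcript], polya_length: int = 0):
        self.transcripts: list[Transcript] = list(transcripts)
        self.polya_length = int(polya_length)
        ids = [t.id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ReferenceError(f"duplicate transcript ids: {dup[:5]}")
        self._index = {t.id: i for i, t in enumerate(self.transcripts)}
        self.gene_map: dict[str, list[str]] = {}
        for t in self.transcripts:
            self.gene_map.setdefault(t.gene_id, []).append(t.id)
        self._encoded: Optional[tuple[np.ndarray, np.ndarray]] = None
        self._seed_index = None  # lazily built by txem.aligner.SeedIndex

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self.transcripts[self._index[key]]
        return self.transcripts[key]

    def index_of(self, transcript_id: str) -> int:
        return self._index[transcript_id]

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.transcripts]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([t.length for t in self.transcripts], dtype=np.int64)

    def gene_of(self) -> np.ndarray:
        """Gene index (into sorted-by-first-appearance gene list) per transcript."""
        genes = list(self.gene_map)
        gidx = {g: i for i, g in enumerate(genes)}
        return np.array([gidx[t.gene_id] for t in self.transcripts], dtype=np.int64)

    def encoded(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated uint8 code array plus per-transcript start offsets.

        offsets has length M+1; transcript i occupies codes[offsets[i]:offsets[i+1]].
        """
        if self._encoded is None:
            codes = np.concatenate([encode_seq(t.sequence) for t in self.transcripts])
            offs = np.zeros(len(self.transcripts) + 1, dtype=np.int64)
            np.cumsum([t.length for t in self.transcripts], out=offs[1:])
            self._encoded = (codes, offs)
        return self._encoded

    def effective_lengths(self, lambda_f: "LengthDistribution") -> np.ndarray:
        return np.array(
            [effective_length(t.length, lambda_f) for t in self.transcripts]
        )


def load_reference(fasta_path, gene_map_path=None) -> TranscriptSet:
    """Load transcripts from FASTA, optionally with a gene_id<TAB>transcript_id map.

    Transcripts absent from the map become singleton genes named after
    themselves; a map entry naming an unknown transcript is a hard error.
    """
    from Bio import SeqIO

    records = [(r.id, _sanitize(str(r.seq))) for r in SeqIO.parse(str(fasta_path), "fasta")]
    if not records:
        raise ReferenceError(f"no FASTA records in {fasta_path}")
    gene_of: dict[str, str] = {}
    if gene_map_path is not None:
        known = {rid for rid, _ in records}
        with open(gene_map_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ReferenceError(
                        f"{gene_map_path}:{lineno}: expected 2 tab-separated columns"
                    )
                gene, tid = parts
                if tid not in known:
                    raise ReferenceError(
                        f"{gene_map_path}:{lineno}: unknown transcript {tid!r}"
                    )
                gene_of[tid] = gene
    transcripts = [
        Transcript(rid, gene_of.get(rid, rid), seq) for rid, seq in records
    ]
    return TranscriptSet(transcripts)


def extract_from_gtf(gtf_path, genome_fasta) -> TranscriptSet:
    """Build transcript sequences by splicing exons out of a genome.

    Exons are concatenated in genomic order; minus-strand transcripts are
    reverse-complemented. Gene membership comes from the gene_id attribute.
    """
    import warnings

    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_transcripts=True,
        disable_infer_genes=True,
    )
    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    exons: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    order: list[str] = []
    for ex in db.features_of_type("exon"):
        tid = ex.attributes["transcript_id"][0]
        gid = ex.attributes.get("gene_id", [tid])[0]
        if tid not in exons:
            exons[tid] = []
            meta[tid] = (gid, ex.seqid, ex.strand)
            order.append(tid)
        exons[tid].append((ex.start, ex.end))  # 1-based inclusive
    transcripts = []
    for tid in order:
        gid, chrom, strand = meta[tid]
        if chrom not in genome:
            raise ReferenceError(f"chromosome {chrom!r} not in genome FASTA")
        chrom_len = len(genome[chrom])
        parts = []
        for start, end in sorted(exons[tid]):
            if start < 1 or end > chrom_len:
                raise ReferenceError(
                    f"exon {chrom}:{start}-{end} of {tid} outside chromosome bounds"
                )
            parts.append(genome[chrom][start - 1 : end])  # to 0-based half-open
        if not parts:
            warnings.warn(f"transcript {tid} has no exons; skipped")
            continue
        seq = _sanitize("".join(parts))
        if strand == "-":
            seq = revcomp(seq)
        transcripts.append(Transcript(tid, gid, seq))
    return TranscriptSet(transcripts)


def append_polya(ts: TranscriptSet, tail_length: int = 125) -> TranscriptSet:
    """Return a new set with `tail_length` A bases appended to every transcript."""
    if tail_length < 0:
        raise ValueError("tail_length must be >= 0")
    if tail_length == 0:
        return ts
    tail = "A" * tail_length
    return TranscriptSet(
        [
            Transcript(t.id, t.gene_id, t.sequence + tail, polya_appended=True)
            for t in ts
        ],
        polya_length=tail_length,
    )


def remove_polya(ts: TranscriptSet) -> TranscriptSet:
    """Undo append_polya, recovering the original sequences exactly."""
    a = ts.polya_length
    if a == 0:
        return ts
    return TranscriptSet(
        [Transcript(t.id, t.gene_id, t.sequence[:-a]) for t in ts], polya_length=0
    )


def effective_length(length: int, lambda_f: "LengthDistribution") -> float:
    """Mean number of positions a fragment may start from within a transcript.

    ``sum_f lambda_F(f | length) * (length - f + 1)`` with the fragment-length
    pmf truncated to f <= length and renormalized. Returns 0 when no fragment
    length fits.
    """
    trunc = lambda_f.truncated(length)
    if trunc is None:
        return 0.0
    f = np.arange(trunc.min_len, trunc.max_len + 1)
    return float(np.sum(trunc.pmf * (length - f + 1)))
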