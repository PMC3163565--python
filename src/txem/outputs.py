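"""Result writers: isoform/gene abundance tables, posterior-weighted SAM,
transcript-coordinate wiggle depth tracks, and a run-statistics file."""
from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .em import MLEstimates, Responsibilities, gene_and_isopct
from .gibbs import PosteriorSummary
from .readsio import AlignmentSet
from .reference import TranscriptSet

_FLOAT_FMT = "%.6f"


def results_tables(
    ml: MLEstimates,
    ts: TranscriptSet,
    post: Optional[PosteriorSummary] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(isoform, gene) DataFrames with the standard column layout."""
    gene_ids, gene_tau, isopct = gene_and_isopct(ml.tau, ts)
    iso = pd.DataFrame(
        {
            "transcript_id": ts.ids,
            "gene_id": [t.gene_id for t in ts],
            "length": ts.lengths,
            "effective_length": ml.eff_lengths,
            "expected_count": ml.expected_counts[1:],
            "TPM": ml.tpm,
            "tau": ml.tau,
            "IsoPct": isopct * 100.0,
        }
    )
    gidx = ts.gene_of()
    gene = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "transcript_ids": [",".join(ts.gene_map[g]) for g in gene_ids],
            "expected_count": np.bincount(
                gidx, weights=ml.expected_counts[1:], minlength=len(gene_ids)
            ),
            "TPM": gene_tau * 1e6,
            "tau": gene_tau,
        }
    )
    if post is not None:
        iso["pme_TPM"] = post.tpm_pme
        iso["TPM_ci_lower"] = post.tpm_ci_lower
        iso["TPM_ci_upper"] = post.tpm_ci_upper
        order = {g: i for i, g in enumerate(post.gene_ids)}
        sel = [order[g] for g in gene_ids]
        gene["pme_TPM"] = post.gene_tpm_pme[sel]
        gene["TPM_ci_lower"] = post.gene_tpm_ci_lower[sel]
        gene["TPM_ci_upper"] = post.gene_tpm_ci_upper[sel]
    return iso, gene


def write_results(
    ml: MLEstimates,
    ts: TranscriptSet,
    iso_path,
    gene_path,
    post: Optional[PosteriorSummary] = None,
) -> None:
    """Write the isoform- and gene-level TSVs (headered, 6-decimal floats)."""
    iso, gene = results_tables(ml, ts, post)
    iso.to_csv(iso_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    gene.to_csv(gene_path, sep="\t", index=False, float_format=_FLOAT_FMT)


def mapq_from_posterior(p: float, cap: int = 100) -> int:
    """Phred-of-error encoding of an alignment posterior: round(-10*log10(1-p)),
    capped (p = 1 maps to the cap). Lossless weights live in the ZW tag."""
    if p >= 1.0:
        return cap
    if p <= 0.0:
        return 0
    return min(cap, int(round(-10.0 * math.log10(1.0 - p))))


def write_posterior_alignments(
    resp: Responsibilities,
    aset: AlignmentSet,
    ts: TranscriptSet,
    path,
) -> None:
    """SAM in transcript coordinates, one record per candidate alignment (two
    for PE pairs), weighted by the posterior probability of being the true
    alignment (ZW tag, full precision; MAPQ, Phred-encoded)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t.id, "LN": t.length} for t in ts],
    }
    with pysam.AlignmentFile(str(path), "w", header=pysam.AlignmentHeader.from_dict(header)) as out:
        for rid in resp.read_ids:
            read = aset.reads[rid]
            _, weighted = resp.per_read(int(rid))
            for aln, p in weighted:
                mapq = mapq_from_posterior(p)
                l1 = len(read.seq1)
                if read.paired:
                    f = aln.fragment_length
                    l2 = len(read.seq2)
                    if aln.reverse:
                        pos1, rev1 = aln.pos + f - l1, True
                        pos2, rev2 = aln.pos, False
                    else:
                        pos1, rev1 = aln.pos, False
                        pos2, rev2 = aln.pos + f - l2, True
                    for mate, (seq, qual, pos, rev, other_pos, tlen) in enumerate(
                        (
                            (read.seq1, read.qual1, pos1, rev1, pos2, f),
                            (read.seq2, read.qual2, pos2, rev2, pos1, -f),
                        )
                    ):
                        a = pysam.AlignedSegment()
                        a.query_name = read.id
                        a.query_sequence = seq
                        if qual:
                            a.query_qualities = pysam.qualitystring_to_array(qual)
                        a.reference_id = aln.tindex
                        a.reference_start = pos
                        a.cigarstring = f"{len(seq)}M"
                        a.mapping_quality = mapq
                        a.flag = (
                            0x1
                            | 0x2
                            | (0x10 if rev else 0)
                            | (0x20 if not rev else 0)
                            | (0x40 if mate == 0 else 0x80)
                        )
                        a.next_reference_id = aln.tindex
                        a.next_reference_start = other_pos
                        a.template_length = tlen if not aln.reverse else -tlen
                        a.set_tag("ZW", float(p))
                        out.write(a)
                else:
                    a = pysam.AlignedSegment()
                    a.query_name = read.id
                    a.query_sequence = read.seq1
                    if read.qual1:
                        a.query_qualities = pysam.qualitystring_to_array(read.qual1)
                    a.reference_id = aln.tindex
                    a.reference_start = aln.pos
                    a.cigarstring = f"{l1}M"
                    a.mapping_quality = mapq
                    a.flag = 0x10 if aln.reverse else 0
                    a.set_tag("ZW", float(p))
                    out.write(a)


def depth_track(
    resp: Responsibilities, aset: AlignmentSet, ts: TranscriptSet, path
) -> None:
    """fixedStep wiggle of expected read depth per transcript position: the
    sum of posterior weights of alignments covering each base."""
    depth = [np.zeros(t.length) for t in ts]
    for rid in resp.read_ids:
        read = aset.reads[rid]
        _, weighted = resp.per_read(int(rid))
        for aln, p in weighted:
            if p <= 0:
                continue
            l1 = len(read.seq1)
            if read.paired:
                f = aln.fragment_length
                l2 = len(read.seq2)
                depth[aln.tindex][aln.pos : aln.pos + l1 if not aln.reverse else aln.pos + l2] += p
                # cover both mate windows
                if aln.reverse:
                    depth[aln.tindex][aln.pos + f - l1 : aln.pos + f] += p
                else:
                    depth[aln.tindex][aln.pos + f - l2 : aln.pos + f] += p
            else:
                depth[aln.tindex][aln.pos : aln.pos + l1] += p
    with open(path, "w") as fh:
        for t, d in zip(ts, depth):
            if not np.any(d):
                continue
            fh.write(f"fixedStep chrom={t.id} start=1 step=1\n")
            fh.write("\n".join(f"{x:.6f}" for x in d) + "\n")


def write_run_stats(ml: MLEstimates, aset: AlignmentSet, path) -> None:
    from collections import Counter

    reasons = Counter(f for f in aset.filtered if f is not None)
    with open(path, "w") as fh:
        fh.write(f"reads_total\t{len(aset.reads)}\n")
        fh.write(f"reads_unfiltered\t{aset.n_unfiltered}\n")
        for reason, n in sorted(reasons.items()):
            fh.write(f"reads_filtered_{reason}\t{n}\n")
        fh.write(f"noise_expected_count\t{ml.expected_counts[0]:.6f}\n")
        fh.write(f"em_iterations\t{ml.iterations_run}\n")
        fh.write(f"log_likelihood\t{ml.log_likelihood:.6f}\n")
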