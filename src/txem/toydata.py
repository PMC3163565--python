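"""Deterministic toy transcriptomes for self-contained testing.

Genes are built from a pool of exons; isoforms of a gene are subsets of its
exons, so isoforms share sequence blocks (multireads by construction). A few
genes are emitted as exact duplicates to exercise repeat handling and
mappability. Designed abundances are sparse and span several orders of
magnitude, as in real libraries.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import Transcript, TranscriptSet


@dataclass
class ToySpec:
    n_genes: int = 175
    # isoform count per gene drawn from this pmf over 1..k; the default has
    # mean 1.7, the isoform density of a mammalian RefSeq annotation
    isoform_count_probs: tuple = (0.55, 0.25, 0.15, 0.05)
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (120, 500)
    min_transcript_length: int = 360
    repeat_copies: int = 2  # duplicated genes (identical sequence, distinct ids)
    zero_fraction: float = 0.2
    abundance_range: tuple[float, float] = (1e-6, 1e-2)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.exon_length[0]) <= 0:
            raise ValueError("counts and lengths must be positive")
        if abs(sum(self.isoform_count_probs) - 1.0) > 1e-9:
            raise ValueError("isoform_count_probs must sum to 1")


def make_toy_reference(spec: ToySpec) -> tuple[TranscriptSet, np.ndarray]:
    """Seeded toy reference plus a designed tau vector (sums to 1).

    tau values are log-uniform over spec.abundance_range with a configurable
    zero fraction, then normalized.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    transcripts: list[Transcript] = []
    for g in range(spec.n_genes):
        n_ex = rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1)
        exons = [
            "".join(
                rng.choice(bases, size=rng.integers(*spec.exon_length, endpoint=True))
            )
            for _ in range(n_ex)
        ]
        gene_id = f"g{g:04d}"
        n_iso = 1 + int(rng.choice(len(spec.isoform_count_probs), p=spec.isoform_count_probs))
        seen: set[tuple[int, ...]] = set()
        made = 0
        for attempt in range(20 * n_iso):
            if made >= n_iso:
                break
            keep = tuple(np.flatnonzero(rng.random(n_ex) < 0.7))
            if not keep or keep in seen:
                continue
            seq = "".join(exons[i] for i in keep)
            if len(seq) < spec.min_transcript_length:
                continue
            seen.add(keep)
            transcripts.append(Transcript(f"{gene_id}.i{made + 1}", gene_id, seq))
            made += 1
        if made == 0:  # fall back to the full exon chain
            transcripts.append(Transcript(f"{gene_id}.i1", gene_id, "".join(exons)))
    # duplicated genes: identical sequences under new gene ids
    originals = [t for t in transcripts]
    for c in range(spec.repeat_copies):
        src = originals[c % len(originals)]
        transcripts.append(
            Transcript(f"rep{c:02d}.i1", f"rep{c:02d}", src.sequence)
        )
    ts = TranscriptSet(transcripts)
    lo, hi = spec.abundance_range
    tau = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(ts)))
    zero = rng.random(len(ts)) < spec.zero_fraction
    if np.all(zero):
        zero[0] = False
    tau[zero] = 0.0
    return ts, tau / tau.sum()


def tau_to_theta(tau: np.ndarray, eff_lengths: np.ndarray, theta0: float = 0.0) -> np.ndarray:
    """Fragment-sampling probabilities from transcript fractions: theta_i is
    proportional to tau_i * effective_length_i, with theta_0 = theta0 noise mass."""
    w = np.asarray(tau, dtype=float) * np.asarray(eff_lengths, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("designed abundances are all zero")
    return np.concatenate([[theta0], (1.0 - theta0) * w / total])
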