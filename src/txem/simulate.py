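"""RNA-Seq read simulation from the generative model.

Fragments are drawn transcript ~ theta, length ~ lambda_F truncated to the
transcript, start ~ RSPD over the feasible positions, orientation ~ P(o); the
SE read is the fragment's 5' end (PE adds the reverse complement of the 3'
end). Quality strings come from a first-order Markov chain over Phred scores;
substitution errors are injected either at the theoretical Phred rate
10^(-q/10) (uniform over the three wrong bases) or from an empirical
eps(r | q, c) table.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import ModelParams, QualityErrorModel
from .readsio import ReadRecord
from .reference import CODE_BASE, TranscriptSet, revcomp


@dataclass(frozen=True)
class QualityMarkov:
    """Homogeneous first-order Markov chain over Phred quality scores."""

    states: np.ndarray  # quality values
    initial: np.ndarray  # pmf over states
    transition: np.ndarray  # (n_states, n_states), rows sum to 1

    def __post_init__(self):
        init = np.asarray(self.initial, dtype=float)
        trans = np.asarray(self.transition, dtype=float)
        if not np.isclose(init.sum(), 1.0) or not np.allclose(trans.sum(axis=1), 1.0):
            raise ValueError("initial pmf and transition rows must sum to 1")
        object.__setattr__(self, "states", np.asarray(self.states, dtype=np.int64))
        object.__setattr__(self, "initial", init)
        object.__setattr__(self, "transition", trans)

    @classmethod
    def default_illumina(cls) -> "QualityMarkov":
        """A synthetic Illumina-like chain: qualities mostly in the low-to-mid
        30s, sticky transitions drifting toward the high 20s, with rare
        intermittent dips that recover within a few cycles (a couple percent
        of reads are touched by a dip)."""
        states = np.arange(2, 41)
        n = states.size
        initial = np.exp(-0.5 * ((states - 34) / 3.0) ** 2)
        initial /= initial.sum()
        trans = np.zeros((n, n))
        for i, q in enumerate(states):
            center = q - 0.05 * (q - 28)  # mean-reverting: decay and recovery
            row = np.exp(-0.5 * ((states - center) / 2.0) ** 2)
            row[0] += 0.0005 * row.sum()  # rare quality dips to the floor
            trans[i] = row / row.sum()
        return cls(states, initial, trans)

    def sample(self, n_reads: int, read_len: int, rng: np.random.Generator) -> np.ndarray:
        """(n_reads, read_len) array of quality values."""
        n = self.states.size
        idx = np.empty((n_reads, read_len), dtype=np.int64)
        idx[:, 0] = rng.choice(n, size=n_reads, p=self.initial)
        cum = np.cumsum(self.transition, axis=1)
        for j in range(1, read_len):
            u = rng.random(n_reads)
            rows = cum[idx[:, j - 1]]
            idx[:, j] = (u[:, None] > rows).sum(axis=1)
        return self.states[idx]


def fit_quality_markov(fastq_path) -> QualityMarkov:
    """Fit initial and transition distributions (add-one smoothed) from the
    quality strings of a FASTQ file."""
    from Bio import SeqIO

    firsts: list[int] = []
    pairs: dict[tuple[int, int], int] = {}
    seen: set[int] = set()
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        if not quals:
            continue
        firsts.append(quals[0])
        seen.update(quals)
        for a, b in zip(quals, quals[1:]):
            pairs[(a, b)] = pairs.get((a, b), 0) + 1
    if not firsts:
        raise ValueError(f"{fastq_path}: no quality data")
    states = np.array(sorted(seen), dtype=np.int64)
    pos = {q: i for i, q in enumerate(states)}
    n = states.size
    initial = np.ones(n)
    for q in firsts:
        initial[pos[q]] += 1
    trans = np.ones((n, n))
    for (a, b), c in pairs.items():
        trans[pos[a], pos[b]] += c
    return QualityMarkov(states, initial / initial.sum(),
                         trans / trans.sum(axis=1, keepdims=True))


@dataclass
class SimTruth:
    """Latent variables behind each simulated read: source transcript index
    (-1 = noise), fragment length, fragment start, orientation."""

    transcript: np.ndarray
    fragment_length: np.ndarray
    start: np.ndarray
    reverse: np.ndarray

    def counts(self, n_transcripts: int) -> np.ndarray:
        real = self.transcript[self.transcript >= 0]
        return np.bincount(real, minlength=n_transcripts)

    def to_tsv(self, path, ts: TranscriptSet, read_ids: list[str]) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\ttranscript_id\tfragment_length\tstart\torientation\n")
            for rid, t, f, s, rev in zip(
                read_ids, self.transcript, self.fragment_length, self.start, self.reverse
            ):
                tid = "*" if t < 0 else ts[int(t)].id
                fh.write(f"{rid}\t{tid}\t{f}\t{s}\t{'-' if rev else '+'}\n")


def _inject_errors_theoretical(codes, quals, rng):
    p_err = 10.0 ** (-quals / 10.0)
    hit = rng.random(codes.shape) < p_err
    shift = rng.integers(1, 4, size=codes.shape)
    return np.where(hit, (codes + shift) % 4, codes)


def _inject_errors_empirical(codes, quals, error: QualityErrorModel, rng):
    nq = error.table.shape[0]
    cum = np.cumsum(error.table, axis=2)  # (q, c, r)
    q = np.clip(quals, 0, nq - 1)
    rows = cum[q, codes]  # (..., 4)
    u = rng.random(codes.shape)
    return (u[..., None] > rows).sum(axis=-1).clip(0, 3)


def simulate_dataset(
    params: ModelParams,
    ts: TranscriptSet,
    n_reads: int,
    paired: bool = False,
    read_len: int = 35,
    qmodel: Optional[QualityMarkov] = None,
    error_mode: str = "theoretical",
    seed: int = 0,
) -> tuple[list[ReadRecord], SimTruth]:
    """Simulate reads plus ground truth; bit-reproducible for a given seed.

    theta_0 > 0 emits noise reads drawn i.i.d. from the background composition.
    Output order is randomized draw order; read ids are sim_000000... .
    """
    if error_mode not in ("theoretical", "empirical"):
        raise ValueError("error_mode must be 'theoretical' or 'empirical'")
    if error_mode == "empirical" and not isinstance(params.error, QualityErrorModel):
        raise ValueError("empirical error injection needs a quality error model")
    rng = np.random.default_rng(seed)
    qmodel = qmodel or QualityMarkov.default_illumina()
    M = len(ts)
    lengths = ts.lengths

    comp = rng.choice(M + 1, size=n_reads, p=params.theta)
    src = comp - 1  # -1 = noise
    frag = np.zeros(n_reads, dtype=np.int64)
    start = np.zeros(n_reads, dtype=np.int64)
    rev = np.zeros(n_reads, dtype=bool)
    if params.strand_specific:
        pass  # all forward
    else:
        rev = rng.random(n_reads) < 0.5

    lam = params.lambda_f
    for t in range(M):
        sel = np.flatnonzero(src == t)
        if sel.size == 0:
            continue
        trunc = lam.truncated(int(lengths[t]))
        if trunc is None:
            raise ValueError(
                f"transcript {ts[t].id!r} shorter than every fragment length"
            )
        fmin = max(trunc.min_len, read_len)
        support = np.arange(trunc.min_len, trunc.max_len + 1)
        pmf = trunc.pmf.copy()
        pmf[support < fmin] = 0.0
        if pmf.sum() <= 0:
            raise ValueError(
                f"transcript {ts[t].id!r}: no fragment length can hold a read"
            )
        pmf /= pmf.sum()
        frag[sel] = rng.choice(support, size=sel.size, p=pmf)
        n_starts = int(lengths[t]) - frag[sel] + 1
        if params.rspd.is_uniform:
            start[sel] = (rng.random(sel.size) * n_starts).astype(np.int64)
        else:
            for i in sel:
                pp = params.rspd.position_probs(int(lengths[t]) - int(frag[i]) + 1)
                start[i] = rng.choice(pp.size, p=pp)

    # read windows
    reads: list[ReadRecord] = []
    quals1 = qmodel.sample(n_reads, read_len, rng)
    quals2 = qmodel.sample(n_reads, read_len, rng) if paired else None
    from .reference import encode_seq

    enc = [None] * M  # lazy per-transcript code arrays

    def window_codes(t, lo, hi, rc):
        if enc[t] is None:
            enc[t] = encode_seq(ts[t].sequence)
        w = enc[t][lo:hi]
        if rc:
            w = np.where(w == 4, 4, 3 - w)[::-1]
        return w

    bg = params.noise_background
    code_mat1 = np.empty((n_reads, read_len), dtype=np.int64)
    code_mat2 = np.empty((n_reads, read_len), dtype=np.int64) if paired else None
    for n in range(n_reads):
        t = src[n]
        if t < 0:
            code_mat1[n] = rng.choice(4, size=read_len, p=bg)
            if paired:
                code_mat2[n] = rng.choice(4, size=read_len, p=bg)
            frag[n] = read_len
            start[n] = -1
            continue
        s, f = int(start[n]), int(frag[n])
        if rev[n]:
            code_mat1[n] = window_codes(t, s + f - read_len, s + f, rc=True)
            if paired:
                code_mat2[n] = window_codes(t, s, s + read_len, rc=False)
        else:
            code_mat1[n] = window_codes(t, s, s + read_len, rc=False)
            if paired:
                code_mat2[n] = window_codes(t, s + f - read_len, s + f, rc=True)

    if error_mode == "theoretical":
        code_mat1 = _inject_errors_theoretical(code_mat1, quals1, rng)
        if paired:
            code_mat2 = _inject_errors_theoretical(code_mat2, quals2, rng)
    else:
        code_mat1 = _inject_errors_empirical(code_mat1, quals1, params.error, rng)
        if paired:
            code_mat2 = _inject_errors_empirical(code_mat2, quals2, params.error, rng)

    lut = np.frombuffer(CODE_BASE.encode(), dtype=np.uint8)
    seq1 = lut[np.minimum(code_mat1, 4)]
    q1 = (quals1 + 33).astype(np.uint8)
    if paired:
        seq2 = lut[np.minimum(code_mat2, 4)]
        q2 = (quals2 + 33).astype(np.uint8)
    for n in range(n_reads):
        rid = f"sim_{n:07d}"
        if paired:
            reads.append(
                ReadRecord(
                    rid,
                    seq1[n].tobytes().decode(),
                    q1[n].tobytes().decode(),
                    seq2[n].tobytes().decode(),
                    q2[n].tobytes().decode(),
                )
            )
        else:
            reads.append(
                ReadRecord(rid, seq1[n].tobytes().decode(), q1[n].tobytes().decode())
            )
    truth = SimTruth(transcript=src, fragment_length=frag, start=start, reverse=rev)
    return reads, truth


def write_fastq(reads: list[ReadRecord], path, mate2_path=None) -> None:
    """Write reads as Phred+33 FASTQ (mate 2 to its own file when paired)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq1}\n+\n{r.qual1 or 'I' * len(r.seq1)}\n")
    if mate2_path is not None:
        with open(mate2_path, "w") as fh:
            for r in reads:
                if r.paired:
                    fh.write(f"@{r.id}\n{r.seq2}\n+\n{r.qual2 or 'I' * len(r.seq2)}\n")
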