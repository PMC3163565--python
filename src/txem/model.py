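"""The generative read model: parameters and the single scoring kernel.

A fragment is drawn from transcript i with probability theta_i (theta_0 is a
noise component for reads aligning nowhere); its length from a global
fragment-length distribution lambda_F truncated/renormalized to the transcript
length; its start from a binned read-start-position distribution (RSPD) over
the feasible start positions; its orientation with probability 1/2 (1 if the
protocol is strand-specific); read lengths from lambda_R truncated to the
fragment length; and read characters through a sequencing-error model, either
quality-dependent eps(r | q, c) or position/reference-dependent (the
"profile" model). EM, the Gibbs sampler and the simulator all score reads
through :func:`alignment_weight` / :func:`noise_weight`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .reference import TranscriptSet, encode_seq

N_CODE = 4  # shared A,C,G,T,N -> 0..4 encoding; N never truly matches


@dataclass(frozen=True)
class LengthDistribution:
    """pmf over integer lengths min_len .. min_len+len(pmf)-1."""

    min_len: int
    pmf: np.ndarray

    def __post_init__(self):
        pmf = np.asarray(self.pmf, dtype=float)
        if pmf.ndim != 1 or pmf.size == 0 or np.any(pmf < 0):
            raise ValueError("pmf must be a nonempty nonnegative 1-d array")
        total = pmf.sum()
        if not np.isclose(total, 1.0):
            pmf = pmf / total
        object.__setattr__(self, "pmf", pmf)
        if self.min_len < 1:
            raise ValueError("lengths start at 1")

    @property
    def max_len(self) -> int:
        return self.min_len + self.pmf.size - 1

    def prob(self, length: int) -> float:
        if self.min_len <= length <= self.max_len:
            return float(self.pmf[length - self.min_len])
        return 0.0

    def mean(self) -> float:
        return float(np.dot(np.arange(self.min_len, self.max_len + 1), self.pmf))

    def truncated(self, limit: int) -> Optional["LengthDistribution"]:
        """Restrict mass to lengths <= limit and renormalize; None if no mass fits."""
        if limit >= self.max_len:
            return self
        if limit < self.min_len:
            return None
        head = self.pmf[: limit - self.min_len + 1]
        total = head.sum()
        if total <= 0.0:
            return None
        return LengthDistribution(self.min_len, head / total)

    @classmethod
    def point(cls, length: int) -> "LengthDistribution":
        return cls(length, np.ones(1))

    @classmethod
    def uniform(cls, lo: int, hi: int) -> "LengthDistribution":
        return cls(lo, np.full(hi - lo + 1, 1.0 / (hi - lo + 1)))

    @classmethod
    def discretized_normal(
        cls, mean: float, sd: float, lo: int = 1, hi: Optional[int] = None
    ) -> "LengthDistribution":
        """Gaussian discretized on integers, truncated to [lo, hi] (hi ~ mean+4sd)."""
        if hi is None:
            hi = int(np.ceil(mean + 4 * sd))
        lo = max(1, lo)
        x = np.arange(lo, hi + 1, dtype=float)
        pmf = np.exp(-0.5 * ((x - mean) / sd) ** 2)
        return cls(lo, pmf)


def truncate_length_pmf(d: LengthDistribution, limit: int) -> Optional[LengthDistribution]:
    """Functional alias for :meth:`LengthDistribution.truncated`."""
    if limit < 1:
        raise ValueError("limit must be >= 1")
    return d.truncated(limit)


@dataclass(frozen=True)
class Rspd:
    """Read-start-position distribution: B bin weights over relative position [0,1)."""

    bins: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.bins, dtype=float)
        if np.any(b < 0) or b.sum() <= 0:
            raise ValueError("bin weights must be nonnegative with positive sum")
        object.__setattr__(self, "bins", b / b.sum())

    @property
    def n_bins(self) -> int:
        return self.bins.size

    @property
    def is_uniform(self) -> bool:
        return bool(np.allclose(self.bins, 1.0 / self.n_bins))

    @classmethod
    def uniform(cls, n_bins: int = 20) -> "Rspd":
        return cls(np.full(n_bins, 1.0 / n_bins))

    def position_probs(self, n_starts: int) -> np.ndarray:
        """Per-position start probabilities over 0..n_starts-1, summing to 1.

        Each position s falls in bin floor(B*s/n_starts) and takes an equal
        share of that bin's mass; if n_starts < B (empty bins) the result is
        renormalized.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.is_uniform:
            return np.full(n_starts, 1.0 / n_starts)
        s = np.arange(n_starts)
        binidx = (self.n_bins * s) // n_starts
        counts = np.bincount(binidx, minlength=self.n_bins)
        w = self.bins[binidx] / counts[binidx]
        return w / w.sum()


def rspd_start_prob(rspd: Rspd, start: int, n_starts: int) -> float:
    if not 0 <= start < n_starts:
        raise ValueError("start out of range")
    return float(rspd.position_probs(n_starts)[start])


def _validate_rows(table: np.ndarray, what: str) -> None:
    sums = table.sum(axis=-1)
    if not np.allclose(sums[sums > 0], 1.0):
        raise ValueError(f"{what}: emission rows must sum to 1")


@dataclass(frozen=True)
class QualityErrorModel:
    """eps[q, c, r]: P(observed base r | Phred quality q, reference base c).

    Indexed by quality 0..table.shape[0]-1 and base codes 0..3. Positions
    where the reference or read base is N emit the smallest positive mass of
    the quality's table (never 0).
    """

    table: np.ndarray  # (n_quals, 4, 4)

    def __post_init__(self):
        t = np.asarray(self.table, dtype=float)
        if t.ndim != 3 or t.shape[1:] != (4, 4):
            raise ValueError("table must have shape (n_quals, 4, 4)")
        _validate_rows(t, "QualityErrorModel")
        object.__setattr__(self, "table", t)

    @classmethod
    def theoretical(cls, max_qual: int = 60) -> "QualityErrorModel":
        """Phred-faithful model: error prob 10^(-q/10), split evenly among the
        three wrong bases."""
        q = np.arange(max_qual + 1)
        err = np.minimum(10.0 ** (-q / 10.0), 0.999)
        t = np.empty((max_qual + 1, 4, 4))
        for c in range(4):
            t[:, c, :] = err[:, None] / 3.0
            t[:, c, c] = 1.0 - err
        return cls(t)

    def floor_mass(self) -> np.ndarray:
        """Per-quality smallest positive emission mass (used for N bases)."""
        t = np.where(self.table > 0, self.table, np.inf)
        return t.min(axis=(1, 2))


@dataclass(frozen=True)
class ProfileErrorModel:
    """P(observed base r | read position, reference base c), quality-free."""

    table: np.ndarray  # (max_read_len, 4, 4)

    def __post_init__(self):
        t = np.asarray(self.table, dtype=float)
        if t.ndim != 3 or t.shape[1:] != (4, 4):
            raise ValueError("table must have shape (n_positions, 4, 4)")
        _validate_rows(t, "ProfileErrorModel")
        object.__setattr__(self, "table", t)

    @classmethod
    def flat(cls, max_read_len: int, error_rate: float = 0.01) -> "ProfileErrorModel":
        t = np.empty((max_read_len, 4, 4))
        for c in range(4):
            t[:, c, :] = error_rate / 3.0
            t[:, c, c] = 1.0 - error_rate
        return cls(t)

    def floor_mass(self) -> np.ndarray:
        t = np.where(self.table > 0, self.table, np.inf)
        return t.min(axis=(1, 2))


ErrorModel = Union[QualityErrorModel, ProfileErrorModel]


@dataclass
class ModelParams:
    """Everything needed to score or simulate a read."""

    theta: np.ndarray  # M+1 probabilities; index 0 = noise
    lambda_f: LengthDistribution
    lambda_r: LengthDistribution
    rspd: Rspd
    error: ErrorModel
    strand_specific: bool = False
    noise_background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.theta < 0) or not np.isclose(self.theta.sum(), 1.0):
            raise ValueError("theta must be a probability vector")
        self.noise_background = np.asarray(self.noise_background, dtype=float)
        self.noise_background = self.noise_background / self.noise_background.sum()

    @property
    def n_transcripts(self) -> int:
        return self.theta.size - 1

    @property
    def orientation_prob(self) -> float:
        return 1.0 if self.strand_specific else 0.5

    @classmethod
    def default(
        cls,
        ts: TranscriptSet,
        read_len: int = 35,
        fragment_mean: float = 280.0,
        fragment_sd: float = 17.0,
        strand_specific: bool = False,
        use_quality: bool = True,
        rspd_bins: int = 20,
    ) -> "ModelParams":
        m = len(ts)
        theta = np.full(m + 1, 1.0 / (m + 1))
        err: ErrorModel
        if use_quality:
            err = QualityErrorModel.theoretical()
        else:
            err = ProfileErrorModel.flat(read_len)
        return cls(
            theta=theta,
            lambda_f=LengthDistribution.discretized_normal(fragment_mean, fragment_sd),
            lambda_r=LengthDistribution.point(read_len),
            rspd=Rspd.uniform(rspd_bins),
            error=err,
            strand_specific=strand_specific,
        )


def _quals_to_codes(quals: str) -> np.ndarray:
    return np.frombuffer(quals.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33


def emission_log_prob(
    error: ErrorModel,
    read_codes: np.ndarray,
    qual_codes: Optional[np.ndarray],
    ref_codes: np.ndarray,
) -> float:
    """log P(read characters | reference characters) under either error model."""
    if read_codes.size != ref_codes.size:
        raise ValueError("read and reference windows differ in length")
    if isinstance(error, QualityErrorModel):
        if qual_codes is None:
            raise ValueError("quality model selected but no quality string given")
        rows = error.table[qual_codes]
        floors = error.floor_mass()[qual_codes]
    else:
        pos = np.arange(read_codes.size)
        rows = error.table[pos]
        floors = error.floor_mass()[pos]
    valid = (read_codes < 4) & (ref_codes < 4)
    p = np.where(
        valid,
        rows[np.arange(read_codes.size), np.minimum(ref_codes, 3), np.minimum(read_codes, 3)],
        floors,
    )
    if np.any(p <= 0):
        return -np.inf
    return float(np.log(p).sum())


def read_emission_prob(
    params: ModelParams, read_seq: str, quals: Optional[str], ref_seq: str
) -> float:
    """P(read sequence | aligned reference window) — product of per-character
    emissions under the selected error model."""
    read_codes = encode_seq(read_seq)
    ref_codes = encode_seq(ref_seq)
    qual_codes = _quals_to_codes(quals) if quals is not None else None
    return float(np.exp(emission_log_prob(params.error, read_codes, qual_codes, ref_codes)))


def alignment_weight(params: ModelParams, read, aln, ts: TranscriptSet) -> float:
    """Joint weight of a read (pair) under one candidate alignment, excluding theta.

    Assembles P(orientation) * lambda_F(f | l_i) * RSPD(start) * lambda_R(l | f)
    * emission terms. For SE reads the unknown fragment length is summed out;
    the feasible range is orientation-aware (forward: the fragment starts at
    the read's start; reverse: it ends at the read's end).

    This is the scalar reference implementation; the EM/Gibbs engine uses a
    vectorized equivalent (tested against this one).
    """
    from .reference import revcomp

    t = ts[aln.tindex]
    L = t.length
    seq = t.sequence
    p_o = params.orientation_prob
    lam_f = params.lambda_f.truncated(L)
    if lam_f is None:
        return 0.0

    def emis(read_seq, quals, ref_window, rc):
        ref = revcomp(ref_window) if rc else ref_window
        q = _quals_to_codes(quals) if quals is not None else None
        return np.exp(emission_log_prob(params.error, encode_seq(read_seq), q, encode_seq(ref)))

    l1 = len(read.seq1)
    if read.paired:
        f = aln.fragment_length
        if f is None:
            raise ValueError("paired alignment must carry a fragment length")
        s = aln.pos
        if s < 0 or s + f > L:
            return 0.0
        lf = lam_f.prob(f)
        if lf == 0.0:
            return 0.0
        lam_r = params.lambda_r.truncated(f)
        if lam_r is None:
            return 0.0
        l2 = len(read.seq2)
        start_p = rspd_start_prob(params.rspd, s, L - f + 1)
        if aln.reverse:
            # fragment from the antisense strand: mate1 reverse-complemented at
            # the fragment's right end, mate2 forward at its left end
            e1 = emis(read.seq1, read.qual1, seq[s + f - l1 : s + f], rc=True)
            e2 = emis(read.seq2, read.qual2, seq[s : s + l2], rc=False)
        else:
            e1 = emis(read.seq1, read.qual1, seq[s : s + l1], rc=False)
            e2 = emis(read.seq2, read.qual2, seq[s + f - l2 : s + f], rc=True)
        return float(p_o * lf * start_p * lam_r.prob(l1) * lam_r.prob(l2) * e1 * e2)

    # single-end: marginalize the fragment length
    pos = aln.pos
    if pos < 0 or pos + l1 > L:
        return 0.0
    e1 = emis(read.seq1, read.qual1, seq[pos : pos + l1], rc=aln.reverse)
    total = 0.0
    for f in range(max(lam_f.min_len, l1), lam_f.max_len + 1):
        lf = lam_f.prob(f)
        if lf == 0.0:
            continue
        lam_r = params.lambda_r.truncated(f)
        if lam_r is None:
            continue
        lr = lam_r.prob(l1)
        if lr == 0.0:
            continue
        if aln.reverse:
            s = pos + l1 - f  # fragment ends at the read's right end
        else:
            s = pos
        if s < 0 or s + f > L:
            continue
        total += lf * lr * rspd_start_prob(params.rspd, s, L - f + 1)
    return float(p_o * e1 * total)


def noise_weight(params: ModelParams, read) -> float:
    """Weight of a read under the noise component: i.i.d. background characters
    times the (untruncated) read-length mass; transcript-independent."""
    bg = params.noise_background
    w = 1.0
    for seq in filter(None, (read.seq1, read.seq2)):
        codes = encode_seq(seq)
        p = np.where(codes < 4, bg[np.minimum(codes, 3)], bg.min())
        w *= float(np.prod(p)) * params.lambda_r.prob(len(seq))
    return w


# ---------------------------------------------------------------------------
# plain-text serialization (learn-then-simulate workflow)

def save_params(params: ModelParams, path) -> None:
    """Write model parameters to a sectioned human-readable text file."""
    with open(path, "w") as fh:
        fh.write("# txem model parameters\n")
        fh.write(f"[strand_specific]\n{int(params.strand_specific)}\n")
        fh.write("[theta]\n")
        fh.write(" ".join(f"{x:.12g}" for x in params.theta) + "\n")
        for name, d in (("lambda_f", params.lambda_f), ("lambda_r", params.lambda_r)):
            fh.write(f"[{name}]\n{d.min_len}\n")
            fh.write(" ".join(f"{x:.12g}" for x in d.pmf) + "\n")
        fh.write("[rspd]\n")
        fh.write(" ".join(f"{x:.12g}" for x in params.rspd.bins) + "\n")
        fh.write("[noise_background]\n")
        fh.write(" ".join(f"{x:.12g}" for x in params.noise_background) + "\n")
        kind = "quality" if isinstance(params.error, QualityErrorModel) else "profile"
        fh.write(f"[error_model]\n{kind} {params.error.table.shape[0]}\n")
        for block in params.error.table:
            fh.write(" ".join(f"{x:.12g}" for x in block.ravel()) + "\n")


def load_params(path) -> ModelParams:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    sec: dict[str, list[str]] = {}
    cur = None
    for ln in lines:
        if ln.startswith("["):
            cur = ln.strip("[]")
            sec[cur] = []
        else:
            sec[cur].append(ln)

    def vec(name, row=0):
        return np.array([float(x) for x in sec[name][row].split()])

    kind, n_rows = sec["error_model"][0].split()
    table = np.array(
        [[float(x) for x in row.split()] for row in sec["error_model"][1:]]
    ).reshape(int(n_rows), 4, 4)
    error: ErrorModel = (
        QualityErrorModel(table) if kind == "quality" else ProfileErrorModel(table)
    )
    return ModelParams(
        theta=vec("theta"),
        lambda_f=LengthDistribution(int(sec["lambda_f"][0]), vec("lambda_f", 1)),
        lambda_r=LengthDistribution(int(sec["lambda_r"][0]), vec("lambda_r", 1)),
        rspd=Rspd(vec("rspd")),
        error=error,
        strand_specific=bool(int(sec["strand_specific"][0])),
        noise_background=vec("noise_background"),
    )
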