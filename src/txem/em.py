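"""Maximum-likelihood abundance estimation by EM.

The E-step allocates each read across its candidate alignments plus the noise
outcome in proportion to theta times the model weight; the M-step sets
theta_i proportional to c_i / (N m_i), where m_i is the probability that a
fragment from transcript i survives the multiplicity and poly(A) filters
(de-biasing the estimates for repetitive and tailed transcripts). Auxiliary
distributions (error model; fragment lengths for PE; optionally the RSPD and
the noise background) are re-estimated during the first 20 iterations and
every 100th iteration thereafter. Iteration stops when every theta_i >= 1e-7
changes by less than 0.1% (relative).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import (
    LengthDistribution,
    ModelParams,
    ProfileErrorModel,
    QualityErrorModel,
    Rspd,
    alignment_weight,
    noise_weight,
)
from .readsio import AlignmentSet
from .reference import TranscriptSet


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class AlignFilterConfig:
    """Aligner/filter settings that define which reads are observable."""

    seed_length: int = 25
    max_mismatch: int = 2
    max_alignments: int = 200
    polya_fraction: float = 0.9


@dataclass
class EmConfig:
    max_iterations: int = 10000
    rel_tol: float = 1e-3
    theta_min: float = 1e-7
    aux_first: int = 20
    aux_every: int = 100
    estimate_rspd: bool = False
    estimate_noise_background: bool = False
    apply_repeat_correction: bool = True
    repeat_floor: float = 1e-8
    repeat_mc_limit: int = 10**6  # exact enumeration above this uses Monte Carlo
    repeat_mc_draws: int = 10**4
    filter_cfg: AlignFilterConfig = field(default_factory=AlignFilterConfig)
    seed: int = 0


@dataclass
class Responsibilities:
    """Per-read posterior over candidate alignments plus the noise outcome.

    Flat layout: segment n covers read ``read_ids[n]``; its first slot is the
    noise outcome, the rest follow the read's candidate list order.
    """

    aset: AlignmentSet
    read_ids: np.ndarray
    indptr: np.ndarray
    comp: np.ndarray  # theta component per slot (0 = noise)
    probs: np.ndarray

    def per_read(self, read_id: int):
        """(noise posterior, [(Alignment, posterior), ...]) for one read."""
        n = int(np.searchsorted(self.read_ids, read_id))
        if n >= self.read_ids.size or self.read_ids[n] != read_id:
            raise KeyError(f"read {read_id} is filtered or unknown")
        lo, hi = self.indptr[n], self.indptr[n + 1]
        p = self.probs[lo:hi]
        return float(p[0]), list(zip(self.aset.candidates[read_id], p[1:].tolist()))

    def counts(self, n_components: int) -> np.ndarray:
        return np.bincount(self.comp, weights=self.probs, minlength=n_components)


@dataclass
class MLEstimates:
    theta: np.ndarray
    tau: np.ndarray
    tpm: np.ndarray
    expected_counts: np.ndarray  # length M+1 (index 0 = noise), sums to N
    eff_lengths: np.ndarray
    m: np.ndarray
    params: ModelParams
    log_likelihood: float
    iterations_run: int
    n_reads: int
    responsibilities: Optional[Responsibilities] = None
    _engine: object = None


# ---------------------------------------------------------------------------
# vectorized scoring engine


def _quals_to_codes(q: str) -> np.ndarray:
    return np.frombuffer(q.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33


class _Engine:
    """Flat-array evaluation of the read model over an alignment set.

    Geometry (which reference characters align to which read characters, and
    the feasible-fragment bookkeeping) is computed once; changing parameters
    only re-gathers emission tables and positional prefix sums.
    """

    def __init__(self, aset: AlignmentSet, ts: TranscriptSet, params: ModelParams):
        from .reference import encode_seq

        self.aset = aset
        self.ts = ts
        self.M = len(ts)
        codes, offsets = ts.encoded()
        self.read_ids = aset.unfiltered_indices()
        self.n_reads = self.read_ids.size
        if self.n_reads == 0:
            raise EstimationError("no unfiltered reads")

        seg = np.array(
            [1 + len(aset.candidates[r]) for r in self.read_ids], dtype=np.int64
        )
        self.indptr = np.concatenate([[0], np.cumsum(seg)])
        n_slots = int(self.indptr[-1])
        self.comp = np.zeros(n_slots, dtype=np.int64)
        self.slot_read = np.repeat(np.arange(self.n_reads), seg)

        cands = [a for r in self.read_ids for a in aset.candidates[r]]
        self.n_cand = len(cands)
        self.cand_slot = np.flatnonzero(
            np.arange(n_slots) != self.indptr[self.slot_read]
        )
        self.comp[self.cand_slot] = np.array(
            [a.tindex + 1 for a in cands], dtype=np.int64
        )
        self.ct = np.array([a.tindex for a in cands], dtype=np.int64)
        self.cpos = np.array([a.pos for a in cands], dtype=np.int64)
        self.crev = np.array([a.reverse for a in cands], dtype=bool)
        self.cflen = np.array(
            [-1 if a.fragment_length is None else a.fragment_length for a in cands],
            dtype=np.int64,
        )
        self.cand_read = self.slot_read[self.cand_slot]
        self.tlen = ts.lengths

        # per-read sequences/qualities
        reads = [aset.reads[r] for r in self.read_ids]
        self.paired = np.array([r.paired for r in reads], dtype=bool)
        self.l1 = np.array([len(r.seq1) for r in reads], dtype=np.int64)
        self.l2 = np.array(
            [len(r.seq2) if r.paired else 0 for r in reads], dtype=np.int64
        )
        self.has_quals = all(r.qual1 is not None for r in reads)
        rcodes1 = [encode_seq(r.seq1) for r in reads]
        rcodes2 = [encode_seq(r.seq2) if r.paired else None for r in reads]
        q1 = [(_quals_to_codes(r.qual1) if r.qual1 else None) for r in reads]
        q2 = [(_quals_to_codes(r.qual2) if r.qual2 else None) for r in reads]

        # emission elements, grouped per candidate: mate1 then mate2
        elen = self.l1[self.cand_read] + self.l2[self.cand_read]
        self.e_ptr = np.concatenate([[0], np.cumsum(elen)])
        ne = int(self.e_ptr[-1])
        self.e_ref = np.empty(ne, dtype=np.int64)
        self.e_read = np.empty(ne, dtype=np.int64)
        self.e_qual = np.full(ne, -1, dtype=np.int64)
        self.e_rpos = np.empty(ne, dtype=np.int64)
        for k in range(self.n_cand):
            n = self.cand_read[k]
            t = self.ct[k]
            g = offsets[t]
            L = self.tlen[t]
            lo = self.e_ptr[k]
            l1 = self.l1[n]
            rev = self.crev[k]
            if self.cflen[k] >= 0:  # paired
                f = self.cflen[k]
                s = self.cpos[k]
                l2 = self.l2[n]
                if rev:
                    w1 = codes[g + s + f - l1 : g + s + f]
                    ref1 = np.where(w1 == 4, 4, 3 - w1)[::-1]
                    ref2 = codes[g + s : g + s + l2]
                else:
                    ref1 = codes[g + s : g + s + l1]
                    w2 = codes[g + s + f - l2 : g + s + f]
                    ref2 = np.where(w2 == 4, 4, 3 - w2)[::-1]
                self.e_ref[lo : lo + l1] = ref1
                self.e_ref[lo + l1 : lo + l1 + l2] = ref2
                self.e_read[lo : lo + l1] = rcodes1[n]
                self.e_read[lo + l1 : lo + l1 + l2] = rcodes2[n]
                if q1[n] is not None:
                    self.e_qual[lo : lo + l1] = q1[n]
                    self.e_qual[lo + l1 : lo + l1 + l2] = q2[n]
                self.e_rpos[lo : lo + l1] = np.arange(l1)
                self.e_rpos[lo + l1 : lo + l1 + l2] = np.arange(l2)
            else:
                p = self.cpos[k]
                w = codes[g + p : g + p + l1]
                ref1 = np.where(w == 4, 4, 3 - w)[::-1] if rev else w
                self.e_ref[lo : lo + l1] = ref1
                self.e_read[lo : lo + l1] = rcodes1[n]
                if q1[n] is not None:
                    self.e_qual[lo : lo + l1] = q1[n]
                self.e_rpos[lo : lo + l1] = np.arange(l1)

        # noise emission (background-dependent part recomputed with params)
        self._noise_codes = [
            np.concatenate([rcodes1[n]] + ([rcodes2[n]] if reads[n].paired else []))
            for n in range(self.n_reads)
        ]
        # candidates grouped by transcript for positional-weight evaluation
        self._t_order = np.argsort(self.ct, kind="stable") if self.n_cand else np.empty(0, np.int64)
        sorted_ct = self.ct[self._t_order]
        self._t_values, first = np.unique(sorted_ct, return_index=True)
        self._t_bounds = np.concatenate([first, [self.n_cand]])
        self._noise_cache: Optional[tuple] = None
        self._pos_cache: Optional[tuple] = None
        self.set_params(params)

    # -- parameter-dependent pieces --------------------------------------

    def _emission_logs(self, params: ModelParams) -> np.ndarray:
        err = params.error
        if isinstance(err, QualityErrorModel):
            if not self.has_quals:
                raise EstimationError(
                    "quality-based error model selected but reads carry no qualities"
                )
            idx0 = np.clip(self.e_qual, 0, err.table.shape[0] - 1)
            floor = err.floor_mass()[idx0]
            tab = err.table
        else:
            idx0 = np.minimum(self.e_rpos, err.table.shape[0] - 1)
            floor = err.floor_mass()[idx0]
            tab = err.table
        valid = (self.e_ref < 4) & (self.e_read < 4)
        p = np.where(
            valid,
            tab[idx0, np.minimum(self.e_ref, 3), np.minimum(self.e_read, 3)],
            floor,
        )
        with np.errstate(divide="ignore"):
            logp = np.log(p)
        return np.add.reduceat(logp, self.e_ptr[:-1]) if self.n_cand else np.empty(0)

    def _positional_fast_ok(self, params: ModelParams) -> bool:
        return params.rspd.is_uniform and params.lambda_r.pmf.size == 1

    def _positional_logs(self, params: ModelParams) -> np.ndarray:
        """log of P(o) * sum_f lambda_F(f|l) * lambda_R * RSPD terms per candidate."""
        if not self._positional_fast_ok(params):
            return self._positional_logs_slow(params)
        L0 = params.lambda_r.min_len
        lam = params.lambda_f
        out = np.zeros(self.n_cand)
        for gi, t in enumerate(self._t_values):
            sel = self._t_order[self._t_bounds[gi] : self._t_bounds[gi + 1]]
            L = int(self.tlen[t])
            trunc = lam.truncated(L)
            if trunc is None:
                out[sel] = 0.0
                continue
            fmin, fmax = trunc.min_len, trunc.max_len
            f = np.arange(fmin, fmax + 1)
            arr = trunc.pmf / (L - f + 1)
            A = np.concatenate([[0.0], np.cumsum(arr)])  # A[x-fmin+1] = sum_{fmin..x}

            def cum(x):
                return A[np.clip(x - fmin + 1, 0, A.size - 1)]

            pe = self.cflen[sel] >= 0
            w = np.zeros(sel.size)
            if np.any(pe):
                ks = sel[pe]
                fr = self.cflen[ks]
                n1 = self.l1[self.cand_read[ks]]
                n2 = self.l2[self.cand_read[ks]]
                okf = (
                    (fr >= fmin)
                    & (fr <= fmax)
                    & (fr >= np.maximum(n1, n2))
                    & (n1 == L0)
                    & (n2 == L0)
                    & (self.cpos[ks] >= 0)
                    & (self.cpos[ks] + fr <= L)
                )
                wp = np.where(okf, trunc.pmf[np.clip(fr - fmin, 0, f.size - 1)], 0.0)
                wp = np.where(okf, wp / (L - fr + 1), 0.0)
                w[pe] = wp
            if np.any(~pe):
                ks = sel[~pe]
                l = self.l1[self.cand_read[ks]]
                pos = self.cpos[ks]
                lmin = np.maximum(fmin, l)
                hi = np.where(self.crev[ks], np.minimum(pos + l, fmax), L - pos)
                wse = np.where(
                    (l == L0) & (hi >= lmin), cum(hi) - cum(lmin - 1), 0.0
                )
                w[~pe] = wse
            out[sel] = w
        with np.errstate(divide="ignore"):
            return np.log(out) + np.log(params.orientation_prob)

    def _positional_logs_slow(self, params: ModelParams) -> np.ndarray:
        """General path (non-uniform RSPD or non-degenerate lambda_R):
        scalar fragment-length marginalization per candidate."""
        from .model import rspd_start_prob

        out = np.zeros(self.n_cand)
        for k in range(self.n_cand):
            L = int(self.tlen[self.ct[k]])
            trunc = params.lambda_f.truncated(L)
            if trunc is None:
                continue
            l1 = int(self.l1[self.cand_read[k]])
            if self.cflen[k] >= 0:  # paired: fragment length known
                f = int(self.cflen[k])
                s = int(self.cpos[k])
                lam_r = params.lambda_r.truncated(f)
                if lam_r is None or s < 0 or s + f > L:
                    continue
                l2 = int(self.l2[self.cand_read[k]])
                out[k] = (
                    trunc.prob(f)
                    * rspd_start_prob(params.rspd, s, L - f + 1)
                    * lam_r.prob(l1)
                    * lam_r.prob(l2)
                )
                continue
            pos = int(self.cpos[k])
            total = 0.0
            for f in range(max(trunc.min_len, l1), trunc.max_len + 1):
                lf = trunc.prob(f)
                if lf == 0.0:
                    continue
                lam_r = params.lambda_r.truncated(f)
                if lam_r is None:
                    continue
                lr = lam_r.prob(l1)
                if lr == 0.0:
                    continue
                s = pos + l1 - f if self.crev[k] else pos
                if s < 0 or s + f > L:
                    continue
                total += lf * lr * rspd_start_prob(params.rspd, s, L - f + 1)
            out[k] = total
        with np.errstate(divide="ignore"):
            return np.log(out) + np.log(params.orientation_prob)

    def _noise_logs(self, params: ModelParams) -> np.ndarray:
        bg = params.noise_background
        logbg = np.log(np.concatenate([bg, [bg.min()]]))
        out = np.empty(self.n_reads)
        for n, codes in enumerate(self._noise_codes):
            out[n] = logbg[codes].sum()
        lr = params.lambda_r
        with np.errstate(divide="ignore"):
            out += np.log(np.array([lr.prob(int(l)) for l in self.l1]))
            pe = self.paired
            if np.any(pe):
                out[pe] += np.log(
                    np.array([lr.prob(int(l)) for l in self.l2[pe]])
                )
        return out

    def set_params(self, params: ModelParams) -> None:
        self.params = params
        # positional and noise parts only change when their distributions do
        pos_key = (
            id(params.lambda_f), id(params.rspd), id(params.lambda_r),
            params.strand_specific,
        )
        if self._pos_cache is None or self._pos_cache[0] != pos_key:
            self._pos_cache = (pos_key, self._positional_logs(params))
        noise_key = (params.noise_background.tobytes(), id(params.lambda_r))
        if self._noise_cache is None or self._noise_cache[0] != noise_key:
            self._noise_cache = (noise_key, self._noise_logs(params))
        log_c = self._emission_logs(params) + self._pos_cache[1]
        log_n = self._noise_cache[1]
        logw = np.full(self.indptr[-1], -np.inf)
        logw[self.indptr[:-1]] = log_n
        logw[self.cand_slot] = log_c
        shift = np.maximum.reduceat(logw, self.indptr[:-1])
        shift = np.where(np.isfinite(shift), shift, 0.0)
        self.shift = shift
        self.w_lin = np.exp(logw - shift[self.slot_read])

    # -- inference --------------------------------------------------------

    def responsibilities(self, theta: np.ndarray):
        a = theta[self.comp] * self.w_lin
        sums = np.add.reduceat(a, self.indptr[:-1])
        bad = sums <= 0.0
        if np.any(bad):
            n = int(np.flatnonzero(bad)[0])
            raise EstimationError(
                f"read {self.aset.reads[self.read_ids[n]].id!r} has zero weight "
                "under every outcome (noise component disabled?)"
            )
        resp = a / sums[self.slot_read]
        counts = np.bincount(self.comp, weights=resp, minlength=self.M + 1)
        loglik = float(np.log(sums).sum() + self.shift.sum())
        return resp, counts, loglik

    def make_responsibilities(self, resp: np.ndarray) -> Responsibilities:
        return Responsibilities(
            aset=self.aset,
            read_ids=self.read_ids,
            indptr=self.indptr,
            comp=self.comp,
            probs=resp,
        )

    # -- auxiliary parameter re-estimation --------------------------------

    def update_auxiliary(
        self, resp: np.ndarray, params: ModelParams, config: "EmConfig"
    ) -> tuple[ModelParams, bool]:
        """Re-estimate error model (+ PE fragment lengths, optional RSPD and
        noise background) from responsibility-weighted counts. Returns the new
        params and whether lambda_F or the RSPD changed (which invalidates m)."""
        cand_resp = resp[self.cand_slot]
        new = {}
        geom_changed = False

        err = params.error
        wflat = np.repeat(cand_resp, np.diff(self.e_ptr))
        valid = (self.e_ref < 4) & (self.e_read < 4)
        if isinstance(err, QualityErrorModel):
            nq = err.table.shape[0]
            tab = np.zeros_like(err.table)
            idx0 = np.clip(self.e_qual, 0, nq - 1)
        else:
            tab = np.zeros_like(err.table)
            idx0 = np.minimum(self.e_rpos, tab.shape[0] - 1)
        np.add.at(
            tab,
            (
                idx0[valid],
                self.e_ref[valid],
                self.e_read[valid],
            ),
            wflat[valid],
        )
        tab += 1.0  # add-one smoothing
        tab /= tab.sum(axis=-1, keepdims=True)
        new["error"] = type(err)(tab)

        if np.any(self.paired) and self.n_cand:
            pe = self.cflen >= 0
            if np.any(pe):
                w = np.bincount(self.cflen[pe], weights=cand_resp[pe])
                nz = np.flatnonzero(w)
                lo, hi = int(nz[0]), int(nz[-1])
                new["lambda_f"] = LengthDistribution(lo, w[lo : hi + 1])
                geom_changed = True

        if config.estimate_rspd and self.n_cand:
            B = params.rspd.n_bins
            rel = self.cpos / np.maximum(self.tlen[self.ct], 1)
            bins = np.minimum((rel * B).astype(np.int64), B - 1)
            w = np.bincount(bins, weights=cand_resp, minlength=B) + 1.0
            new["rspd"] = Rspd(w)
            geom_changed = True

        if config.estimate_noise_background:
            noise_resp = resp[self.indptr[:-1]]
            counts = np.zeros(4)
            for n, codes in enumerate(self._noise_codes):
                if noise_resp[n] > 1e-6:
                    counts += np.bincount(
                        np.minimum(codes, 3), minlength=4
                    ) * noise_resp[n]
            if counts.sum() > 0:
                new["noise_background"] = (counts + 1.0) / (counts.sum() + 4.0)

        return replace(params, **new), geom_changed


# ---------------------------------------------------------------------------
# public operations


def e_step(params: ModelParams, aset: AlignmentSet, ts: TranscriptSet) -> Responsibilities:
    """Posterior over candidate alignments (plus noise) per unfiltered read."""
    eng = _Engine(aset, ts, params)
    resp, _, _ = eng.responsibilities(params.theta)
    return eng.make_responsibilities(resp)


def m_step(counts: np.ndarray, m: Optional[np.ndarray] = None) -> np.ndarray:
    """theta_i proportional to c_i / m_i for transcripts (c_0 unadjusted)."""
    counts = np.asarray(counts, dtype=float)
    theta = counts.copy()
    if m is not None:
        theta[1:] = counts[1:] / np.asarray(m, dtype=float)
    total = theta.sum()
    if total <= 0:
        raise EstimationError("all responsibilities are zero")
    return theta / total


def theta_to_tau(theta: np.ndarray, eff_lengths: np.ndarray) -> np.ndarray:
    """Transcript fractions: tau_i = (theta_i/el_i) / sum_j (theta_j/el_j),
    noise excluded."""
    th = np.asarray(theta, dtype=float)[1:]
    el = np.asarray(eff_lengths, dtype=float)
    if np.any((th > 0) & (el <= 0)):
        raise EstimationError("positive abundance on transcript with effective length 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(el > 0, th / np.maximum(el, 1e-300), 0.0)
    total = ratio.sum()
    if total <= 0:
        warnings.warn("all transcript abundances are zero; tau set to 0")
        return np.zeros_like(ratio)
    return ratio / total


def gene_and_isopct(tau: np.ndarray, ts: TranscriptSet):
    """Gene-level fractions (member sums) and within-gene isoform fractions.

    Returns (gene_ids, gene_tau, isopct) with isopct_i = tau_i / gene_tau in
    [0,1] (0 for zero-abundance genes).
    """
    gene_ids = list(ts.gene_map)
    gidx = ts.gene_of()
    gene_tau = np.bincount(gidx, weights=tau, minlength=len(gene_ids))
    denom = gene_tau[gidx]
    isopct = np.where(denom > 0, tau / np.where(denom > 0, denom, 1.0), 0.0)
    return gene_ids, gene_tau, isopct


def estimate_repeat_pass_prob(
    ts: TranscriptSet,
    params: ModelParams,
    filter_cfg: AlignFilterConfig = AlignFilterConfig(),
    paired: bool = False,
    read_len: Optional[int] = None,
    mc_limit: int = 10**6,
    mc_draws: int = 10**4,
    floor: float = 1e-8,
    seed: int = 0,
) -> np.ndarray:
    """m_i: probability that an (error-free) fragment from transcript i yields
    a read surviving the multiplicity and poly(A) filters.

    Exact enumeration over all (fragment length, start, orientation) when
    transcript_length x |support(lambda_F)| <= mc_limit, else seeded Monte
    Carlo. Values are floored at `floor` so fully repetitive transcripts keep
    a finite correction.
    """
    from .aligner import window_survival

    if read_len is None:
        read_len = params.lambda_r.min_len  # point-mass read length
    surv = window_survival(
        ts,
        read_len,
        filter_cfg.seed_length,
        filter_cfg.max_mismatch,
        filter_cfg.max_alignments,
        filter_cfg.polya_fraction,
    )
    rng = np.random.default_rng(seed)
    p_rev = 0.0 if params.strand_specific else 0.5
    m = np.ones(len(ts))
    for t in range(len(ts)):
        L = int(ts.lengths[t])
        trunc = params.lambda_f.truncated(L)
        if trunc is None or L < read_len:
            m[t] = floor
            continue
        fmin = max(trunc.min_len, read_len if not paired else read_len)
        fmax = trunc.max_len
        if fmin > fmax:
            m[t] = floor
            continue
        fvals = np.arange(fmin, fmax + 1)
        pf = np.array([trunc.prob(int(f)) for f in fvals])
        pf_total = pf.sum()
        if pf_total <= 0:
            m[t] = floor
            continue
        pf = pf / pf_total  # condition on fragments long enough to emit reads
        s = surv[t].astype(float)
        S = np.concatenate([[0.0], np.cumsum(s)])
        n_win = s.size  # == L - read_len + 1
        exact = L * fvals.size <= mc_limit
        if exact and not paired:
            acc = 0.0
            for f, p in zip(fvals, pf):
                n_starts = L - f + 1
                fw = (S[min(n_starts, n_win)] - S[0]) / n_starts
                lo = min(max(f - read_len, 0), n_win)
                rv = (S[n_win] - S[lo]) / n_starts
                acc += p * ((1 - p_rev) * fw + p_rev * rv)
            m[t] = acc
        elif exact and paired:
            acc = 0.0
            sb = surv[t]
            for f, p in zip(fvals, pf):
                n_starts = L - f + 1
                starts = np.arange(n_starts)
                w1 = sb[starts]
                w2 = sb[np.minimum(starts + f - read_len, n_win - 1)]
                both = (w1 & w2).mean()
                acc += p * both  # orientation-symmetric for equal mate lengths
            m[t] = acc
        else:
            f = rng.choice(fvals, size=mc_draws, p=pf)
            smax = L - f + 1
            st = (rng.random(mc_draws) * smax).astype(np.int64)
            rev = rng.random(mc_draws) < p_rev
            win = np.where(rev, st + f - read_len, st)
            win = np.clip(win, 0, n_win - 1)
            ok = surv[t][win]
            if paired:
                win2 = np.where(rev, st, st + f - read_len)
                ok = ok & surv[t][np.clip(win2, 0, n_win - 1)]
            m[t] = ok.mean()
    return np.maximum(m, floor)


def update_auxiliary(
    resp: Responsibilities,
    aset: AlignmentSet,
    params: ModelParams,
    config: Optional[EmConfig] = None,
    ts: Optional[TranscriptSet] = None,
) -> ModelParams:
    """Standalone auxiliary re-estimation from a Responsibilities object."""
    config = config or EmConfig()
    if ts is None:
        raise ValueError("ts required")
    eng = _Engine(aset, ts, params)
    new, _ = eng.update_auxiliary(resp.probs, params, config)
    return new


def run_em(
    aset: AlignmentSet,
    ts: TranscriptSet,
    params: Optional[ModelParams] = None,
    config: Optional[EmConfig] = None,
    m: Optional[np.ndarray] = None,
) -> MLEstimates:
    """Full EM with the auxiliary-update schedule, convergence rule and
    repeat-filter bias correction; deterministic given inputs and config."""
    config = config or EmConfig()
    if params is None:
        read_len = len(aset.reads[0].seq1)
        params = ModelParams.default(
            ts,
            read_len=read_len,
            use_quality=all(r.qual1 is not None for r in aset.reads),
        )
    M = len(ts)
    N = aset.n_unfiltered
    eng = _Engine(aset, ts, params)

    if m is None:
        if config.apply_repeat_correction:
            paired = aset.reads[0].paired
            m = estimate_repeat_pass_prob(
                ts,
                params,
                config.filter_cfg,
                paired=paired,
                mc_limit=config.repeat_mc_limit,
                mc_draws=config.repeat_mc_draws,
                floor=config.repeat_floor,
                seed=config.seed,
            )
        else:
            m = np.ones(M)

    from ._kernels import em_theta_iterations

    theta = np.full(M + 1, 1.0 / (M + 1))
    loglik = -np.inf
    it = 0
    converged = False
    while it < config.max_iterations and not converged:
        it += 1
        resp, counts, loglik = eng.responsibilities(theta)
        if it <= config.aux_first or it % config.aux_every == 0:
            new_params, geom_changed = eng.update_auxiliary(resp, eng.params, config)
            eng.set_params(new_params)
            if geom_changed and config.apply_repeat_correction:
                m = estimate_repeat_pass_prob(
                    ts,
                    new_params,
                    config.filter_cfg,
                    paired=aset.reads[0].paired,
                    mc_limit=config.repeat_mc_limit,
                    mc_draws=config.repeat_mc_draws,
                    floor=config.repeat_floor,
                    seed=config.seed,
                )
        new_theta = m_step(counts, m)
        active = theta >= config.theta_min
        rel = np.abs(new_theta[active] - theta[active]) / np.maximum(
            theta[active], 1e-300
        )
        theta = new_theta
        if it > 1 and rel.size and rel.max() < config.rel_tol:
            converged = True
            break
        if it >= config.aux_first:
            # run theta-only iterations up to the next auxiliary checkpoint
            nxt = ((it // config.aux_every) + 1) * config.aux_every
            budget = min(nxt - 1, config.max_iterations) - it
            if budget > 0:
                theta, done, converged = em_theta_iterations(
                    eng.indptr,
                    eng.comp,
                    eng.w_lin,
                    theta.copy(),
                    1.0 / np.asarray(m, dtype=float),
                    M + 1,
                    budget,
                    config.rel_tol,
                    config.theta_min,
                )
                it += done

    resp, counts, loglik = eng.responsibilities(theta)
    eff = ts.effective_lengths(eng.params.lambda_f)
    tau = theta_to_tau(theta, eff)
    final_params = replace(eng.params, theta=theta)
    return MLEstimates(
        theta=theta,
        tau=tau,
        tpm=tau * 1e6,
        expected_counts=counts,
        eff_lengths=eff,
        m=np.asarray(m, dtype=float),
        params=final_params,
        log_likelihood=loglik,
        iterations_run=it,
        n_reads=N,
        responsibilities=eng.make_responsibilities(resp),
        _engine=eng,
    )
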