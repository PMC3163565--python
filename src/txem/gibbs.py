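"""Bayesian posterior inference by two-stage sampling.

theta gets a symmetric Dirichlet(alpha) prior (alpha = 1, i.e. uniform, so the
posterior mode coincides with the ML estimate). Stage one integrates theta out
and runs collapsed Gibbs over fragment assignments: each read's assignment is
resampled given all the others with probability proportional to
(alpha + c_{-n,i}) times the model weight of the candidate. One count vector is
recorded per sweep after burn-in. Stage two draws theta ~ Dirichlet(c + alpha)
per count vector; theta draws are converted to transcript fractions and
summarized as posterior means and equal-tailed credibility intervals.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._kernels import gibbs_sweeps
from .em import MLEstimates, _Engine, theta_to_tau
from .readsio import AlignmentSet
from .reference import TranscriptSet


@dataclass
class SamplerConfig:
    alpha: float = 1.0
    n_count_vectors: int = 1000
    theta_per_vector: int = 50
    burn_in: int = 200
    thin: int = 1  # sweeps between recorded count vectors
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if min(self.n_count_vectors, self.theta_per_vector, self.burn_in + 1, self.thin) <= 0:
            raise ValueError("sampler counts must be positive")


@dataclass
class PosteriorSummary:
    """PME and credibility intervals of tau/TPM at transcript and gene level."""

    transcript_ids: list
    tau_pme: np.ndarray
    tpm_pme: np.ndarray
    tpm_ci_lower: np.ndarray
    tpm_ci_upper: np.ndarray
    gene_ids: list
    gene_tau_pme: np.ndarray
    gene_tpm_pme: np.ndarray
    gene_tpm_ci_lower: np.ndarray
    gene_tpm_ci_upper: np.ndarray
    credibility_level: float


def gibbs_count_vectors(
    aset: AlignmentSet,
    ts: TranscriptSet,
    ml: MLEstimates,
    cfg: SamplerConfig,
) -> np.ndarray:
    """Sample (n_count_vectors, M+1) fragment-count vectors by collapsed Gibbs.

    Initial assignments are drawn from the per-read posteriors at the ML
    parameters; auxiliary distributions stay fixed at their ML values. Each
    vector sums to the number of unfiltered reads.
    """
    eng: Optional[_Engine] = ml._engine  # reuse precomputed weights if present
    if eng is None or eng.aset is not aset:
        eng = _Engine(aset, ts, ml.params)
        eng.set_params(ml.params)
    resp, _, _ = eng.responsibilities(ml.theta)

    rng = np.random.default_rng(cfg.seed)
    # vectorized categorical draw per read from its responsibility segment
    cum = np.cumsum(resp)
    seg_tot = cum[eng.indptr[1:] - 1]
    base = np.concatenate([[0.0], cum[eng.indptr[1:-1] - 1]])
    u = rng.random(eng.n_reads) * (seg_tot - base) + base
    assign = np.searchsorted(cum, u, side="right")
    assign = np.minimum(assign, eng.indptr[1:] - 1).astype(np.int64)

    counts = np.bincount(eng.comp[assign], minlength=eng.M + 1).astype(np.int64)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    vectors = gibbs_sweeps(
        eng.indptr,
        eng.comp,
        eng.w_lin,
        assign,
        counts,
        float(cfg.alpha),
        int(cfg.burn_in),
        int(cfg.n_count_vectors),
        int(cfg.thin),
        kernel_seed,
    )
    return vectors


def theta_samples_from_counts(
    count_vectors: np.ndarray, cfg: SamplerConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw theta ~ Dirichlet(c + alpha) per count vector; returns an array of
    shape (n_count_vectors * theta_per_vector, M+1)."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    cv = np.asarray(count_vectors, dtype=float)
    n_vec, dim = cv.shape
    out = np.empty((n_vec * cfg.theta_per_vector, dim))
    for i in range(n_vec):
        g = rng.standard_gamma(cv[i] + cfg.alpha, size=(cfg.theta_per_vector, dim))
        out[i * cfg.theta_per_vector : (i + 1) * cfg.theta_per_vector] = (
            g / g.sum(axis=1, keepdims=True)
        )
    return out


def summarize_posterior(
    theta_samples: np.ndarray,
    ts: TranscriptSet,
    eff_lengths: np.ndarray,
    level: float = 0.95,
    repeat_pass: Optional[np.ndarray] = None,
) -> PosteriorSummary:
    """Convert theta draws to tau, then summarize: PME = sample mean, CI =
    equal-tailed quantiles. Gene summaries use per-sample member sums (interval
    endpoints do not add).

    ``repeat_pass`` (the m_i filter-survival probabilities) de-biases each
    sample the same way the M-step de-biases the ML estimate: sampled counts
    describe *surviving* fragments, so generation-scale abundance is
    proportional to theta_i / m_i.
    """
    if not 0 < level < 1:
        raise ValueError("credibility level must be in (0,1)")
    th = np.asarray(theta_samples, dtype=float)
    if th.ndim != 2 or th.shape[0] == 0:
        raise ValueError("need a nonempty 2-d sample array")
    el = np.asarray(eff_lengths, dtype=float)
    th_t = th[:, 1:]
    if repeat_pass is not None:
        th_t = th_t / np.asarray(repeat_pass, dtype=float)
    ratio = np.where(el > 0, th_t / np.maximum(el, 1e-300), 0.0)
    tau = ratio / np.maximum(ratio.sum(axis=1, keepdims=True), 1e-300)
    tpm = tau * 1e6

    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    tpm_lo, tpm_hi = np.quantile(tpm, [lo_q, hi_q], axis=0)

    gidx = ts.gene_of()
    n_genes = len(ts.gene_map)
    gene_tpm = np.zeros((tpm.shape[0], n_genes))
    np.add.at(gene_tpm.T, gidx, tpm.T)
    g_lo, g_hi = np.quantile(gene_tpm, [lo_q, hi_q], axis=0)

    return PosteriorSummary(
        transcript_ids=ts.ids,
        tau_pme=tau.mean(axis=0),
        tpm_pme=tpm.mean(axis=0),
        tpm_ci_lower=tpm_lo,
        tpm_ci_upper=tpm_hi,
        gene_ids=list(ts.gene_map),
        gene_tau_pme=gene_tpm.mean(axis=0) / 1e6,
        gene_tpm_pme=gene_tpm.mean(axis=0),
        gene_tpm_ci_lower=g_lo,
        gene_tpm_ci_upper=g_hi,
        credibility_level=level,
    )


def posterior_summary(
    aset: AlignmentSet,
    ts: TranscriptSet,
    ml: MLEstimates,
    cfg: Optional[SamplerConfig] = None,
    level: float = 0.95,
) -> tuple[PosteriorSummary, np.ndarray]:
    """Run both sampling stages and summarize; returns (summary, count_vectors)."""
    cfg = cfg or SamplerConfig()
    cv = gibbs_count_vectors(aset, ts, ml, cfg)
    th = theta_samples_from_counts(cv, cfg)
    summary = summarize_posterior(
        th, ts, ml.eff_lengths, level=level, repeat_pass=ml.m
    )
    return summary, cv
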