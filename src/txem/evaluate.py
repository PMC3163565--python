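"""Accuracy statistics (MPE / EF / FP), CI coverage, and mappability."""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .reference import TranscriptSet


def accuracy_stats(
    est: np.ndarray,
    truth: np.ndarray,
    ef_threshold: float = 10.0,
    fp_tpm_cutoff: float = 1.0,
) -> dict:
    """MPE / EF / FP for one abundance vector pair (TPM scale for FP).

    Percent error = 100*|est - true|/true over entries with true > 0; MPE is
    its median, EF the fraction exceeding ef_threshold. FP is the fraction of
    entries with truth < fp_tpm_cutoff called >= fp_tpm_cutoff. Undefined
    statistics (empty eligible sets) come back as NaN.
    """
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError("est and truth must align")
    if np.any(truth < 0):
        raise ValueError("truth must be nonnegative")
    pos = truth > 0
    if np.any(pos):
        pe = 100.0 * np.abs(est[pos] - truth[pos]) / truth[pos]
        mpe = float(np.median(pe))
        ef = float(np.mean(pe > ef_threshold) * 100.0)
    else:
        mpe = ef = float("nan")
    low = truth < fp_tpm_cutoff
    fp = float(np.mean(est[low] >= fp_tpm_cutoff) * 100.0) if np.any(low) else float("nan")
    return {"mpe": mpe, "ef": ef, "fp": fp}


def accuracy_report(
    est_tau: np.ndarray,
    true_tau: np.ndarray,
    ts: TranscriptSet,
    ef_threshold: float = 10.0,
    fp_tpm_cutoff: float = 1.0,
) -> pd.DataFrame:
    """The three-level layout: gene, global isoform, within-gene isoform.

    Gene/isoform rows compare TPM; the within-gene row compares isoform
    fractions within genes that are truly expressed and have >= 2 isoforms
    (FP left NaN there — fraction space has no TPM cutoff).
    """
    est_tau = np.asarray(est_tau, dtype=float)
    true_tau = np.asarray(true_tau, dtype=float)
    gidx = ts.gene_of()
    n_genes = len(ts.gene_map)
    g_est = np.bincount(gidx, weights=est_tau, minlength=n_genes)
    g_true = np.bincount(gidx, weights=true_tau, minlength=n_genes)

    rows = {
        "gene": accuracy_stats(g_est * 1e6, g_true * 1e6, ef_threshold, fp_tpm_cutoff),
        "isoform": accuracy_stats(
            est_tau * 1e6, true_tau * 1e6, ef_threshold, fp_tpm_cutoff
        ),
    }
    iso_per_gene = np.bincount(gidx, minlength=n_genes)
    eligible = (g_true[gidx] > 0) & (iso_per_gene[gidx] >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wt = np.where(g_true[gidx] > 0, true_tau / np.maximum(g_true[gidx], 1e-300), 0.0)
        we = np.where(g_est[gidx] > 0, est_tau / np.maximum(g_est[gidx], 1e-300), 0.0)
    sub_t, sub_e = wt[eligible], we[eligible]
    pos = sub_t > 0
    if np.any(pos):
        pe = 100.0 * np.abs(sub_e[pos] - sub_t[pos]) / sub_t[pos]
        rows["within_gene"] = {
            "mpe": float(np.median(pe)),
            "ef": float(np.mean(pe > ef_threshold) * 100.0),
            "fp": float("nan"),
        }
    else:
        rows["within_gene"] = {"mpe": float("nan"), "ef": float("nan"), "fp": float("nan")}
    return pd.DataFrame(rows).T[["mpe", "ef", "fp"]]


def ci_coverage(
    truth: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    min_abundance: float = 1.0,
) -> float:
    """Percent of entries with truth >= min_abundance whose truth lies inside
    [lower, upper]; NaN when no entry is eligible."""
    truth = np.asarray(truth, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if np.any(lower > upper):
        raise ValueError("malformed intervals")
    ok = truth >= min_abundance
    if not np.any(ok):
        return float("nan")
    inside = (truth[ok] >= lower[ok]) & (truth[ok] <= upper[ok])
    return float(inside.mean() * 100.0)


def mappability(
    ts: TranscriptSet, read_len: int = 35, max_mismatch: int = 2
) -> tuple[np.ndarray, dict]:
    """Per-isoform fraction of its read-length windows that align only within
    the isoform's own gene (full-read matching at the mismatch budget);
    per-gene value is the mean over member isoforms. Transcripts shorter than
    read_len get NaN.
    """
    from .aligner import SeedIndex

    index = SeedIndex.for_transcripts(ts)
    iso = np.full(len(ts), np.nan)
    gene_of = {t.id: t.gene_id for t in ts}
    for i, t in enumerate(ts):
        L = t.length
        if L < read_len:
            continue
        own_gene = t.gene_id
        n_win = L - read_len + 1
        good = 0
        for p in range(n_win):
            window = t.sequence[p : p + read_len]
            hits, _ = index.find(window, seed_length=read_len, max_mismatch=max_mismatch)
            if all(gene_of[ts[h[0]].id] == own_gene for h in hits):
                good += 1
        iso[i] = good / n_win
    gene = {}
    for g, members in ts.gene_map.items():
        vals = [iso[ts.index_of(m)] for m in members]
        vals = [v for v in vals if not np.isnan(v)]
        gene[g] = float(np.mean(vals)) if vals else float("nan")
    return iso, gene
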