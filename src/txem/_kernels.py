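"""Numba-compiled inner loops: seed verification, brute-force scanning, and the
collapsed Gibbs sweep. Everything here operates on plain numpy arrays."""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def verify_seed(ref_codes, starts, seed_codes, max_mm):
    """For each global start position, does ref[start:start+len(seed)] match the
    seed with <= max_mm mismatches? N (code 4) never matches."""
    out = np.zeros(starts.size, dtype=np.bool_)
    L = seed_codes.size
    for i in range(starts.size):
        p = starts[i]
        mm = 0
        ok = True
        for j in range(L):
            r = ref_codes[p + j]
            q = seed_codes[j]
            if r != q or r == 4:
                mm += 1
                if mm > max_mm:
                    ok = False
                    break
        out[i] = ok
    return out


@njit(cache=False)
def brute_scan(ref_codes, offsets, seed_codes, read_len, max_mm):
    """Exhaustive scan: all global positions where the seed matches with
    <= max_mm mismatches and a read of read_len fits inside one transcript."""
    hits = []
    L = seed_codes.size
    for t in range(offsets.size - 1):
        lo, hi = offsets[t], offsets[t + 1]
        for p in range(lo, hi - read_len + 1):
            mm = 0
            ok = True
            for j in range(L):
                r = ref_codes[p + j]
                q = seed_codes[j]
                if r != q or r == 4:
                    mm += 1
                    if mm > max_mm:
                        ok = False
                        break
            if ok:
                hits.append(p)
    return np.array(hits, dtype=np.int64)


@njit(cache=False)
def em_theta_iterations(
    indptr, comp, weight, theta, m_inv, n_components,
    max_iters, rel_tol, theta_min,
):
    """theta-only EM iterations (auxiliary parameters fixed).

    Runs until convergence (every theta_i >= theta_min moves by < rel_tol
    relative) or max_iters. Returns (theta, iterations_done, converged).
    """
    n_slots = weight.size
    a = np.empty(n_slots)
    counts = np.empty(n_components)
    it = 0
    converged = False
    while it < max_iters:
        it += 1
        for k in range(n_slots):
            a[k] = theta[comp[k]] * weight[k]
        # per-read normalization and count accumulation
        for c in range(n_components):
            counts[c] = 0.0
        n_reads = indptr.size - 1
        for n in range(n_reads):
            s = 0.0
            for k in range(indptr[n], indptr[n + 1]):
                s += a[k]
            if s <= 0.0:
                return theta, it, False
            inv = 1.0 / s
            for k in range(indptr[n], indptr[n + 1]):
                counts[comp[k]] += a[k] * inv
        total = counts[0]
        for c in range(1, n_components):
            counts[c] *= m_inv[c - 1]
            total += counts[c]
        ok = True
        for c in range(n_components):
            new = counts[c] / total
            if theta[c] >= theta_min:
                if abs(new - theta[c]) > rel_tol * theta[c]:
                    ok = False
            theta[c] = new
        if ok:
            converged = True
            break
    return theta, it, converged


@njit(cache=False)
def gibbs_sweeps(
    indptr,
    comp,
    weight,
    assign,
    counts,
    alpha,
    n_burn,
    n_keep,
    thin,
    seed,
):
    """Collapsed Gibbs sweeps over read assignments.

    comp[k] is the theta-vector component (0 = noise, i>=1 = transcript) of
    candidate k; weight[k] its model weight (per-read rescaled; the noise
    outcome is included as an ordinary candidate with comp 0). assign holds
    each read's current candidate index into the flat arrays. counts (length
    M+1) must agree with assign on entry. After burn-in, one count vector is
    recorded every `thin` sweeps until n_keep are collected.
    """
    np.random.seed(seed)
    n_reads = indptr.size - 1
    out = np.zeros((n_keep, counts.size), dtype=np.int64)
    for sweep in range(n_burn + n_keep * thin):
        for n in range(n_reads):
            lo = indptr[n]
            hi = indptr[n + 1]
            counts[comp[assign[n]]] -= 1
            total = 0.0
            for k in range(lo, hi):
                total += (alpha + counts[comp[k]]) * weight[k]
            u = np.random.random() * total
            acc = 0.0
            pick = hi - 1
            for k in range(lo, hi):
                acc += (alpha + counts[comp[k]]) * weight[k]
                if u < acc:
                    pick = k
                    break
            assign[n] = pick
            counts[comp[pick]] += 1
        if sweep >= n_burn and (sweep - n_burn) % thin == thin - 1:
            out[(sweep - n_burn) // thin] = counts
    return out
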