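"""Built-in all-hits seed aligner (stands in for an external aligner such as
Bowtie in self-contained runs): report every placement whose first
``seed_length`` bases match with at most ``max_mismatch`` mismatches.

The index stores every 8-mer of the reference in a sorted key array; a query
seed with <= k mismatches must contain an exact 8-mer at one of k+1 disjoint
interval starts (pigeonhole), so candidate positions come from k+1 exact
lookups and are then verified. Short seeds fall back to an exhaustive scan.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from ._kernels import brute_scan, verify_seed
from .readsio import Alignment, AlignmentSet, ReadRecord, filter_reads, is_polya_like
from .reference import TranscriptSet, encode_seq, revcomp

PART_LEN = 8
_POW4 = 4 ** np.arange(PART_LEN - 1, -1, -1, dtype=np.int64)


class SeedIndex:
    """Sorted 8-mer index over a transcript set (forward strand)."""

    def __init__(self, ts: TranscriptSet):
        self.ts = ts
        self.codes, self.offsets = ts.encoded()
        n = self.codes.size
        if n >= PART_LEN:
            win = np.lib.stride_tricks.sliding_window_view(self.codes, PART_LEN)
            keys = win.astype(np.int64) @ _POW4
            valid = ~np.any(win == 4, axis=1)
            # window must not cross a transcript boundary
            pos = np.arange(win.shape[0])
            tid = np.searchsorted(self.offsets, pos, side="right") - 1
            valid &= pos + PART_LEN <= self.offsets[tid + 1]
            pos = pos[valid]
            keys = keys[valid]
            order = np.lexsort((pos, keys))
            self._keys = keys[order]
            self._pos = pos[order]
        else:
            self._keys = np.empty(0, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)

    @classmethod
    def for_transcripts(cls, ts: TranscriptSet) -> "SeedIndex":
        if ts._seed_index is None:
            ts._seed_index = cls(ts)
        return ts._seed_index

    def _part_hits(self, key: int) -> np.ndarray:
        lo = np.searchsorted(self._keys, key, side="left")
        hi = np.searchsorted(self._keys, key, side="right")
        return self._pos[lo:hi]

    def _find_one_orientation(
        self, qcodes: np.ndarray, seed_length: int, max_mismatch: int,
        read_len: int, budget: Optional[int],
    ) -> tuple[list[tuple[int, int]], bool]:
        """Hits as (tid, local_pos); True when the hit budget was exhausted."""
        seed = qcodes[:seed_length]
        if seed_length < PART_LEN * (max_mismatch + 1):
            starts = brute_scan(self.codes, self.offsets, seed, read_len, max_mismatch)
            cand = starts
        else:
            k1 = max_mismatch + 1
            parts = [(j * seed_length) // k1 for j in range(k1)]
            cands = []
            for off in parts:
                part = seed[off : off + PART_LEN]
                if np.any(part == 4):
                    continue  # a part containing N can never be exact
                key = int(part.astype(np.int64) @ _POW4)
                cands.append(self._part_hits(key) - off)
            if not cands:
                return [], False
            cand = np.unique(np.concatenate(cands))
            tid = np.searchsorted(self.offsets, cand, side="right") - 1
            ok = (cand >= 0) & (cand >= self.offsets[np.maximum(tid, 0)])
            ok &= cand + read_len <= self.offsets[np.minimum(tid, len(self.ts) - 1) + 1]
            cand = cand[ok]
            if seed_length > PART_LEN or max_mismatch > 0:
                pass  # verification below
        hits: list[tuple[int, int]] = []
        for chunk_start in range(0, cand.size, 1024):
            chunk = cand[chunk_start : chunk_start + 1024]
            good = chunk if seed_length < PART_LEN * (max_mismatch + 1) else chunk[
                verify_seed(self.codes, chunk, seed, max_mismatch)
            ]
            for p in good:
                t = int(np.searchsorted(self.offsets, p, side="right") - 1)
                hits.append((t, int(p - self.offsets[t])))
                if budget is not None and len(hits) >= budget:
                    return hits, True
        return hits, False

    def find(
        self,
        seq: str,
        seed_length: int = 25,
        max_mismatch: int = 2,
        max_hits: Optional[int] = None,
    ) -> tuple[list[tuple[int, int, bool]], bool]:
        """All (tindex, pos, reverse) placements of a read; second element is
        True when enumeration stopped at max_hits (count is then a lower bound)."""
        read_len = len(seq)
        seed_length = min(seed_length, read_len)
        out: list[tuple[int, int, bool]] = []
        capped = False
        for rev in (False, True):
            q = revcomp(seq) if rev else seq
            budget = None if max_hits is None else max_hits - len(out)
            hits, hit_cap = self._find_one_orientation(
                encode_seq(q), seed_length, max_mismatch, read_len, budget
            )
            out.extend((t, p, rev) for t, p in hits)
            if hit_cap:
                capped = True
                break
        if not capped:
            out.sort(key=lambda h: (h[0], h[1], h[2]))
        return out, capped


def enumerate_alignments(
    read: ReadRecord,
    ts: TranscriptSet,
    seed_length: int = 25,
    max_mismatch: int = 2,
    max_hits: Optional[int] = None,
    max_fragment: int = 1000,
) -> list[Alignment]:
    """Exhaustively enumerate candidate alignments of a read (pair).

    SE: every seed placement in either orientation. PE: mate placements joined
    on the same transcript in FR geometry with fragment length between the
    longer mate and ``max_fragment``. Deterministic order: transcript index,
    then position, forward before reverse.
    """
    index = SeedIndex.for_transcripts(ts)
    if not read.paired:
        hits, _ = index.find(read.seq1, seed_length, max_mismatch, max_hits)
        return [Alignment(0, t, p, reverse=rev) for t, p, rev in hits]
    l1, l2 = len(read.seq1), len(read.seq2)
    h1, _ = index.find(read.seq1, seed_length, max_mismatch)
    h2, _ = index.find(read.seq2, seed_length, max_mismatch)
    by_t: dict[tuple[int, bool], list[int]] = {}
    for t, p, rev in h2:
        by_t.setdefault((t, rev), []).append(p)
    out = []
    for t, p1, rev1 in h1:
        if rev1:
            # mate1 antisense at the fragment's right end; mate2 sense at its left
            for p2 in by_t.get((t, False), ()):
                frag = p1 + l1 - p2
                if max(l1, l2) <= frag <= max_fragment:
                    out.append(Alignment(0, t, p2, reverse=True, fragment_length=frag))
        else:
            for p2 in by_t.get((t, True), ()):
                frag = p2 + l2 - p1
                if max(l1, l2) <= frag <= max_fragment:
                    out.append(Alignment(0, t, p1, reverse=False, fragment_length=frag))
    out.sort(key=lambda a: (a.tindex, a.pos, a.reverse))
    if max_hits is not None:
        out = out[:max_hits]
    return out


def align_reads(
    reads: list[ReadRecord],
    ts: TranscriptSet,
    seed_length: int = 25,
    max_mismatch: int = 2,
    max_alignments: int = 200,
    polya_fraction: float = 0.9,
    max_fragment: int = 1000,
) -> AlignmentSet:
    """Align a batch of reads with the built-in aligner and apply the filters.

    Poly(A)-like reads are flagged without being aligned; enumeration for the
    rest stops at max_alignments candidates (such reads are flagged anyway, and
    counts below the cap are exact, so the filter boundary is unaffected).
    """
    index = SeedIndex.for_transcripts(ts)
    candidates: list[list[Alignment]] = []
    flags: list[Optional[str]] = []
    for n, read in enumerate(reads):
        if is_polya_like(read, polya_fraction):
            candidates.append([])
            flags.append("polya_like")
            continue
        alns = enumerate_alignments(
            read, ts, seed_length, max_mismatch,
            max_hits=max_alignments, max_fragment=max_fragment,
        )
        alns = [
            Alignment(n, a.tindex, a.pos, a.reverse, a.fragment_length) for a in alns
        ]
        candidates.append(alns)
        flags.append("too_many_alignments" if len(alns) >= max_alignments else None)
    return AlignmentSet(reads=list(reads), candidates=candidates, filtered=flags)


def window_survival(
    ts: TranscriptSet,
    read_len: int,
    seed_length: int = 25,
    max_mismatch: int = 2,
    max_alignments: int = 200,
    polya_fraction: float = 0.9,
) -> list[np.ndarray]:
    """Per transcript: for every read window [p, p+read_len), would an
    error-free read from it survive the filters?

    A window's read and its reverse complement have identical total hit counts
    and the poly(A) rule is A/T symmetric, so survival depends only on the
    window. Hit counting is only performed for windows whose pigeonhole part
    lookups admit >= max_alignments candidates (an upper bound on the true
    count); all others trivially pass the multiplicity filter.
    """
    cache = getattr(ts, "_survival_cache", None)
    if cache is None:
        cache = ts._survival_cache = {}
    key = (read_len, seed_length, max_mismatch, max_alignments, polya_fraction)
    if key in cache:
        return cache[key]
    index = SeedIndex.for_transcripts(ts)
    codes, offsets = ts.encoded()
    k1 = max_mismatch + 1
    seed_length = min(seed_length, read_len)
    use_parts = seed_length >= PART_LEN * k1
    out = []
    athresh = polya_fraction * read_len
    for t in range(len(ts)):
        lo, hi = offsets[t], offsets[t + 1]
        length = hi - lo
        n_win = length - read_len + 1
        if n_win <= 0:
            out.append(np.zeros(0, dtype=bool))
            continue
        tcodes = codes[lo:hi]
        # vectorized poly(A)/poly(T) rule on windows
        a_cum = np.concatenate([[0], np.cumsum(tcodes == 0)])
        t_cum = np.concatenate([[0], np.cumsum(tcodes == 3)])
        a_in = a_cum[read_len:] - a_cum[:-read_len]
        t_in = t_cum[read_len:] - t_cum[:-read_len]
        polya = (a_in >= athresh) | (t_in >= athresh)
        survive = ~polya
        check = np.flatnonzero(survive)
        if use_parts and check.size:
            # cheap upper bound on hit counts from exact part-lookup sizes
            ub = np.zeros(check.size, dtype=np.int64)
            for rev in (False, True):
                wcodes = (3 - tcodes) if rev else tcodes  # complement
                for off in [(j * seed_length) // k1 for j in range(k1)]:
                    keys = np.zeros(check.size, dtype=np.int64)
                    bad = np.zeros(check.size, dtype=bool)
                    for j in range(PART_LEN):
                        if rev:
                            idx = check + read_len - 1 - (off + j)
                        else:
                            idx = check + off + j
                        c = wcodes[idx].astype(np.int64)
                        bad |= c > 3
                        keys = keys * 4 + np.minimum(c, 3)
                    lo_i = np.searchsorted(index._keys, keys, side="left")
                    hi_i = np.searchsorted(index._keys, keys, side="right")
                    ub += np.where(bad, 0, hi_i - lo_i)
            check = check[ub >= max_alignments]
        seqs = ts[t].sequence
        for p in check:
            window = seqs[p : p + read_len]
            hits, capped = index.find(
                window, seed_length, max_mismatch, max_hits=max_alignments
            )
            if capped or len(hits) >= max_alignments:
                survive[p] = False
        out.append(survive)
    cache[key] = out
    return out
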