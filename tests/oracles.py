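"""Independent brute-force oracles used to validate the run-length pipeline.

Everything here works on dense per-base numpy arrays or naive all-pairs
scans, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def dense_track(track, chrom):
    """Materialize one chromosome of a CoverageTrack as a per-base array."""
    return track.to_dense(chrom)


def dense_from_reads(reads, length, policy):
    arr = np.zeros(length)
    for start, end, n_hits in reads:
        if policy == "unique_only":
            if n_hits != 1:
                continue
            w = 1.0
        else:
            w = 1.0 / n_hits
        arr[start:end] += w
    return arr


def dense_integral(arr, a: float, b: float) -> float:
    """Integral of a per-base-constant array over fractional [a, b)."""
    total = 0.0
    ia, ib = int(np.floor(a)), int(np.ceil(b))
    for base in range(ia, ib):
        lo = max(a, base)
        hi = min(b, base + 1)
        if hi > lo:
            total += arr[base] * (hi - lo)
    return total


def dense_mean(arr, a: float, b: float) -> float:
    return dense_integral(arr, a, b) / (b - a)


def union_bp(intervals) -> int:
    """Per-base union size via a boolean mask."""
    if not intervals:
        return 0
    hi = max(e for _, e in intervals)
    mask = np.zeros(hi, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())


def partition_per_base(seg_start, seg_end, repeat_intervals):
    """Label each base of a segment R/NR; return merged sub-segments."""
    mask = np.zeros(seg_end - seg_start, dtype=bool)
    for s, e in repeat_intervals:
        lo, hi = max(s, seg_start), min(e, seg_end)
        if hi > lo:
            mask[lo - seg_start : hi - seg_start] = True
    pieces = []
    i = 0
    while i < len(mask):
        j = i
        while j < len(mask) and mask[j] == mask[i]:
            j += 1
        pieces.append((seg_start + i, seg_start + j, "R" if mask[i] else "NR"))
        i = j
    return pieces


def assign_peak_bruteforce(peak, copies):
    """(copy_id or None) under the >=50%-of-peak largest-overlap rule.

    ``copies`` is a list of (start, end, copy_id) on the peak's chromosome.
    """
    p_start, p_end = peak
    plen = p_end - p_start
    best = None
    for s, e, cid in copies:
        ov = min(e, p_end) - max(s, p_start)
        if ov > 0 and 2 * ov >= plen:
            key = (-ov, s, cid)
            if best is None or key < best[0]:
                best = (key, cid)
    return None if best is None else best[1]


def count_read_bruteforce(read, copies):
    """Copy receiving the read (largest overlap >= 1 bp, same tie-break)."""
    r_start, r_end = read
    best = None
    for s, e, cid in copies:
        ov = min(e, r_end) - max(s, r_start)
        if ov >= 1:
            key = (-ov, s, cid)
            if best is None or key < best[0]:
                best = (key, cid)
    return None if best is None else best[1]


def tandem_bruteforce(focal, context, window_bp):
    """O(n^2) all-pairs tandem labels.

    ``focal``/``context``: lists of (chrom, start, end, copy_id).
    """
    labels = {}
    for chrom, fs, fe, fid in focal:
        has5 = has3 = False
        for c_chrom, s, e, cid in context:
            if c_chrom != chrom or cid == fid:
                continue
            if s < fs and fs - e <= window_bp:
                has5 = True
            if e > fe and s - fe <= window_bp:
                has3 = True
        labels[fid] = (
            "internal" if has5 and has3 else "last" if has5 else "first" if has3 else "alone"
        )
    return labels


def signed_rank_exact_p(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors.

    Assumes no zeros and no tied |diffs|.  p = 2 * min(P(W+ <= w), P(W+ >= w)),
    capped at 1, where W+ is the positive-rank sum.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
    w_obs = ranks[diffs > 0].sum()
    total = 0
    le = ge = 0
    for mask in range(2 ** n):
        w = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
        total += 1
        if w <= w_obs:
            le += 1
        if w >= w_obs:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def mann_whitney_exact_p(a, b) -> float:
    """Two-sided exact U-test p by enumerating rank assignments (no ties)."""
    from itertools import combinations

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    combined = np.concatenate([a, b])
    order = np.argsort(combined)
    ranks = np.empty(n1 + n2)
    ranks[order] = np.arange(1, n1 + n2 + 1)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    all_ranks = np.arange(1, n1 + n2 + 1)
    le = ge = total = 0
    for positions in combinations(range(n1 + n2), n1):
        u = all_ranks[list(positions)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if u <= u_obs:
            le += 1
        if u >= u_obs:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)
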