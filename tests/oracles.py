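"""Independent reference implementations used as test oracles.

These deliberately re-derive results by brute force (explicit enumeration
or naive recomputation) so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np

NEG = (-(10**9), 0, 0)


def exhaustive_alignment(a: str, b: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    """Best (score, -gap_runs, -mismatches) over all alignments of a vs b
    with one-sided free terminal gaps, by recursive enumeration of
    alignment columns (memoized on the suffix state).

    A leading overhang may sit on one sequence only (start positions with
    i0 == 0 or j0 == 0) and likewise a trailing overhang (stop allowed
    once either sequence is exhausted).  Alignments with terminal gap
    columns on one side are dominated by the corresponding stopped
    alignment, so this enumeration covers the optimum.
    """
    la, lb = len(a), len(b)
    memo: dict = {}

    def F(i: int, j: int, last: str):
        key = (i, j, last)
        if key in memo:
            return memo[key]
        # stopping leaves the rest of ONE sequence as a free overhang
        best = (0, 0, 0) if (i == la or j == lb) else NEG
        if i < la and j < lb:
            ds, dm = (match, 0) if a[i] == b[j] else (mismatch, 1)
            s, r, m = F(i + 1, j + 1, "M")
            cand = (s + ds, r, m - dm)
            if cand > best:
                best = cand
        if i < la:  # column (a[i], -)
            pen = gap_extend if last == "X" else gap_open
            run = 0 if last == "X" else -1
            s, r, m = F(i + 1, j, "X")
            cand = (s + pen, r + run, m)
            if cand > best:
                best = cand
        if j < lb:  # column (-, b[j])
            pen = gap_extend if last == "Y" else gap_open
            run = 0 if last == "Y" else -1
            s, r, m = F(i, j + 1, "Y")
            cand = (s + pen, r + run, m)
            if cand > best:
                best = cand
        memo[key] = best
        return best

    overall = NEG
    for i0 in range(la):
        for j0 in range(lb):
            if i0 != 0 and j0 != 0:
                continue  # a leading overhang sits on one sequence only
            ds, dm = (match, 0) if a[i0] == b[j0] else (mismatch, 1)
            s, r, m = F(i0 + 1, j0 + 1, "M")
            cand = (s + ds, r, m - dm)
            if cand > overall:
                overall = cand
    score, neg_runs, neg_mism = overall
    n_diff = -neg_runs - neg_mism
    return score, n_diff


def brute_average_linkage(d: np.ndarray, cutoff: float) -> list[frozenset]:
    """Naive agglomerative average linkage: recompute every between-cluster
    mean at every step; merge the smallest until it exceeds the cutoff."""
    clusters: list[set[int]] = [{i} for i in range(d.shape[0])]
    while len(clusters) > 1:
        best = None
        best_pair = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                vals = [d[i, j] for i in clusters[x] for j in clusters[y]]
                avg = float(np.mean(vals))
                if best is None or avg < best:
                    best = avg
                    best_pair = (x, y)
        if best is None or best > cutoff:
            break
        x, y = best_pair
        clusters[x] |= clusters[y]
        del clusters[y]
    return sorted((frozenset(c) for c in clusters), key=lambda c: sorted(c))


def ks_statistic(x, y) -> float:
    """Max ECDF difference over the pooled support, by direct scan."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    support = np.concatenate([x, y])
    dmax = 0.0
    for v in support:
        fx = np.searchsorted(x, v, side="right") / x.size
        fy = np.searchsorted(y, v, side="right") / y.size
        dmax = max(dmax, abs(fx - fy))
    return dmax
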