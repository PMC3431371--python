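"""Implied per-nucleotide error rates between raw and corrected reads.

A denoiser does not report which bases it changed; the "implied error rate"
is recovered after the fact by aligning each read before and after
correction and counting differences.  The distance convention used
throughout the package is:

* global pairwise alignment with affine gap costs (+1 match, -1 mismatch,
  -2 gap open, -1 gap extend) in which terminal gaps are free and ignored,
* ``n_differences`` = mismatched columns + number of *internal* gap runs
  (a contiguous run of gap columns counts once, whatever its length),
* the denominator is the length of the shorter sequence.

Two engines implement the convention: an exact dynamic program
(:func:`implied_distance`, used for small inputs and as the reference) and
a fast engine (:func:`fast_pair_distance`) built on Hamming screening plus
edlib alignment paths, used at pipeline scale.  The two are held together
by property tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

try:
    import edlib as _edlib
except ImportError:  # pragma: no cover - edlib is a hard dependency
    _edlib = None

__all__ = [
    "AlignmentParams",
    "ImpliedDistance",
    "ErrorProfile",
    "implied_distance",
    "fast_pair_distance",
    "error_profile",
    "regress",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for pairwise alignment; terminal gaps are always free."""

    match_reward: int = 1
    mismatch_penalty: int = -1
    gap_open_penalty: int = -2
    gap_extend_penalty: int = -1

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if max(self.mismatch_penalty, self.gap_open_penalty, self.gap_extend_penalty) >= 0:
            raise ValueError("penalties must be negative")


@dataclass(frozen=True)
class ImpliedDistance:
    """Distance between an input and an output sequence."""

    value: float
    n_differences: int
    denominator: int


_NEG = (-(10 ** 9), 0, 0)


def implied_distance(
    seq_in: str, seq_out: str, params: AlignmentParams | None = None
) -> ImpliedDistance:
    """Exact implied distance between two sequences.

    The alignment maximizes score; ties are broken toward fewer internal
    gap runs, then fewer mismatched columns, which pins down the reported
    difference count deterministically.

    Raises
    ------
    ValueError
        If either sequence is empty.
    """
    if not seq_in or not seq_out:
        raise ValueError("implied_distance requires two non-empty sequences")
    params = params or AlignmentParams()
    a, b = seq_in, seq_out
    m, n = len(a), len(b)
    ma, mi = params.match_reward, params.mismatch_penalty
    go, ge = params.gap_open_penalty, params.gap_extend_penalty

    # Cell values are lexicographic tuples (score, -gap_runs, -mismatches).
    # M[i][j]: best alignment whose last column aligns a[i-1] with b[j-1];
    # X: last column is (a[i-1], -); Y: last column is (-, b[j-1]).
    # Terminal gaps are free on one side at each end: an alignment may
    # start fresh only on the first row/column and ends on the last row
    # or column (the other sequence's overhang is ignored).
    M = [[_NEG] * (n + 1) for _ in range(m + 1)]
    X = [[_NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[_NEG] * (n + 1) for _ in range(m + 1)]
    best = _NEG
    start = (0, 0, 0)
    for i in range(1, m + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, n + 1):
            if ai == b[j - 1]:
                ds, dm = ma, 0
            else:
                ds, dm = mi, 1
            prev = Mp[j - 1]
            if Xp[j - 1] > prev:
                prev = Xp[j - 1]
            if Yp[j - 1] > prev:
                prev = Yp[j - 1]
            if (i == 1 or j == 1) and start > prev:
                prev = start
            cell = (prev[0] + ds, prev[1], prev[2] - dm)
            Mi[j] = cell
            if (i == m or j == n) and cell > best:
                best = cell
            # gap in b (consume a[i-1])
            xo = (Mp[j][0] + go, Mp[j][1] - 1, Mp[j][2])
            xs = (Yp[j][0] + go, Yp[j][1] - 1, Yp[j][2])
            xe = (Xp[j][0] + ge, Xp[j][1], Xp[j][2])
            Xi[j] = max(xo, xs, xe)
            # gap in a (consume b[j-1])
            yo = (Mi[j - 1][0] + go, Mi[j - 1][1] - 1, Mi[j - 1][2])
            ys = (Xi[j - 1][0] + go, Xi[j - 1][1] - 1, Xi[j - 1][2])
            ye = (Yi[j - 1][0] + ge, Yi[j - 1][1], Yi[j - 1][2])
            Yi[j] = max(yo, ys, ye)
    n_diff = -best[1] - best[2]
    denom = min(m, n)
    return ImpliedDistance(value=n_diff / denom, n_differences=n_diff, denominator=denom)


# ---------------------------------------------------------------------------
# fast engine
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_differences(cigar: str) -> int:
    """Mismatches + internal gap runs from an extended CIGAR string.

    Leading and trailing *gap* runs are terminal and ignored; mismatched
    columns count wherever they sit.
    """
    ops = [(int(k), op) for k, op in _CIGAR_RE.findall(cigar)]
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    n = 0
    for k, op in ops:
        if op in "XM":
            n += k
        elif op in "ID":
            n += 1  # one run, whatever its length
    return n


def fast_pair_distance(a: str, b: str, gap_suspect_at: int = 7) -> ImpliedDistance:
    """Implied distance via the fast engine.

    Equal-length pairs are first measured by Hamming distance (the
    diagonal alignment).  If that count reaches ``gap_suspect_at`` — or
    the lengths differ — the pair may be related by an indel, and an
    edlib alignment path is converted to the package distance convention
    instead.
    """
    if not a or not b:
        raise ValueError("fast_pair_distance requires two non-empty sequences")
    denom = min(len(a), len(b))
    n_sub = None
    if len(a) == len(b):
        diffs = np.frombuffer(a.encode(), np.uint8) != np.frombuffer(b.encode(), np.uint8)
        n_sub = int(diffs.sum())
        if n_sub == 0:
            return ImpliedDistance(0.0, 0, denom)
        if n_sub < gap_suspect_at:
            return ImpliedDistance(n_sub / denom, n_sub, denom)
    n_ed = _edlib_convention_differences(a, b)
    if n_sub is not None and n_sub <= n_ed:
        return ImpliedDistance(n_sub / denom, n_sub, denom)
    return ImpliedDistance(n_ed / denom, n_ed, denom)


def _edlib_convention_differences(a: str, b: str) -> int:
    """Alignment differences from an edlib path, terminal gaps free."""
    if _edlib is None:  # pragma: no cover
        raise RuntimeError("edlib is required for the fast distance engine")
    if len(a) > len(b):
        a, b = b, a
    mode = "NW" if len(a) == len(b) else "HW"
    res = _edlib.align(a, b, mode=mode, task="path")
    return _cigar_differences(res["cigar"])


# ---------------------------------------------------------------------------
# per-sample aggregation
# ---------------------------------------------------------------------------


@dataclass
class ErrorProfile:
    """Implied-error summary, per sample and pooled.

    ``overall_rate`` pools total differences over total aligned bases
    (the sum of per-read denominators); ``mean_distance_changed`` averages
    the per-read distance over reads the corrector actually changed.
    """

    per_sample: "pd.DataFrame"
    fraction_unchanged: float
    mean_distance_changed: float
    corrections_per_sequence: float
    overall_rate: float
    n_reads: int


def error_profile(
    db,
    raw_reads: dict[str, str],
    corrected_reads: dict[str, str],
    params: AlignmentParams | None = None,
    sample_of: dict[str, str] | None = None,
    engine: str = "fast",
):
    """Implied error rates between raw reads and their corrected versions.

    Parameters
    ----------
    db
        A :class:`~denoise_impact.provenance.ProvenanceDB` (or any object
        with ``kept_ids(pipeline)`` returning raw read ids kept by the
        corrector arm) used to restrict the comparison to 1:1 kept reads;
        pass ``None`` to compare every id present in both dicts.
    raw_reads, corrected_reads
        Mapping read_id -> sequence.  Corrected reads must be 1:1 with
        kept raw reads.
    sample_of
        Mapping read_id -> sample_id.  Samples with no kept reads are
        reported as missing (absent rows), never as zero.
    engine
        ``"fast"`` (default) or ``"exact"`` for the full dynamic program.
    """
    import pandas as pd

    if db is not None:
        ids = [r for r in db.kept_ids("B") if r in corrected_reads]
    else:
        ids = [r for r in corrected_reads if r in raw_reads]
    missing = [r for r in corrected_reads if r not in raw_reads]
    if missing:
        raise ValueError(f"corrected reads with unknown raw id: {missing[:5]}")
    dist = implied_distance if engine == "exact" else fast_pair_distance
    rows = []
    for rid in ids:
        raw, cor = raw_reads[rid], corrected_reads[rid]
        if raw == cor:
            d = ImpliedDistance(0.0, 0, len(raw))
        else:
            d = dist(raw, cor) if engine == "fast" else dist(raw, cor, params)
        rows.append((rid, sample_of.get(rid) if sample_of else "all", d.n_differences, d.denominator, d.value))
    df = pd.DataFrame(rows, columns=["read_id", "sample_id", "n_diff", "denom", "distance"])
    per_sample = (
        df.groupby("sample_id")
        .apply(_sample_summary, include_groups=False)
        .reset_index()
        if len(df)
        else pd.DataFrame(columns=["sample_id", "n_reads", "fraction_unchanged", "mean_distance_changed", "corrections_per_sequence", "overall_rate"])
    )
    changed = df[df.n_diff > 0]
    return ErrorProfile(
        per_sample=per_sample,
        fraction_unchanged=float((df.n_diff == 0).mean()) if len(df) else float("nan"),
        mean_distance_changed=float(changed.distance.mean()) if len(changed) else 0.0,
        corrections_per_sequence=float(df.n_diff.mean()) if len(df) else float("nan"),
        overall_rate=float(df.n_diff.sum() / df.denom.sum()) if len(df) else float("nan"),
        n_reads=len(df),
    )


def _sample_summary(g):
    import pandas as pd

    changed = g[g.n_diff > 0]
    return pd.Series(
        {
            "n_reads": len(g),
            "fraction_unchanged": (g.n_diff == 0).mean(),
            "mean_distance_changed": changed.distance.mean() if len(changed) else 0.0,
            "corrections_per_sequence": g.n_diff.mean(),
            "overall_rate": g.n_diff.sum() / g.denom.sum(),
        }
    )


def regress(x: Sequence[float], y: Sequence[float]):
    """Ordinary least squares of per-sample error rate on a covariate.

    Returns (slope, r_squared, p_value); the p-value is the two-sided test
    of zero slope.  Requires >= 3 paired observations and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("regress requires >=3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; slope is not identifiable")
    res = _stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)
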