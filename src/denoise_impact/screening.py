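"""Quality screening, preclustering, chimera flagging, and a stand-in denoiser.

Two processing arms are modelled.  The *standard* arm culls reads on the
classic quality criteria (5' primer match, minimum length, ambiguous
bases, homopolymer runs, average quality score, alignment identity to a
reference set), trims survivors to a fixed length, merges single-base
variants into their more abundant neighbor (preclustering), and flags
chimeras.  The *corrector* arm (:func:`mock_denoise`) culls on primer and
a flow-length proxy, then rewrites each surviving read to the consensus of
its abundance group — a deliberately simple consensus corrector standing
in for flowgram-likelihood denoisers, which are out of scope here.

Every operation reports per-read verdicts so the provenance of each raw
read through both arms can be reconstructed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._util import max_run_length, seq_to_bytes
from .otu import UniqueSequenceSet, Unique, dereplicate, _kmer_matrix
from .synthetic import RawReadSet

try:
    import edlib as _edlib
except ImportError:  # pragma: no cover
    _edlib = None

__all__ = [
    "ScreeningCriteria",
    "ScreenOutcome",
    "DenoiserParams",
    "screen_reads",
    "trim_reads",
    "precluster",
    "flag_chimeras",
    "mock_denoise",
    "best_reference_identity",
]

CRITERIA_ORDER = ("primer", "length", "ambiguous", "homopolymer", "quality", "alignment")


@dataclass(frozen=True)
class ScreeningCriteria:
    """Standard-arm screening thresholds.

    A read fails "length" if its post-primer length is below
    ``min_length``; "homopolymer" if it contains a run longer than
    ``max_homopolymer``; "quality" if the mean post-primer quality is
    below ``min_avg_quality``; "alignment" if its identity to the best
    reference falls below ``min_reference_identity``.  Trimming to
    ``trim_length`` happens after screening.
    """

    primer: str
    min_length: int = 120
    max_ambiguous: int = 0
    max_homopolymer: int = 6
    min_avg_quality: float | None = 25.0
    min_reference_identity: float | None = 0.75
    trim_length: int = 150

    def __post_init__(self) -> None:
        if self.min_length <= 0 or self.max_homopolymer <= 0 or self.trim_length <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ScreenOutcome:
    """Per-read verdicts: kept iff no criterion failed; every input read
    appears exactly once and multi-criterion failures are all recorded."""

    failed: dict[str, tuple[str, ...]]  # read_id -> failed criteria (possibly empty)

    def __post_init__(self) -> None:
        self.kept = [r for r, f in self.failed.items() if not f]

    @property
    def n_input(self) -> int:
        return len(self.failed)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def failure_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CRITERIA_ORDER}
        for flags in self.failed.values():
            for c in flags:
                counts[c] = counts.get(c, 0) + 1
        return counts


def best_reference_identity(seqs: Sequence[str], references: Sequence[str], top: int = 2) -> np.ndarray:
    """Identity of each sequence to its best-matching reference.

    Candidate references are shortlisted by shared 8-mers (sparse matrix
    product), then scored by edlib infix alignment; identity is
    1 - dist/len(seq)."""
    if not references:
        raise ValueError("references must be non-empty")
    # identity depends only on the sequence: compute per distinct sequence
    uniq: dict[str, int] = {}
    for s in seqs:
        uniq.setdefault(s, len(uniq))
    useqs = list(uniq)
    S = _kmer_matrix([seq_to_bytes(s) for s in useqs])
    R = _kmer_matrix([seq_to_bytes(r) for r in references])
    RT = R.T.tocsc()
    vals = np.zeros(len(useqs))
    block = 20000
    for start in range(0, len(useqs), block):
        C = (S[start : start + block] @ RT).toarray()
        if C.shape[1] > top:
            ranked = np.argpartition(-C, top, axis=1)[:, :top]
        else:
            ranked = np.tile(np.arange(C.shape[1]), (C.shape[0], 1))
        for i in range(C.shape[0]):
            seq = useqs[start + i]
            best = 0.0
            for j in ranked[i]:
                ref = references[int(j)]
                q, t = (seq, ref) if len(seq) <= len(ref) else (ref, seq)
                dist = _edlib.align(q, t, mode="HW")["editDistance"]
                best = max(best, 1.0 - dist / max(len(seq), 1))
            vals[start + i] = best
    return np.array([vals[uniq[s]] for s in seqs])


def screen_reads(
    reads: RawReadSet,
    criteria: ScreeningCriteria,
    references: Sequence[str] | None = None,
) -> ScreenOutcome:
    """Evaluate every criterion for every read (multi-failures recorded).

    Raises ValueError when a quality criterion is active but a read has no
    quality scores, or when the alignment criterion is active without
    references.
    """
    import re

    np_ = len(criteria.primer)
    if criteria.min_reference_identity is not None:
        if references is None:
            raise ValueError("alignment criterion active but no references given")
        posts = [r.bases[np_:] or "A" for r in reads]
        idents = best_reference_identity(posts, list(references))
    keep_acgt = str.maketrans("", "", "ACGT")
    hp_re = re.compile(r"(.)\1{%d,}" % criteria.max_homopolymer)
    failed: dict[str, tuple[str, ...]] = {}
    for k, r in enumerate(reads):
        flags: list[str] = []
        if not r.bases.startswith(criteria.primer):
            flags.append("primer")
        post = r.bases[np_:]
        if len(post) < criteria.min_length:
            flags.append("length")
        if len(post.translate(keep_acgt)) > criteria.max_ambiguous:
            flags.append("ambiguous")
        if hp_re.search(post):
            flags.append("homopolymer")
        if criteria.min_avg_quality is not None:
            if r.quality is None or len(r.quality) == 0:
                raise ValueError(f"read {r.read_id} has no qualities but a quality criterion is active")
            if float(np.mean(r.quality[np_:])) < criteria.min_avg_quality:
                flags.append("quality")
        if criteria.min_reference_identity is not None:
            if idents[k] < criteria.min_reference_identity:
                flags.append("alignment")
        failed[r.read_id] = tuple(flags)
    return ScreenOutcome(failed=failed)


def trim_reads(kept: Sequence[tuple[str, str]], trim_length: int) -> list[tuple[str, str]]:
    """Truncate each (read_id, sequence) to at most ``trim_length``; order
    is preserved."""
    return [(rid, seq[:trim_length]) for rid, seq in kept]


# ---------------------------------------------------------------------------
# preclustering
# ---------------------------------------------------------------------------

# 31-bit Mersenne modulus keeps all products within int64
_HMOD = (1 << 31) - 1
_HBASE = 131


def _deletion_hashes(seq: str, pows: np.ndarray, invpows: np.ndarray) -> np.ndarray:
    """Rolling hash of every single-deletion variant of seq (vectorized).

    Collisions are possible and harmless: every candidate pair is verified
    with a direct edit-distance-1 check."""
    a = seq_to_bytes(seq).astype(np.int64)
    L = a.size
    # prefix hashes: pre[i] = sum_{j<i} a[j] B^(i-1-j) (mod)
    # = (cumsum of a[j] B^(L-1-j)) * B^(i-L) (mod)
    scaled = (a * pows[L - 1 :: -1]) % _HMOD
    csum = np.cumsum(scaled) % _HMOD
    pre = np.zeros(L + 1, dtype=np.int64)
    pre[1:] = (csum * invpows[L - 1 - np.arange(L)]) % _HMOD
    total = int(pre[L])
    # pre[L] = pre[p+1] * B^(L-p-1) + H(s[p+1:])  (mod)
    p = np.arange(L)
    suf = (total - (pre[p + 1] * pows[L - p - 1]) % _HMOD) % _HMOD
    # hash(s[:p] + s[p+1:]) = pre[p] * B^(L-1-p) + H(s[p+1:])  (mod)
    out = ((pre[p] * pows[L - 1 - p]) % _HMOD + suf) % _HMOD
    return out


def _full_hash(seq: str) -> int:
    acc = 0
    for ch in seq.encode():
        acc = (acc * _HBASE + ch) % _HMOD
    return acc


def _edit1_neighbors(uniques: UniqueSequenceSet) -> list[tuple[int, int]]:
    """Pairs of unique indices at Hamming/edit distance exactly 1."""
    seqs = [u.sequence for u in uniques.uniques]
    n = len(seqs)
    maxlen = max((len(s) for s in seqs), default=0)
    pows = np.ones(maxlen + 2, dtype=np.int64)
    invpows = np.ones(maxlen + 2, dtype=np.int64)
    invb = pow(_HBASE, _HMOD - 2, _HMOD)
    for i in range(1, pows.size):
        pows[i] = (pows[i - 1] * _HBASE) % _HMOD
        invpows[i] = (invpows[i - 1] * invb) % _HMOD
    keys, idxs, kinds = [], [], []  # kind: deletion position, or -1 for full
    for i, s in enumerate(seqs):
        dh = _deletion_hashes(s, pows, invpows)
        keys.append(dh)
        idxs.append(np.full(dh.size, i, dtype=np.int64))
        kinds.append(np.arange(dh.size, dtype=np.int64))
        keys.append(np.array([_full_hash(s)], dtype=np.int64))
        idxs.append(np.array([i], dtype=np.int64))
        kinds.append(np.array([-1], dtype=np.int64))
    key = np.concatenate(keys)
    idx = np.concatenate(idxs)
    kind = np.concatenate(kinds)
    order = np.argsort(key, kind="stable")
    key, idx, kind = key[order], idx[order], kind[order]
    pairs: set[tuple[int, int]] = set()
    bounds = np.flatnonzero(key[1:] != key[:-1]) + 1
    starts = np.concatenate(([0], bounds))
    stops = np.concatenate((bounds, [key.size]))
    for b in np.flatnonzero(stops - starts > 1):
        bucket = list(zip(idx[starts[b] : stops[b]], kind[starts[b] : stops[b]]))
        for a in range(len(bucket)):
            for c in range(a + 1, len(bucket)):
                i1, k1 = bucket[a]
                i2, k2 = bucket[c]
                if i1 == i2:
                    continue
                lo, hi = (int(i1), int(i2)) if i1 < i2 else (int(i2), int(i1))
                if _is_edit1(seqs[lo], seqs[hi], int(k1), int(k2)):
                    pairs.add((lo, hi))
    return sorted(pairs)


def _is_edit1(s: str, t: str, k1: int, k2: int) -> bool:
    if s == t:
        return False
    if len(s) == len(t):
        a, b = seq_to_bytes(s), seq_to_bytes(t)
        return int((a != b).sum()) == 1
    if abs(len(s) - len(t)) != 1:
        return False
    long, short = (s, t) if len(s) > len(t) else (t, s)
    # verify short is a single deletion of long
    i = 0
    while i < len(short) and short[i] == long[i]:
        i += 1
    return short[:i] + long[i] + short[i:] == long or long[:i] + long[i + 1 :] == short


def precluster(uniques: UniqueSequenceSet) -> UniqueSequenceSet:
    """Merge each unique into a more abundant unique at edit distance 1.

    Processing follows descending abundance (ties: the lexicographically
    later representative merges into the earlier); chain merging is
    allowed, so a unique one step from an already-merged variant follows
    it into the same group.  Total member counts are conserved.
    """
    us = uniques.uniques  # already in canonical (count desc, rep asc) order
    n = len(us)
    if n <= 1:
        return uniques
    pairs = _edit1_neighbors(uniques)
    higher: dict[int, list[int]] = {}
    for a, b in pairs:  # a < b in rank order, so a outranks b
        higher.setdefault(b, []).append(a)
    group = list(range(n))

    def find(x: int) -> int:
        while group[x] != x:
            group[x] = group[group[x]]
            x = group[x]
        return x

    for b in range(n):
        cands = higher.get(b)
        if cands:
            group[b] = find(min(cands))
    merged: dict[int, list[int]] = {}
    for i in range(n):
        merged.setdefault(find(i), []).append(i)
    out = []
    for root, members_idx in merged.items():
        members = [m for i in members_idx for m in us[i].members]
        members.sort()
        out.append(
            Unique(us[root].sequence, us[root].representative_id, len(members), members)
        )
    return UniqueSequenceSet(out)


# ---------------------------------------------------------------------------
# chimera flagging
# ---------------------------------------------------------------------------


def flag_chimeras(
    uniques: UniqueSequenceSet,
    references: Sequence[str] | None = None,
    identity: float = 0.99,
    max_parents: int = 300,
    min_side: int = 10,
) -> dict[str, bool]:
    """Two-parent mosaic test: a unique is flagged iff it can be split at
    one breakpoint so each side matches a distinct, more abundant sequence
    at >= ``identity`` while its full-length identity to either parent is
    below ``identity``.

    Parents are the reference sequences when given, otherwise the more
    abundant uniques themselves (self-reference mode, limited to the
    ``max_parents`` most abundant).  Candidates whose length differs from
    every parent are never flagged.
    """
    us = uniques.uniques
    if not us:
        raise ValueError("candidate set is empty")
    flags: dict[str, bool] = {}
    if references is not None:
        parent_seqs = list(references)
        parent_rank_of = None
    else:
        parent_seqs = [u.sequence for u in us[:max_parents]]
        parent_rank_of = True
    by_len: dict[int, list[int]] = {}
    for j, pseq in enumerate(parent_seqs):
        by_len.setdefault(len(pseq), []).append(j)
    parent_mats = {L: np.stack([seq_to_bytes(parent_seqs[j]) for j in idxs]) for L, idxs in by_len.items()}

    for rank, u in enumerate(us):
        L = len(u.sequence)
        flags[u.representative_id] = False
        idxs = by_len.get(L)
        if not idxs:
            continue
        if parent_rank_of is not None:
            usable = [k for k, j in enumerate(idxs) if j < rank]
        else:
            usable = list(range(len(idxs)))
        if len(usable) < 1:
            continue
        P = parent_mats[L][usable]
        cand = seq_to_bytes(u.sequence)
        mm = (P != cand).astype(np.int32)
        cum = np.cumsum(mm, axis=1)
        tot = cum[:, -1]
        if (tot <= np.floor((1 - identity) * L)).any():
            continue  # essentially a copy of a parent
        b = np.arange(min_side, L - min_side)
        left_ok = cum[:, b - 1] <= np.floor((1 - identity) * b)  # parents x breaks
        right_ok = (tot[:, None] - cum[:, b - 1]) <= np.floor((1 - identity) * (L - b))
        nl = left_ok.sum(0)
        nr = right_ok.sum(0)
        possible = (nl >= 1) & (nr >= 1)
        for t in np.flatnonzero(possible):
            if nl[t] > 1 or nr[t] > 1:
                flags[u.representative_id] = True
                break
            if np.flatnonzero(left_ok[:, t])[0] != np.flatnonzero(right_ok[:, t])[0]:
                flags[u.representative_id] = True
                break
    return flags


# ---------------------------------------------------------------------------
# stand-in denoiser
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DenoiserParams:
    """Parameters of the consensus stand-in corrector.

    ``length_threshold`` is the flowgram length cutoff expressed in
    bases: a read is discarded unless its first ``length_threshold``
    bases can be read within ``flows`` flows (plus the read's own
    flow-yield jitter); survivors are truncated to ``length_threshold``
    bases.  Set ``flows`` to None for a pure base-length screen.
    Correction is two-stage, mirroring the fine-then-coarse structure of
    flowgram denoisers: surviving reads are grouped with any unique within
    ``cluster_radius`` (fractional distance) of a more abundant unique
    holding at least ``min_cluster_size`` reads and rewritten to that
    group's consensus; leftover near-singleton uniques (count <=
    ``coarse_max_count``) are then absorbed into any eligible center
    within ``coarse_radius``.  Abundant distinct sequences are never
    absorbed, so real variation survives while error tails collapse.
    """

    length_threshold: int = 150
    cluster_radius: float = 0.02
    min_cluster_size: int = 2
    max_centers: int = 2000
    flows: float | None = 238.0
    coarse_radius: float = 0.05
    coarse_max_count: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.cluster_radius <= 0.1:
            raise ValueError("cluster_radius must be in (0, 0.1]")
        if self.length_threshold <= 0:
            raise ValueError("length_threshold must be positive")


def mock_denoise(
    reads: RawReadSet,
    params: DenoiserParams | None = None,
    primer: str | None = None,
):
    """Cull on primer/length, then rewrite reads to their group consensus.

    Returns ``(corrected, failed, n_changed)``: corrected maps each
    retained read id to its (possibly rewritten) sequence, 1:1 with raw
    ids; ``failed`` maps every read id to its cull flags (empty if
    retained); ``n_changed`` records changed positions per retained read.
    """
    from .synthetic import flows_needed

    params = params or DenoiserParams()
    primer = primer if primer is not None else reads.primer
    np_ = len(primer)
    failed: dict[str, tuple[str, ...]] = {}
    retained: list[tuple[str, str]] = []
    flow_cache: dict[str, float] = {}
    for r in reads:
        flags = []
        if not r.bases.startswith(primer):
            flags.append("primer")
        post = r.bases[np_:]
        if len(post) < params.length_threshold:
            flags.append("length")
        elif params.flows is not None:
            prefix = post[: params.length_threshold]
            f = flow_cache.get(prefix)
            if f is None:
                f = flows_needed(prefix, params.length_threshold)
                flow_cache[prefix] = f
            if f > params.flows + getattr(r, "flow_noise", 0.0):
                flags.append("length")
        failed[r.read_id] = tuple(flags)
        if not flags:
            retained.append((r.read_id, post[: params.length_threshold]))
    corrected: dict[str, str] = {}
    n_changed: dict[str, int] = {}
    if not retained:
        return corrected, failed, n_changed
    uniques = dereplicate(retained)
    L = params.length_threshold
    radius = params.cluster_radius * L
    n_u = len(uniques)
    # comparisons are made against the (at most) max_centers most abundant
    # centers; rarer centers cannot absorb reads, which only leaves very
    # rare variants uncorrected
    cap = params.max_centers
    mat = np.empty((min(cap, n_u), L), dtype=np.uint8)
    elig = np.zeros(min(cap, n_u), dtype=bool)
    center_seq: list[str] = []
    n_centers = 0
    n_compare = 0  # centers stored in mat
    assigned_center: list[int] = []
    for u in uniques:
        row = seq_to_bytes(u.sequence)
        target = -1
        if n_compare:
            h = (mat[:n_compare] != row).sum(1).astype(float)
            h[~elig[:n_compare]] = np.inf
            best = int(np.argmin(h))
            if h[best] <= radius:
                target = best
        if target >= 0:
            assigned_center.append(target)
        else:
            assigned_center.append(n_centers)
            center_seq.append(u.sequence)
            if n_compare < cap:
                mat[n_compare] = row
                elig[n_compare] = u.count >= params.min_cluster_size
                n_compare += 1
            n_centers += 1
    # coarse pass: absorb leftover near-singleton centers into an eligible
    # abundant center (errors too numerous for the fine radius)
    coarse = params.coarse_radius * L
    own_center = {}
    ulist = list(uniques)
    for idx, (u, c) in enumerate(zip(ulist, assigned_center)):
        if center_seq[c] == u.sequence and u.count <= params.coarse_max_count and n_compare:
            row = seq_to_bytes(u.sequence)
            h = (mat[:n_compare] != row).sum(1).astype(float)
            h[~elig[:n_compare]] = np.inf
            h[h == 0] = np.inf  # self
            best = int(np.argmin(h))
            if h[best] <= coarse:
                assigned_center[idx] = best
    for u, c in zip(ulist, assigned_center):
        cseq = center_seq[c]
        changes = int((seq_to_bytes(u.sequence) != seq_to_bytes(cseq)).sum())
        for rid in u.members:
            corrected[rid] = cseq
            n_changed[rid] = changes
    return corrected, failed, n_changed
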