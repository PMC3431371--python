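"""Dereplication, pairwise distances, and average-neighbor OTU clustering.

OTUs are formed by agglomerative clustering with average linkage (the
unweighted mean of all between-cluster pairwise distances) on unique
sequences, stopping when the smallest average linkage exceeds the cutoff
(3% by default).  A cluster set reported at 0.03 means the last completed
merge was at distance <= 0.03.

For small inputs the full distance matrix is built and clustered directly;
at pipeline scale (:func:`cluster_uniques`) the partition is computed by an
exact decomposition: an average-linkage merge at distance <= cutoff always
contains at least one sequence pair at <= cutoff, so connected components
of the <=cutoff pair graph can be clustered independently.  Candidate close
pairs are found with an 8-mer sharing screen (an edit operation destroys at
most 8 overlapping 8-mers, so near pairs must share many).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components

from ._util import seq_to_bytes
from .error_rate import AlignmentParams, _CIGAR_RE, fast_pair_distance, implied_distance

__all__ = [
    "Unique",
    "UniqueSequenceSet",
    "DistanceMatrix",
    "OTUPartition",
    "dereplicate",
    "distance_matrix",
    "average_neighbor_cluster",
    "cluster_uniques",
    "otu_table",
    "write_list_file",
    "write_names_file",
    "write_shared_file",
]


@dataclass(slots=True)
class Unique:
    sequence: str
    representative_id: str
    count: int
    members: list[str]


class UniqueSequenceSet:
    """Dereplicated sequences with member read ids.

    Uniques are kept in canonical order: descending count, then
    lexicographic representative id.
    """

    def __init__(self, uniques: list[Unique]):
        seen: set[str] = set()
        total: set[str] = set()
        for u in uniques:
            if u.sequence in seen:
                raise ValueError("duplicate unique sequence")
            seen.add(u.sequence)
            if u.count != len(u.members):
                raise ValueError(f"count != member size for {u.representative_id}")
            overlap = total.intersection(u.members)
            if overlap:
                raise ValueError(f"member sets not disjoint: {sorted(overlap)[:3]}")
            total.update(u.members)
        self.uniques = sorted(uniques, key=lambda u: (-u.count, u.representative_id))

    def __len__(self) -> int:
        return len(self.uniques)

    def __iter__(self):
        return iter(self.uniques)

    @property
    def total_reads(self) -> int:
        return sum(u.count for u in self.uniques)

    def sequences(self) -> list[str]:
        return [u.sequence for u in self.uniques]


def dereplicate(reads: Mapping[str, str] | Iterable[tuple[str, str]]) -> UniqueSequenceSet:
    """Collapse identical sequences; representative is the lexicographically
    first member read id."""
    items = reads.items() if isinstance(reads, Mapping) else reads
    groups: dict[str, list[str]] = {}
    for rid, seq in items:
        groups.setdefault(seq, []).append(rid)
    uniques = []
    for seq, members in groups.items():
        members.sort()
        uniques.append(Unique(seq, members[0], len(members), members))
    return UniqueSequenceSet(uniques)


@dataclass
class DistanceMatrix:
    """Square symmetric pairwise distance matrix over unique sequences."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = self.data
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diagonal(d)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must have a zero diagonal")


def distance_matrix(
    uniques: UniqueSequenceSet | Sequence[str],
    params: AlignmentParams | None = None,
    engine: str = "fast",
) -> DistanceMatrix:
    """All-pairs implied distances over uniques.

    ``engine="exact"`` runs the full dynamic program per pair (small inputs
    and oracle checks); ``"fast"`` (default) uses the screened engine,
    which is property-tested to agree with the exact one.
    """
    if isinstance(uniques, UniqueSequenceSet):
        ids = [u.representative_id for u in uniques]
        seqs = uniques.sequences()
    else:
        seqs = list(uniques)
        ids = [f"seq_{i}" for i in range(len(seqs))]
    n = len(seqs)
    if n < 1:
        raise ValueError("need at least one unique")
    d = np.zeros((n, n))
    if engine == "exact":
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = implied_distance(seqs[i], seqs[j], params).value
    elif n > 1:
        ii, jj = np.triu_indices(n, k=1)
        arrays = [seq_to_bytes(s) for s in seqs]
        vals = _pair_distances(arrays, seqs, ii, jj)
        d[ii, jj] = vals
        d[jj, ii] = vals
    return DistanceMatrix(ids=ids, data=d)


@dataclass
class OTUPartition:
    """Read-level OTU assignment at a distance cutoff."""

    cutoff_label: float
    otus: dict[str, list[str]]  # OTU id -> member read ids
    rep_sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for oid, members in self.otus.items():
            if not members:
                raise ValueError(f"empty OTU {oid}")
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"read in two OTUs: {sorted(overlap)[:3]}")
            seen.update(members)

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    @property
    def n_reads(self) -> int:
        return sum(len(m) for m in self.otus.values())

    def read_to_otu(self) -> dict[str, str]:
        return {r: oid for oid, members in self.otus.items() for r in members}

    def sizes(self) -> dict[str, int]:
        return {oid: len(m) for oid, m in self.otus.items()}


def _labels_to_partition(
    labels: np.ndarray,
    cutoff: float,
    ids: list[str],
    uniques: UniqueSequenceSet | None,
) -> OTUPartition:
    clusters: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(idx)
    by_unique = {u.representative_id: u for u in uniques} if uniques is not None else None
    rows = []
    for idxs in clusters.values():
        if by_unique is not None:
            members = [m for i in idxs for m in by_unique[ids[i]].members]
            best = max(idxs, key=lambda i: (by_unique[ids[i]].count, ids[i]))
            rep_seq = by_unique[ids[best]].sequence
        else:
            members = [ids[i] for i in idxs]
            rep_seq = ""
        rows.append((sorted(members), rep_seq))
    rows.sort(key=lambda t: (-len(t[0]), t[0][0]))
    otus = {f"OTU_{k + 1:04d}": members for k, (members, _) in enumerate(rows)}
    reps = {f"OTU_{k + 1:04d}": seq for k, (_, seq) in enumerate(rows) if seq}
    return OTUPartition(cutoff_label=cutoff, otus=otus, rep_sequences=reps)


def average_neighbor_cluster(
    dm: DistanceMatrix,
    cutoff: float = 0.03,
    uniques: UniqueSequenceSet | None = None,
) -> OTUPartition:
    """Average-linkage clustering of a distance matrix at a cutoff.

    When ``uniques`` is given, clusters are expanded to their member reads;
    otherwise each matrix row is treated as one read.
    """
    n = len(dm.ids)
    if n == 1:
        labels = np.array([1])
    else:
        condensed = dm.data[np.triu_indices(n, k=1)]
        Z = linkage(condensed, method="average")
        labels = fcluster(Z, t=cutoff, criterion="distance")
    return _labels_to_partition(labels, cutoff, dm.ids, uniques)


# ---------------------------------------------------------------------------
# scalable clustering
# ---------------------------------------------------------------------------

_KMER = 8


def _kmer_matrix(seq_arrays: list[np.ndarray], k: int = _KMER, hash_bits: int | None = None) -> sp.csr_matrix:
    """Binary sequences x k-mers incidence matrix.

    For k > 10 the k-mer space is folded into ``hash_bits`` buckets with a
    multiplicative hash; collisions only create extra candidate pairs,
    which are verified downstream."""
    n = len(seq_arrays)
    ncols = 4**k if hash_bits is None else 2**hash_bits
    if n == 0:
        return sp.csr_matrix((0, ncols), dtype=np.int32)
    code = np.zeros(256, dtype=np.int64)
    code[ord("C")], code[ord("G")], code[ord("T")] = 1, 2, 3
    lens = np.array([a.size for a in seq_arrays])
    flat = code[np.concatenate(seq_arrays)] if lens.sum() else np.zeros(0, dtype=np.int64)
    starts = np.concatenate(([0], np.cumsum(lens)))
    total = flat.size
    if total < k:
        return sp.csr_matrix((n, ncols), dtype=np.int32)
    kmers = np.zeros(total - k + 1, dtype=np.int64)
    for j in range(k):
        kmers = (kmers * 4 + flat[j : total - k + 1 + j]) & 0x7FFFFFFFFFFFFFFF
    if hash_bits is not None:
        h = kmers.astype(np.uint64) * np.uint64(0x9E3779B97F4A7C15)
        kmers = (h >> np.uint64(64 - hash_bits)).astype(np.int64)
    # per-row unique kmers, assembled without a global sort
    col_chunks = []
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        if lens[i] < k:
            indptr[i + 1] = indptr[i]
            continue
        u = np.unique(kmers[starts[i] : starts[i + 1] - k + 1])
        col_chunks.append(u.astype(np.int32))
        indptr[i + 1] = indptr[i] + u.size
    cols = np.concatenate(col_chunks) if col_chunks else np.zeros(0, dtype=np.int32)
    data = np.ones(cols.size, dtype=np.int32)
    return sp.csr_matrix((data, cols, indptr), shape=(n, ncols))


def _candidate_pairs(seqs: list[str], max_ops: int, block: int = 4000):
    """Pairs (i < j) that could be within ``max_ops`` edit operations,
    by the 8-mer destruction bound: one edit operation destroys at most 8
    distinct 8-mers, so a pair within ``max_ops`` operations must share at
    least (lmin - 7) - 8*max_ops of them.

    The sharing-count matrix is computed exactly, but split: columns
    carried by many sequences (shared ancestry) cost quadratically in a
    sparse product, so they go through a dense BLAS product instead.

    Returns (ii, jj, shared, arrays).
    """
    arrays = [seq_to_bytes(s) for s in seqs]
    S = _kmer_matrix(arrays)
    lens = np.array([a.size for a in arrays])
    n = len(seqs)
    df = np.asarray(S.sum(axis=0)).ravel()
    dense_cols = np.flatnonzero(df > max(64, n // 8))
    if dense_cols.size:
        Bg = S[:, dense_cols].toarray().astype(np.float32)
        S = S[:, np.flatnonzero(df <= max(64, n // 8))]
    else:
        Bg = None
    ST = S.T.tocsc()
    out_i, out_j, out_s = [], [], []
    for start in range(0, n, block):
        stop = min(start + block, n)
        C = (S[start:stop] @ ST).toarray().astype(np.float32)
        if Bg is not None:
            C += Bg[start:stop] @ Bg.T
        lmin = np.minimum(lens[start:stop, None], lens[None, :])
        # when the bound is non-positive (short sequences) every pair is
        # a legitimate candidate
        thresh = np.maximum((lmin - _KMER + 1) - _KMER * max_ops, 0)
        ii, jj = np.nonzero(C >= thresh)
        shared = C[ii, jj]
        ii = ii + start
        keep = ii < jj
        out_i.append(ii[keep])
        out_j.append(jj[keep])
        out_s.append(shared[keep])
    return (
        np.concatenate(out_i),
        np.concatenate(out_j),
        np.concatenate(out_s),
        arrays,
    )


def _pair_distances(
    arrays, seqs, ii, jj, indel_like=None, gap_suspect_at: int = 7, M=None, lens=None
) -> np.ndarray:
    """Distances for an explicit pair list, vectorized where possible.

    The shorter member of each pair is compared to the other's prefix
    (free terminal gaps make the overhang and any terminal mismatch runs
    droppable), giving a stripped-Hamming count.  Pairs that may contain
    internal indels — those touching a known frameshift carrier, or with
    a small length difference — are re-examined with a bounded alignment
    and, when it confirms gap structure, the full convention-correct
    pairwise alignment.  Without an ``indel_like`` mask every pair at or
    beyond ``gap_suspect_at`` differences (and every length-differing
    pair) is aligned, which is exact but slower.
    """
    d = np.empty(ii.size)
    if lens is None:
        lens = np.array([a.size for a in arrays])
    if M is None:
        M = np.zeros((len(arrays), int(lens.max())), dtype=np.uint8)
        for k, a in enumerate(arrays):
            M[k, : a.size] = a
    ls = np.minimum(lens[ii], lens[jj])
    ldiff = np.abs(lens[ii] - lens[jj])
    for L in np.unique(ls):
        lsel = np.flatnonzero(ls == L)
        diff = M[ii[lsel], :L] != M[jj[lsel], :L]
        nd = diff.sum(1)
        vals = nd / L
        if indel_like is not None:
            import edlib as _el

            # equal-length pairs touching a frameshift carrier can beat
            # their Hamming count: cheap bounded reject, then the full
            # convention-correct alignment for genuine hits
            suspect = (
                (ldiff[lsel] == 0)
                & (nd >= 4)
                & (indel_like[ii[lsel]] | indel_like[jj[lsel]])
            )
            k_cut = int(0.06 * L) + 2
            for t in np.flatnonzero(suspect):
                sa, sb = seqs[ii[lsel[t]]], seqs[jj[lsel[t]]]
                e = _el.align(sa, sb, mode="NW", task="distance", k=k_cut)["editDistance"]
                if e != -1 and e < nd[t] + 2:
                    vals[t] = min(vals[t], fast_pair_distance(sa, sb).value)
            # length-differing pairs always carry an overhang: realign
            # those near the decision zone or with indel evidence (small
            # length offset or a frameshift carrier); distant truncation
            # pairs keep the (slightly conservative) prefix count
            unequal = (ldiff[lsel] > 0) & (nd >= 1)
            realign = unequal & (
                (nd <= 8)
                | (ldiff[lsel] <= 3)
                | indel_like[ii[lsel]]
                | indel_like[jj[lsel]]
            )
            for t in np.flatnonzero(realign):
                vals[t] = fast_pair_distance(seqs[ii[lsel[t]]], seqs[jj[lsel[t]]]).value
        else:
            suspect = (nd >= gap_suspect_at) | (ldiff[lsel] > 0)
            for t in np.flatnonzero(suspect):
                vals[t] = fast_pair_distance(seqs[ii[lsel[t]]], seqs[jj[lsel[t]]]).value
        d[lsel] = vals
    return d


def _detect_indel_like(seqs, arrays, ii, jj, shared):
    """Mark sequences that carry a frameshift relative to their nearest
    neighbor: each sequence is compared (once) to its strongest-sharing
    candidate partner; if a unit-cost alignment beats the mismatch count,
    the sequence contains indels and its pairs deserve full alignment."""
    try:
        import edlib
    except ImportError:  # pragma: no cover
        return np.ones(len(seqs), dtype=bool)
    n = len(seqs)
    flags = np.zeros(n, dtype=bool)
    if ii.size == 0:
        return flags
    # partner = the most abundant candidate neighbor (uniques come in
    # descending-abundance order, so the smallest index): almost always
    # the home template, never a rare frameshift variant
    both_i = np.concatenate([ii, jj])
    both_j = np.concatenate([jj, ii])
    order = np.lexsort((both_j, both_i))
    first = np.unique(both_i[order], return_index=True)[1]
    partner = np.full(n, -1, dtype=np.int64)
    partner[both_i[order][first]] = both_j[order][first]
    for u in range(n):
        v = partner[u]
        if v < 0:
            continue
        a, b = arrays[u], arrays[int(v)]
        if a.size != b.size:
            # terminal truncation is not indel evidence; an *internal*
            # indel shows as an infix alignment beating the prefix match
            short, long_ = (a, b) if a.size < b.size else (b, a)
            h = int((short != long_[: short.size]).sum())
            if h < 3:
                continue
            res = edlib.align(
                seqs[u] if a.size < b.size else seqs[int(v)],
                seqs[int(v)] if a.size < b.size else seqs[u],
                mode="HW",
                task="distance",
                k=h - 1,
            )
        else:
            h = int((a != b).sum())
            if h < 3:
                continue
            res = edlib.align(seqs[u], seqs[int(v)], mode="NW", task="distance", k=h - 1)
        if res["editDistance"] != -1:
            flags[u] = True
    return flags


def cluster_uniques(
    uniques: UniqueSequenceSet,
    cutoff: float = 0.03,
) -> OTUPartition:
    """Average-neighbor partition at pipeline scale.

    Equivalent to clustering the full matrix at the cutoff: merges at
    <= cutoff cannot cross connected components of the <= cutoff pair
    graph (an average at or below the cutoff implies at least one pair at
    or below it), so each component — in practice, one error cloud per
    community member — is clustered independently with average linkage on
    its complete within-component distance matrix.
    """
    seqs = uniques.sequences()
    ids = [u.representative_id for u in uniques.uniques]
    n = len(seqs)
    if n == 1:
        return _labels_to_partition(np.array([1]), cutoff, ids, uniques)
    lmin = min(len(s) for s in seqs)
    max_ops = int(np.ceil(cutoff * lmin)) + 2
    ii, jj, shared, arrays = _candidate_pairs(seqs, max_ops)
    indel_like = _detect_indel_like(seqs, arrays, ii, jj, shared)
    lens = np.array([a.size for a in arrays])
    M = np.zeros((n, int(lens.max())), dtype=np.uint8)
    for k, a in enumerate(arrays):
        M[k, : a.size] = a
    d = (
        _pair_distances(arrays, seqs, ii, jj, indel_like=indel_like, M=M, lens=lens)
        if ii.size
        else np.empty(0)
    )
    close = d <= cutoff
    g = sp.csr_matrix(
        (np.ones(close.sum()), (ii[close], jj[close])), shape=(n, n)
    )
    n_comp, comp = connected_components(g, directed=False)
    labels = np.zeros(n, dtype=np.int64)
    next_label = 1
    for cid in range(n_comp):
        members = np.flatnonzero(comp == cid)
        if members.size == 1:
            labels[members[0]] = next_label
            next_label += 1
            continue
        ki, kj = np.triu_indices(members.size, k=1)
        sub_d = _pair_distances(
            arrays, seqs, members[ki], members[kj], indel_like=indel_like, M=M, lens=lens
        )
        sub = np.zeros((members.size, members.size))
        sub[ki, kj] = sub_d
        sub[kj, ki] = sub_d
        Z = linkage(sub[np.triu_indices(members.size, k=1)], method="average")
        sub_labels = fcluster(Z, t=cutoff, criterion="distance")
        for k, m in enumerate(members):
            labels[m] = next_label + sub_labels[k] - 1
        next_label += sub_labels.max()
    return _labels_to_partition(labels, cutoff, ids, uniques)


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------


def otu_table(partition: OTUPartition, groups: Mapping[str, str]):
    """Samples x OTUs count matrix (pandas DataFrame).

    Raises ValueError if a read in the partition has no sample assignment.
    """
    import pandas as pd

    counts: dict[str, dict[str, int]] = {}
    missing = []
    for oid, members in partition.otus.items():
        for rid in members:
            sid = groups.get(rid)
            if sid is None:
                missing.append(rid)
                continue
            counts.setdefault(sid, {}).setdefault(oid, 0)
            counts[sid][oid] += 1
    if missing:
        raise ValueError(f"reads with unknown sample: {missing[:5]}")
    table = pd.DataFrame(counts).T.fillna(0).astype(int)
    table = table.reindex(sorted(table.index), axis=0)
    table = table.reindex(sorted(partition.otus), axis=1, fill_value=0)
    return table


# ---------------------------------------------------------------------------
# flat-file output
# ---------------------------------------------------------------------------


def write_list_file(path, partition: OTUPartition) -> None:
    """List-style OTU file: label, n_otus, then comma-joined members per OTU."""
    with open(path, "w") as fh:
        cols = [",".join(m) for m in partition.otus.values()]
        fh.write("\t".join([str(partition.cutoff_label), str(partition.n_otus)] + cols) + "\n")


def write_names_file(path, uniques: UniqueSequenceSet) -> None:
    with open(path, "w") as fh:
        for u in uniques:
            fh.write(f"{u.representative_id}\t{','.join(u.members)}\n")


def write_shared_file(path, table) -> None:
    table.to_csv(path, sep="\t", index_label="sample")
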