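"""Dereplication, distances, and average-neighbor clustering."""

import numpy as np
import pytest

from denoise_impact import (
    average_neighbor_cluster,
    cluster_uniques,
    dereplicate,
    distance_matrix,
    otu_table,
)
from denoise_impact.otu import DistanceMatrix, write_list_file, write_names_file
from oracles import brute_average_linkage

DNA = "ACGT"


class TestDereplicate:
    def test_identical_reads_collapse(self):
        u = dereplicate({f"r{i}": "ACGT" for i in range(5)})
        assert len(u) == 1
        assert u.uniques[0].count == 5
        assert u.uniques[0].representative_id == "r0"

    def test_all_distinct(self):
        u = dereplicate({"a": "AAAA", "b": "CCCC", "c": "GGGG"})
        assert len(u) == 3

    def test_mixed_toy_counts_match_hand_tally(self):
        reads = {
            "r1": "AAAA", "r2": "AAAA", "r3": "AAAA", "r4": "CCCC",
            "r5": "CCCC", "r6": "GGGG", "r7": "AAAA",
        }
        u = dereplicate(reads)
        counts = {x.sequence: x.count for x in u}
        assert counts == {"AAAA": 4, "CCCC": 2, "GGGG": 1}
        # canonical order: count desc then representative id
        assert [x.sequence for x in u] == ["AAAA", "CCCC", "GGGG"]


class TestDistanceMatrix:
    def test_single_unique_gives_zero_matrix(self):
        dm = distance_matrix(["ACGTACGT"])
        assert dm.data.shape == (1, 1) and dm.data[0, 0] == 0

    def test_three_of_hundred_positions(self):
        a = ("ACGT" * 25)[:100]
        b = a[:10] + "T" + a[11:50] + "C" + a[51:90] + "A" + a[91:]
        assert b != a and len(b) == 100
        dm = distance_matrix([a, b])
        assert dm.data[0, 1] == pytest.approx(3 / 100)

    def test_fast_matches_exact_on_random_uniques(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list(DNA), 60))
        seqs = [base]
        for _ in range(5):
            s = list(base)
            for p in rng.choice(60, rng.integers(1, 6), replace=False):
                s[p] = rng.choice([c for c in DNA if c != s[p]])
            seqs.append("".join(s))
        fast = distance_matrix(seqs).data
        exact = distance_matrix(seqs, engine="exact").data
        assert np.allclose(fast, exact)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], data=np.array([[0.0, 0.1], [0.2, 0.0]]))


class TestAverageNeighbor:
    def dm(self, entries, n):
        d = np.zeros((n, n))
        for (i, j), v in entries.items():
            d[i, j] = d[j, i] = v
        return DistanceMatrix(ids=[f"u{k}" for k in range(n)], data=d)

    def test_hand_traced_simple_merge(self):
        dm = self.dm({(0, 1): 0.02, (0, 2): 0.05, (1, 2): 0.05}, 3)
        part = average_neighbor_cluster(dm, cutoff=0.03)
        groups = {frozenset(m) for m in part.otus.values()}
        assert groups == {frozenset({"u0", "u1"}), frozenset({"u2"})}

    def test_discriminating_case_vs_single_linkage(self):
        # avg({u0,u1}, u2) = (0.025+0.05)/2 = 0.0375 > 0.03: average linkage
        # refuses the merge single linkage would make
        dm = self.dm({(0, 1): 0.02, (0, 2): 0.025, (1, 2): 0.05}, 3)
        part = average_neighbor_cluster(dm, cutoff=0.03)
        groups = {frozenset(m) for m in part.otus.values()}
        assert groups == {frozenset({"u0", "u1"}), frozenset({"u2"})}

    def test_cutoff_zero_gives_one_otu_per_unique(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.01, 0.5, (6, 6))
        d = np.triu(d, 1)
        d = d + d.T
        part = average_neighbor_cluster(DistanceMatrix(ids=[f"u{k}" for k in range(6)], data=d), cutoff=0.0)
        assert part.n_otus == 6

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        d = np.triu(rng.uniform(0, 0.2, (10, 10)), 1)
        d = d + d.T
        dm = DistanceMatrix(ids=[f"u{k}" for k in range(10)], data=d)
        counts = [average_neighbor_cluster(dm, cutoff=c).n_otus for c in (0.01, 0.03, 0.08, 0.15)]
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_oracle(self):
        """Partition equals naive recompute-every-mean average linkage."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            d = np.triu(rng.uniform(0.0, 0.12, (n, n)), 1)
            d = d + d.T
            dm = DistanceMatrix(ids=[f"u{k}" for k in range(n)], data=d)
            part = average_neighbor_cluster(dm, cutoff=0.03)
            got = sorted(
                (frozenset(int(m[1:]) for m in members) for members in part.otus.values()),
                key=lambda c: sorted(c),
            )
            assert got == brute_average_linkage(d, 0.03)


class TestClusterUniques:
    def test_tracks_matrix_route_on_reads(self, small_rawset):
        """The scalable route reproduces the full-matrix partition almost
        exactly; the two distance engines may disagree by one difference
        on gapped ties, so a handful of boundary OTUs may differ."""
        kept = {r.read_id: r.bases[20:][:150] for r in small_rawset.reads[:800]}
        uniques = dereplicate(kept)
        fast = cluster_uniques(uniques, cutoff=0.03)
        dm = distance_matrix(uniques)
        ref = average_neighbor_cluster(dm, cutoff=0.03, uniques=uniques)
        from sklearn.metrics import adjusted_rand_score

        fast_of = fast.read_to_otu()
        ref_of = ref.read_to_otu()
        reads = sorted(kept)
        ari = adjusted_rand_score([ref_of[r] for r in reads], [fast_of[r] for r in reads])
        assert ari >= 0.98
        assert abs(fast.n_otus - ref.n_otus) <= max(2, 0.02 * ref.n_otus)

    def test_partition_conserves_reads(self, small_rawset):
        kept = {r.read_id: r.bases[20:][:150] for r in small_rawset.reads[:1500]}
        part = cluster_uniques(dereplicate(kept), cutoff=0.03)
        assert part.n_reads == len(kept)

    def test_uniques_then_expand_equals_reads_directly(self):
        seqs = {"a": "ACGTACGTAC", "b": "ACGTACGTAC", "c": "ACGAACGTAC", "d": "TTTTGGGGCC"}
        via_uniques = cluster_uniques(dereplicate(seqs), cutoff=0.11)
        dm = distance_matrix(list(seqs.values()))
        dm.ids = list(seqs)
        direct = average_neighbor_cluster(dm, cutoff=0.11)
        assert {frozenset(m) for m in via_uniques.otus.values()} == {
            frozenset(m) for m in direct.otus.values()
        }


class TestOtuTable:
    def test_single_sample_row_equals_otu_sizes(self):
        part = cluster_uniques(dereplicate({"a": "AAAA", "b": "AAAA", "c": "TTTT"}), cutoff=0.03)
        tab = otu_table(part, {"a": "s1", "b": "s1", "c": "s1"})
        assert sorted(tab.loc["s1"].tolist()) == [1, 2]

    def test_two_sample_toy_matches_hand_tally(self):
        part = cluster_uniques(
            dereplicate({"a": "AAAA", "b": "AAAA", "c": "TTTT", "d": "GGCC", "e": "TTTT"}),
            cutoff=0.03,
        )
        groups = {"a": "s1", "b": "s2", "c": "s1", "d": "s2", "e": "s2"}
        tab = otu_table(part, groups)
        assert tab.to_numpy().sum() == 5
        assert tab.loc["s1"].sum() == 2 and tab.loc["s2"].sum() == 3

    def test_unknown_read_is_explicit_failure(self):
        part = cluster_uniques(dereplicate({"a": "AAAA"}), cutoff=0.03)
        with pytest.raises(ValueError):
            otu_table(part, {})

    def test_row_sums_conserved_on_simulated_run(self, small_rawset):
        kept = {r.read_id: r.bases[20:][:150] for r in small_rawset.reads[:1000]}
        part = cluster_uniques(dereplicate(kept), cutoff=0.03)
        tab = otu_table(part, small_rawset.sample_of())
        per_sample = {}
        for rid in kept:
            sid = small_rawset.sample_of()[rid]
            per_sample[sid] = per_sample.get(sid, 0) + 1
        assert {s: int(v) for s, v in tab.sum(axis=1).items()} == per_sample


def test_list_and_names_files(tmp_path):
    uniques = dereplicate({"a": "AAAA", "b": "AAAA", "c": "TTTT"})
    part = cluster_uniques(uniques, cutoff=0.03)
    lp, np_ = tmp_path / "x.list", tmp_path / "x.names"
    write_list_file(lp, part)
    write_names_file(np_, uniques)
    fields = lp.read_text().strip().split("\t")
    assert fields[0] == "0.03" and int(fields[1]) == part.n_otus
    assert set(",".join(fields[2:]).split(",")) == {"a", "b", "c"}
    lines = dict(l.split("\t") for l in np_.read_text().splitlines())
    assert lines["a"] == "a,b"
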