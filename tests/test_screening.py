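"""Quality screening, preclustering, chimera flagging, mock denoiser."""

import numpy as np
import pytest

from denoise_impact import (
    DEFAULT_PRIMER,
    DenoiserParams,
    NoiseModel,
    RawReadSet,
    flag_chimeras,
    mock_denoise,
    precluster,
    screen_reads,
    trim_reads,
)
from denoise_impact.otu import dereplicate
from denoise_impact.screening import ScreeningCriteria

P = DEFAULT_PRIMER
REF = ("ACGT" * 50)[:160]


def crit(**kw):
    defaults = dict(primer=P, min_reference_identity=None, min_avg_quality=25.0)
    defaults.update(kw)
    return ScreeningCriteria(**defaults)


def outcome_for(reads, criteria=None, refs=None):
    return screen_reads(RawReadSet(reads, primer=P), criteria or crit(), references=refs)


class TestScreenReads:
    def test_homopolymer_run_of_seven_is_culled(self, toy_reads):
        seq = REF[:70] + "G" * 7 + REF[77:150]
        out = outcome_for([toy_reads("r1", seq)])
        assert out.failed["r1"] == ("homopolymer",)

    def test_length_119_is_culled(self, toy_reads):
        out = outcome_for([toy_reads("r1", REF[:119])])
        assert "length" in out.failed["r1"]

    def test_clean_read_passes_all_criteria(self, toy_reads):
        r = toy_reads("r1", REF[:150], qual=np.full(20 + 150, 40))
        out = outcome_for([r], crit(min_reference_identity=0.75), refs=[REF])
        assert out.failed["r1"] == ()
        assert out.kept == ["r1"]

    def test_multiple_failures_all_recorded(self, toy_reads):
        seq = REF[:100] + "A" * 8  # short AND long homopolymer
        r = toy_reads("r1", seq, qual=np.full(20 + 108, 10))
        out = outcome_for([r])
        assert set(out.failed["r1"]) == {"length", "homopolymer", "quality"}
        counts = out.failure_counts()
        assert counts["length"] == counts["homopolymer"] == counts["quality"] == 1

    def test_primer_mismatch_flagged(self, toy_reads):
        r = toy_reads("r1", REF[:150], primer="T" + P[1:])
        out = outcome_for([r])
        assert "primer" in out.failed["r1"]

    def test_ambiguous_base_flagged(self, toy_reads):
        out = outcome_for([toy_reads("r1", REF[:100] + "N" + REF[101:150])])
        assert out.failed["r1"] == ("ambiguous",)

    def test_missing_qualities_with_quality_criterion_is_error(self, toy_reads):
        r = toy_reads("r1", REF[:150])
        r.quality = np.array([], dtype=np.int16)
        r.bases = ""
        with pytest.raises(ValueError):
            outcome_for([r])

    def test_alignment_criterion_requires_references(self, toy_reads):
        with pytest.raises(ValueError):
            outcome_for([toy_reads("r1", REF[:150])], crit(min_reference_identity=0.8))

    def test_accounting_identity(self, small_rawset, small_community):
        refs = [t.sequence for t in small_community]
        out = screen_reads(small_rawset, ScreeningCriteria(primer=P), references=refs)
        assert out.n_kept + sum(1 for f in out.failed.values() if f) == out.n_input
        assert out.n_input == len(small_rawset)
        # multi-failure reads mean summed counts can exceed dropped reads
        assert out.n_input - out.n_kept <= sum(out.failure_counts().values())


class TestTrim:
    def test_long_read_truncated(self):
        assert trim_reads([("r1", "A" * 165)], 150) == [("r1", "A" * 150)]

    def test_read_at_length_unchanged_and_order_preserved(self):
        pairs = [("b", "C" * 150), ("a", "G" * 140)]
        out = trim_reads(pairs, 150)
        assert out == pairs

    def test_empty_input(self):
        assert trim_reads([], 150) == []


class TestPrecluster:
    def test_single_base_variant_merges_into_abundant(self):
        reads = {f"x{i}": "ACGTACGT" for i in range(10)} | {"y0": "ACGTACGA"}
        out = precluster(dereplicate(reads))
        assert len(out) == 1
        u = out.uniques[0]
        assert u.sequence == "ACGTACGT"
        assert u.count == 11
        assert "y0" in u.members

    def test_distant_uniques_unchanged(self):
        reads = {"a": "AAAAAA", "b": "AATTAA", "c": "GGGGGG"}
        out = precluster(dereplicate(reads))
        assert len(out) == 3

    def test_chain_merging_in_abundance_order(self):
        reads = (
            {f"a{i}": "AAAAC" for i in range(5)}
            | {f"b{i}": "AAATC" for i in range(2)}
            | {"c0": "AATTC"}
        )
        out = precluster(dereplicate(reads))
        assert len(out) == 1
        assert out.uniques[0].sequence == "AAAAC"
        assert out.uniques[0].count == 8

    def test_single_base_indel_merges(self):
        reads = {f"a{i}": "ACGTACGTAC" for i in range(3)} | {"d0": "ACGACGTAC"[:9]}
        out = precluster(dereplicate(reads))
        assert len(out) == 1

    def test_member_count_conserved(self, small_rawset):
        kept = {r.read_id: r.bases[len(P):][:150] for r in small_rawset.reads[:2000]}
        u0 = dereplicate(kept)
        u1 = precluster(u0)
        assert u1.total_reads == u0.total_reads == len(kept)
        assert len(u1) <= len(u0)


class TestChimeraFlagging:
    def _uniques(self, extra):
        t1 = ("ACGT" * 40)[:150]
        t2 = ("TTAGGCCA" * 20)[:150]
        reads = {f"p{i}": t1 for i in range(20)} | {f"q{i}": t2 for i in range(10)} | extra
        return dereplicate(reads), t1, t2

    def test_constructed_bimera_is_flagged(self):
        uniques, t1, t2 = self._uniques({})
        chim = t1[:75] + t2[75:]
        uniques, _, _ = self._uniques({"c0": chim})
        flags = flag_chimeras(uniques)
        rep_of = {u.sequence: u.representative_id for u in uniques}
        assert flags[rep_of[chim]]
        assert not flags[rep_of[t1]]
        assert not flags[rep_of[t2]]

    def test_exact_copy_never_flagged(self):
        t1 = ("ACGT" * 40)[:150]
        uniques, _, _ = self._uniques({"c0": t1})
        flags = flag_chimeras(uniques)
        assert not any(flags.values())

    def test_no_parents_above_threshold_not_flagged(self):
        uniques, _, _ = self._uniques({"c0": ("GATCCGTA" * 20)[:150]})
        flags = flag_chimeras(uniques)
        assert not any(flags.values())

    def test_empty_candidate_set_is_error(self):
        from denoise_impact.otu import UniqueSequenceSet

        with pytest.raises(ValueError):
            flag_chimeras(UniqueSequenceSet([]))


class TestMockDenoise:
    def test_zero_noise_keeps_everything_but_short_reads(self, clean_rawset):
        corrected, failed, n_changed = mock_denoise(
            clean_rawset, DenoiserParams(flows=None), P
        )
        assert all(v == 0 for v in n_changed.values())
        for rid, flags in failed.items():
            assert flags in ((), ("length",))  # no primer failures at zero noise
        assert len(corrected) + sum(1 for f in failed.values() if f) == len(clean_rawset)

    def test_variant_rewritten_to_consensus(self, toy_reads):
        tpl = REF[:150]
        var = tpl[:50] + ("A" if tpl[50] != "A" else "C") + tpl[51:]
        reads = [toy_reads(f"t{i}", tpl) for i in range(10)] + [toy_reads("v0", var)]
        corrected, failed, n_changed = mock_denoise(
            RawReadSet(reads, primer=P), DenoiserParams(cluster_radius=0.03, flows=None), P
        )
        assert corrected["v0"] == tpl
        assert n_changed["v0"] == 1

    def test_primer_mismatch_is_culled(self, toy_reads):
        reads = [toy_reads("t0", REF[:150]), toy_reads("bad", REF[:150], primer="A" + P[1:])]
        corrected, failed, _ = mock_denoise(RawReadSet(reads, primer=P), DenoiserParams(flows=None), P)
        assert failed["bad"] == ("primer",)
        assert "bad" not in corrected

    def test_flow_cut_removes_flow_expensive_reads(self, toy_reads):
        # an alternating sequence needs ~1 flow per base: far above 100 flows
        reads = [toy_reads("slow", ("ACGT" * 40)[:150]), toy_reads("fast", ("AAAACCCCGGGGTTTT" * 10)[:150])]
        params = DenoiserParams(flows=100.0)
        corrected, failed, _ = mock_denoise(RawReadSet(reads, primer=P), params, P)
        assert "length" in failed["slow"]
        assert failed["fast"] == ()

    def test_unique_count_shrinks_with_radius(self, small_rawset):
        counts = []
        for radius in (0.005, 0.02, 0.05):
            corrected, _, _ = mock_denoise(
                small_rawset, DenoiserParams(cluster_radius=radius, flows=None), P
            )
            counts.append(len(set(corrected.values())))
        assert counts[0] >= counts[1] >= counts[2]

    def test_output_is_one_to_one_with_retained_reads(self, small_rawset):
        corrected, failed, n_changed = mock_denoise(small_rawset, DenoiserParams(), P)
        retained = [rid for rid, f in failed.items() if not f]
        assert sorted(corrected) == sorted(retained)
        assert sorted(n_changed) == sorted(retained)

    def test_radius_validation(self):
        with pytest.raises(ValueError):
            DenoiserParams(cluster_radius=0.5)
        with pytest.raises(ValueError):
            DenoiserParams(length_threshold=0)
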