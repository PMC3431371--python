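"""Read-fate tracking through two processing pipelines.

Replaces the relational read-mapping database of the original workflow
with an in-memory total mapping persisted as a flat, diffable TSV: for
every raw read, its fate (KEPT with a processed id, or CULLED with the
criteria that removed it) in each pipeline, plus the reverse index from
processed ids back to raw ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = ["ProvenanceDB", "OverlapReport", "build_provenance", "overlap_stats"]

KEPT = "KEPT"
CULLED = "CULLED"


@dataclass
class OverlapReport:
    """Four-cell partition of the raw read set by joint fate.

    The two headline percentages use each pipeline's *kept* set as the
    denominator (the asymmetric convention of the source analysis):
    ``pct_a_only`` is the share of A-kept reads culled by B.  Percentages
    are ``None`` (undefined), never zero, when a denominator is empty.
    """

    kept_both: int
    kept_only_a: int
    kept_only_b: int
    culled_both: int
    pct_a_only: float | None
    pct_b_only: float | None

    @property
    def total(self) -> int:
        return self.kept_both + self.kept_only_a + self.kept_only_b + self.culled_both

    def as_dict(self) -> dict:
        return {
            "kept_both": self.kept_both,
            "kept_only_a": self.kept_only_a,
            "kept_only_b": self.kept_only_b,
            "culled_both": self.culled_both,
            "pct_a_only": self.pct_a_only,
            "pct_b_only": self.pct_b_only,
        }


class ProvenanceDB:
    """Total per-read fate map for two pipelines (A and B)."""

    def __init__(self, fates: dict[str, tuple]):
        # fates: read_id -> (fate_a, processed_a, criteria_a, fate_b, processed_b, criteria_b)
        self.fates = fates
        self._reverse = {"A": {}, "B": {}}
        for rid, (fa, pa, _, fb, pb, _) in fates.items():
            if fa == KEPT:
                if pa in self._reverse["A"]:
                    raise ValueError(f"processed id {pa} maps to two raw reads in A")
                self._reverse["A"][pa] = rid
            if fb == KEPT:
                if pb in self._reverse["B"]:
                    raise ValueError(f"processed id {pb} maps to two raw reads in B")
                self._reverse["B"][pb] = rid

    def __len__(self) -> int:
        return len(self.fates)

    def kept_ids(self, pipeline: str) -> list[str]:
        k = 0 if pipeline == "A" else 3
        return [rid for rid, f in self.fates.items() if f[k] == KEPT]

    def raw_of(self, pipeline: str, processed_id: str) -> str:
        return self._reverse[pipeline][processed_id]

    def swap(self) -> "ProvenanceDB":
        """Pipeline labels exchanged (A<->B)."""
        return ProvenanceDB(
            {rid: (fb, pb, cb, fa, pa, ca) for rid, (fa, pa, ca, fb, pb, cb) in self.fates.items()}
        )

    # -- persistence -------------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tfate_a\tprocessed_a\tcriteria_a\tfate_b\tprocessed_b\tcriteria_b\n")
            for rid, (fa, pa, ca, fb, pb, cb) in self.fates.items():
                fh.write(
                    f"{rid}\t{fa}\t{pa or ''}\t{','.join(ca)}\t{fb}\t{pb or ''}\t{','.join(cb)}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "ProvenanceDB":
        fates = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                rid, fa, pa, ca, fb, pb, cb = line.rstrip("\n").split("\t")
                fates[rid] = (
                    fa,
                    pa or None,
                    tuple(ca.split(",")) if ca else (),
                    fb,
                    pb or None,
                    tuple(cb.split(",")) if cb else (),
                )
        return cls(fates)


def build_provenance(
    raw_ids,
    outcome_a: Mapping[str, tuple],
    outcome_b: Mapping[str, tuple],
    processed_a: Mapping[str, str] | None = None,
    processed_b: Mapping[str, str] | None = None,
) -> ProvenanceDB:
    """Assemble the fate map from two pipelines' per-read verdicts.

    ``outcome_a``/``outcome_b`` map read_id -> tuple of failed criteria
    (empty = kept).  ``processed_a``/``processed_b`` optionally map kept
    raw ids to processed ids (defaults to identity).  Any processed read
    whose raw id is unknown is an explicit failure.
    """
    raw_ids = list(raw_ids)
    raw_set = set(raw_ids)
    for name, proc in (("A", processed_a), ("B", processed_b)):
        if proc is not None:
            unknown = [r for r in proc if r not in raw_set]
            if unknown:
                raise ValueError(f"pipeline {name} processed reads with unknown raw ids: {unknown[:5]}")
    fates = {}
    for rid in raw_ids:
        ca = tuple(outcome_a.get(rid, ()))
        cb = tuple(outcome_b.get(rid, ()))
        fa = CULLED if ca else KEPT
        fb = CULLED if cb else KEPT
        pa = (processed_a.get(rid, rid) if processed_a is not None else rid) if fa == KEPT else None
        pb = (processed_b.get(rid, rid) if processed_b is not None else rid) if fb == KEPT else None
        fates[rid] = (fa, pa, ca, fb, pb, cb)
    return ProvenanceDB(fates)


def overlap_stats(db: ProvenanceDB) -> OverlapReport:
    """Joint-fate cell counts and the two kept-set percentages.

    Asserts the partition property: the four cells sum to the raw total.
    """
    kb = oa = ob = cb = 0
    for fa, _, _, fb, _, _ in db.fates.values():
        if fa == KEPT and fb == KEPT:
            kb += 1
        elif fa == KEPT:
            oa += 1
        elif fb == KEPT:
            ob += 1
        else:
            cb += 1
    assert kb + oa + ob + cb == len(db), "overlap cells must partition the raw read set"
    kept_a, kept_b = kb + oa, kb + ob
    return OverlapReport(
        kept_both=kb,
        kept_only_a=oa,
        kept_only_b=ob,
        culled_both=cb,
        pct_a_only=100.0 * oa / kept_a if kept_a else None,
        pct_b_only=100.0 * ob / kept_b if kept_b else None,
    )
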