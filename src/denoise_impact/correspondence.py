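"""OTU correspondence between pipelines via shared read provenance.

Two pipelines' OTUs are matched not by sequence similarity but by the
reads they share: a read is *shared* when both pipelines kept it, and a
source OTU's partner distribution counts where its shared reads landed in
the other pipeline's partition.  An OTU with no shared reads at all is
*inconsistent* — it is built entirely from reads the other pipeline
culled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .otu import OTUPartition
from .provenance import KEPT, ProvenanceDB

__all__ = ["CorrespondenceTable", "OTUCorrespondence", "build_correspondence", "correspondence_summary"]


@dataclass
class OTUCorrespondence:
    otu_id: str
    total_reads: int
    shared_reads: int
    partners: dict[str, int]  # other-pipeline OTU -> shared-read count
    best_partner: str | None
    best_fraction: float | None  # best partner's share of shared reads
    n_partners: int
    inconsistent: bool


@dataclass
class CorrespondenceTable:
    """Directional (source -> other) correspondence, one row per source OTU."""

    rows: dict[str, OTUCorrespondence]

    @property
    def total_shared(self) -> int:
        return sum(r.shared_reads for r in self.rows.values())

    @property
    def n_inconsistent(self) -> int:
        return sum(r.inconsistent for r in self.rows.values())


def build_correspondence(
    part_a: OTUPartition,
    part_b: OTUPartition,
    db: ProvenanceDB,
    a_is: str = "A",
    best_fraction_of: str = "shared",
    partner_sizes: dict[str, int] | None = None,
) -> CorrespondenceTable:
    """Partner distribution of each A-side OTU over B-side OTUs.

    ``best_fraction_of`` selects the denominator of ``best_fraction``:
    the OTU's shared reads (default) or its total membership
    (``"total"``) — the published figure is ambiguous between the two.
    Best-partner ties go to the larger partner OTU, then lexicographic id.

    Raises ValueError if a read kept by both pipelines is missing from a
    partition.
    """
    b_is = "B" if a_is == "A" else "A"
    ia, ib = (0, 3) if a_is == "A" else (3, 0)
    b_of_read = part_b.read_to_otu()
    b_sizes = partner_sizes or part_b.sizes()
    rows: dict[str, OTUCorrespondence] = {}
    for oid, members in part_a.otus.items():
        partners: dict[str, int] = {}
        shared = 0
        for rid in members:
            raw = db.raw_of(a_is, rid)
            fate = db.fates[raw]
            if fate[ib] != KEPT:
                continue
            shared += 1
            pid = fate[ib + 1]
            boid = b_of_read.get(pid)
            if boid is None:
                raise ValueError(
                    f"read {raw} kept by both pipelines but absent from partition {b_is}"
                )
            partners[boid] = partners.get(boid, 0) + 1
        if partners:
            best = max(partners, key=lambda k: (partners[k], b_sizes.get(k, 0), _neg(k)))
            denom = shared if best_fraction_of == "shared" else len(members)
            bf = partners[best] / denom
        else:
            best, bf = None, None
        rows[oid] = OTUCorrespondence(
            otu_id=oid,
            total_reads=len(members),
            shared_reads=shared,
            partners=partners,
            best_partner=best,
            best_fraction=bf,
            n_partners=len(partners),
            inconsistent=shared == 0,
        )
    table = CorrespondenceTable(rows=rows)
    assert all(
        sum(r.partners.values()) == r.shared_reads and (r.inconsistent == (r.shared_reads == 0))
        for r in rows.values()
    )
    return table


class _neg(str):
    """Reverses lexicographic order inside a max() key."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


def correspondence_summary(table: CorrespondenceTable, min_membership: int = 0) -> dict:
    """Counts and percentages of partner dispersion and inconsistency.

    ``min_membership`` optionally restricts the partner-dispersion
    percentages to OTUs above a membership size (the published figure
    used > 50 reads); inconsistency counts always cover all OTUs.
    The identity (inconsistent + shared-containing == total) is asserted.
    """
    rows = list(table.rows.values())
    total = len(rows)
    inconsistent = sum(r.inconsistent for r in rows)
    with_shared = total - inconsistent
    singleton_inconsistent = sum(r.inconsistent and r.total_reads == 1 for r in rows)
    assert inconsistent + with_shared == total
    sel = [r for r in rows if not r.inconsistent and r.total_reads > min_membership]
    n = len(sel)
    one = sum(r.n_partners == 1 for r in sel)
    le3 = sum(r.n_partners <= 3 for r in sel)
    gt3 = sum(r.n_partners > 3 for r in sel)
    return {
        "total_otus": total,
        "otus_with_shared_reads": with_shared,
        "inconsistent_otus": inconsistent,
        "inconsistent_singletons": singleton_inconsistent,
        "n_considered": n,
        "pct_single_partner": 100.0 * one / n if n else None,
        "pct_le3_partners": 100.0 * le3 / n if n else None,
        "pct_gt3_partners": 100.0 * gt3 / n if n else None,
        "total_shared_reads": table.total_shared,
    }
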