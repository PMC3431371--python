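"""Ground-truth communities and 454-style noisy amplicon reads.

The generator emulates the structure of a pyrosequencing amplicon survey:
a community of short 16S-like template sequences with a lognormal
rank-abundance distribution, sampled across a factorial design (host
species x plant-richness level x replicate), sequenced with a clustered
error model in which a minority of "error-rich" reads carry most of the
per-base errors, indels concentrate inside homopolymer runs, a fraction
of reads terminate prematurely (the dominant cause of length culls in
flow-based sequencing), and a small fraction of reads are single-breakpoint
chimeras of two templates.  Every read records its truth (source template
or chimera parents, injected error positions), so each downstream pipeline
stage can be validated without external data.

Determinism: one master seed on the design; per-sample generators are
derived with ``numpy.random.SeedSequence(seed, spawn_key=(sample_index,))``
(fixed arithmetic), so each sample is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._util import BASES, bytes_to_seq, max_run_length, run_mask, seq_to_bytes, softmax

__all__ = [
    "DEFAULT_PRIMER",
    "TaxonTemplate",
    "SampleFactors",
    "SimulationDesign",
    "NoiseModel",
    "RawRead",
    "RawReadSet",
    "generate_community",
    "simulate_reads",
    "simulate_offtarget_reads",
    "truth_restoring_denoise",
    "write_fasta",
    "write_qual",
    "write_fastq",
    "write_groups",
    "write_truth",
]

#: fixed 5' forward primer prepended to every simulated read
DEFAULT_PRIMER = "CATGCTGCCTCCCGTAGGAG"

HOST_SPECIES = ("host_A", "host_B", "host_C", "host_D")
RICHNESS_LEVELS = (1, 4, 8, 16, 32)
REPLICATES = (1, 2, 3)


@dataclass(frozen=True)
class TaxonTemplate:
    taxon_id: str
    sequence: str
    relative_abundance: float


@dataclass(frozen=True)
class SampleFactors:
    sample_id: str
    host_species: str
    plant_richness: int
    replicate: int


@dataclass
class SimulationDesign:
    """Sampling design plus community-perturbation knobs.

    ``sample_sigma`` is the SD of per-sample lognormal abundance noise,
    ``host_sigma`` the SD of a fixed per-host-species abundance tilt, and
    ``richness_evenness_gain`` scales community evenness up with
    log2(plant richness) so the diversity ANOVA has structure to find.
    """

    samples: list[SampleFactors]
    reads_per_sample: int = 3500
    seed: int = 0
    sample_sigma: float = 0.4
    host_sigma: float = 0.3
    richness_evenness_gain: float = 0.15

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be non-negative")

    @classmethod
    def full_crossing(
        cls,
        reads_per_sample: int = 3500,
        seed: int = 0,
        hosts: Sequence[str] = HOST_SPECIES,
        richness: Sequence[int] = RICHNESS_LEVELS,
        replicates: Sequence[int] = REPLICATES,
        **kwargs,
    ) -> "SimulationDesign":
        """The study layout: 4 hosts x 5 richness levels x 3 replicates = 60."""
        samples = [
            SampleFactors(f"{h}.r{r}.rep{k}", h, r, k)
            for h in hosts
            for r in richness
            for k in replicates
        ]
        return cls(samples=samples, reads_per_sample=reads_per_sample, seed=seed, **kwargs)


@dataclass
class NoiseModel:
    """454-style clustered error model.

    Per-base substitution/indel probabilities apply to ordinary reads; a
    ``bad_read_fraction`` of reads have all rates multiplied by
    ``bad_read_multiplier`` (errors cluster in a minority of reads), and
    indel probability is further multiplied by ``homopolymer_multiplier``
    inside homopolymer runs of length >= 3.  Defaults give an overall
    per-base error rate of ~0.2% with ~21% of reads carrying at least one
    error.  ``truncated_fraction`` of reads stop early (length uniform in
    [truncated_min_length, full length)), emulating short flow-terminated
    reads.  Quality scores are Phred-like integers ~ N(quality_mean_good, sd)
    at correct positions and N(quality_mean_error, sd) at injected errors,
    clamped to [2, 40].  Each injected error sits inside a low-quality
    stretch of ``low_quality_halo`` bases to either side, mirroring real
    flow-based data where errors concentrate in low-quality read regions;
    this is what makes the mean-quality screen selective for error-rich
    reads rather than blind to them.
    """

    substitution_rate: float = 7.5e-4
    indel_rate: float = 8.0e-5
    homopolymer_multiplier: float = 5.0
    bad_read_fraction: float = 0.30
    bad_read_multiplier: float = 5.7
    chimera_rate: float = 0.005
    quality_mean_good: float = 35.0
    quality_mean_error: float = 15.0
    quality_sd: float = 5.0
    ambiguous_rate: float = 1.0e-4
    truncated_fraction: float = 0.30
    truncated_min_length: int = 40
    low_quality_halo: int = 15
    flow_noise_sd: float = 12.0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "bad_read_fraction", "chimera_rate", "ambiguous_rate", "truncated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.homopolymer_multiplier < 1 or self.bad_read_multiplier < 1:
            raise ValueError("multipliers must be >= 1")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(
            substitution_rate=0.0,
            indel_rate=0.0,
            chimera_rate=0.0,
            ambiguous_rate=0.0,
            truncated_fraction=0.0,
        )

    def expected_error_rate(self) -> float:
        """Expected per-base injected-error rate (homopolymer effect excluded)."""
        mix = 1.0 - self.bad_read_fraction + self.bad_read_fraction * self.bad_read_multiplier
        return (self.substitution_rate + self.indel_rate + self.ambiguous_rate) * mix


@dataclass(slots=True)
class RawRead:
    read_id: str
    sample_id: str
    bases: str
    quality: np.ndarray  # int16, same length as bases
    true_taxon: str | None  # template id, or None for chimeras
    chimera_parents: tuple[str, str] | None
    error_positions: list[int]  # coordinates of the noise-free read
    truncated: bool = False
    chimera_breakpoint: int | None = None
    flow_noise: float = 0.0  # per-read flow-yield jitter, in flows


class RawReadSet:
    """All simulated reads plus the primer they carry."""

    def __init__(self, reads: list[RawRead], primer: str = DEFAULT_PRIMER):
        ids = set()
        for r in reads:
            if r.read_id in ids:
                raise ValueError(f"duplicate read_id {r.read_id}")
            ids.add(r.read_id)
            if len(r.quality) != len(r.bases):
                raise ValueError(f"quality/bases length mismatch for {r.read_id}")
        self.reads = reads
        self.primer = primer

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def sequences(self) -> dict[str, str]:
        return {r.read_id: r.bases for r in self.reads}

    def sample_of(self) -> dict[str, str]:
        return {r.read_id: r.sample_id for r in self.reads}

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reads:
            seen.setdefault(r.sample_id, None)
        return list(seen)


# ---------------------------------------------------------------------------
# community generation
# ---------------------------------------------------------------------------


def generate_community(
    n_taxa: int,
    abundance_shape: float = 2.0,
    divergence: float = 0.05,
    seed: int = 0,
    length: int = 165,
    max_attempts: int = 500,
    flow_cost_coupling: float = 0.7,
) -> list[TaxonTemplate]:
    """Generate template sequences with a lognormal rank-abundance curve.

    Each template is the common ancestor mutated at ~``divergence`` of its
    sites; candidates are rejected until every pairwise distance is at
    least ``divergence`` (and above the 1% identity floor, so single-base
    preclustering can never merge two distinct taxa).  Homopolymer runs in
    templates are capped at 6 so no true sequence trips the homopolymer
    screen.  Deterministic given ``seed``.

    ``flow_cost_coupling`` (0..1) correlates a template's flow cost (the
    pyrosequencing flows needed to read it; see :func:`flows_needed`) with
    its abundance rank: the study this generator emulates observed that
    flow-length culling during denoising disproportionately reduced the
    membership of the most abundant phylotypes, flattening the
    rank-abundance distribution — i.e. its dominant organisms were
    flow-expensive.  Set to 0 for flow-neutral abundances.

    Raises
    ------
    ValueError
        If ``n_taxa`` templates at the requested divergence cannot be
        placed within ``max_attempts`` tries each (infeasible geometry is
        an explicit failure, never a silent relaxation).
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not 0.0 < divergence < 0.5:
        raise ValueError("divergence must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    # pin the amplicon's flow usage to a standard band so the flow-length
    # screen always sits in the same place relative to the community
    # (real amplicon designs target a sequencing budget the same way)
    target = min(150, length)
    for _ in range(200):
        ancestor = _random_sequence(rng, length)
        if 214 <= flows_needed(bytes_to_seq(ancestor), target) <= 224:
            break
    floor_diffs = int(np.floor(0.01 * length)) + 1  # identity < 99%
    min_diffs = max(int(np.ceil(divergence * length)), floor_diffs)
    mu = max(divergence, min_diffs / length)

    accepted: list[np.ndarray] = []
    seqs: list[str] = []
    acc_mat: np.ndarray | None = None
    for _ in range(n_taxa):
        for attempt in range(max_attempts):
            cand = _mutate(rng, ancestor, mu)
            s = bytes_to_seq(cand)
            if max_run_length(s) > 6:
                continue
            # substitution-only templates: aligned distance is within two
            # end-realignment columns of Hamming, so requiring Hamming >=
            # min_diffs + 2 guarantees the aligned floor
            if acc_mat is not None:
                h = (acc_mat != cand).sum(axis=1)
                if int(h.min()) < min_diffs + 2:
                    continue
            accepted.append(cand)
            seqs.append(s)
            acc_mat = np.stack(accepted)
            break
        else:
            raise ValueError(
                f"could not place {n_taxa} templates at divergence {divergence} "
                f"and length {length}; community is infeasible"
            )

    z = rng.standard_normal(n_taxa)
    ab = np.sort(np.exp(abundance_shape * z))[::-1]
    ab /= ab.sum()
    if n_taxa > 1 and flow_cost_coupling > 0:
        fcost = np.array([flows_needed(s, min(150, length)) for s in seqs])
        zf = (fcost - fcost.mean()) / (fcost.std() or 1.0)
        # winsorize: dominant taxa are moderately flow-expensive, so a flow
        # screen thins them partially — it must never wipe a community out
        zf = np.clip(zf, -1.2, 1.2)
        blend = flow_cost_coupling * zf + (1.0 - flow_cost_coupling) * rng.standard_normal(n_taxa)
        seq_order = np.argsort(-blend)  # most flow-expensive first
    else:
        seq_order = np.arange(n_taxa)
    return [
        TaxonTemplate(f"taxon_{rank + 1:04d}", seqs[int(i)], float(ab[rank]))
        for rank, i in enumerate(seq_order)
    ]


def _random_sequence(rng: np.random.Generator, length: int, max_run: int = 5) -> np.ndarray:
    arr = rng.choice(BASES, size=length)
    # break runs longer than max_run
    changed = True
    while changed:
        changed = False
        run = 1
        for i in range(1, length):
            run = run + 1 if arr[i] == arr[i - 1] else 1
            if run > max_run:
                arr[i] = rng.choice(BASES[BASES != arr[i]])
                run = 1
                changed = True
    return arr


def _mutate(rng: np.random.Generator, ancestor: np.ndarray, mu: float) -> np.ndarray:
    n = ancestor.size
    k = max(1, rng.binomial(n, mu))
    pos = rng.choice(n, size=min(k, n), replace=False)
    out = ancestor.copy()
    for p in pos:
        out[p] = rng.choice(BASES[BASES != out[p]])
    return out


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    templates: Sequence[TaxonTemplate],
    design: SimulationDesign,
    noise: NoiseModel,
    primer: str = DEFAULT_PRIMER,
) -> RawReadSet:
    """Simulate noisy reads for every sample in the design.

    Per-sample community composition is drawn from the template abundances
    perturbed by the design's sample/host/richness factors; chimeras join a
    prefix of one template to the suffix of another at a uniform breakpoint;
    quality scores are lower at injected-error positions.
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    master = np.random.SeedSequence(design.seed)
    effects_rng = np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(0xE0FF,)))
    hosts = sorted({s.host_species for s in design.samples})
    host_tilt = {h: effects_rng.normal(0.0, design.host_sigma, len(templates)) for h in hosts}
    log_ab = np.log(np.array([t.relative_abundance for t in templates]))

    reads: list[RawRead] = []
    for idx, sf in enumerate(design.samples):
        rng = np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(idx + 1,)))
        p = _sample_composition(log_ab, sf, host_tilt, design, rng)
        reads.extend(
            _simulate_sample(templates, sf.sample_id, design.reads_per_sample, p, noise, primer, rng)
        )
    return RawReadSet(reads, primer=primer)


def _sample_composition(log_ab, sf, host_tilt, design, rng) -> np.ndarray:
    scale = 1.0 - design.richness_evenness_gain * np.log2(max(sf.plant_richness, 1)) / 5.0
    la = (log_ab - log_ab.mean()) * scale
    la = la + host_tilt[sf.host_species]
    la = la + rng.normal(0.0, design.sample_sigma, la.size)
    return softmax(la)


def _simulate_sample(templates, sample_id, n_reads, p, noise, primer, rng) -> list[RawRead]:
    if n_reads == 0:
        return []
    tpl_bytes = [seq_to_bytes(primer + t.sequence) for t in templates]
    tpl_hp = [run_mask(b) for b in tpl_bytes]
    n_primer = len(primer)

    is_chimera = rng.random(n_reads) < noise.chimera_rate
    taxon_idx = rng.choice(len(templates), size=n_reads, p=p)
    is_bad = rng.random(n_reads) < noise.bad_read_fraction
    is_trunc = rng.random(n_reads) < noise.truncated_fraction

    out: list[RawRead] = []
    for i in range(n_reads):
        if is_chimera[i] and len(templates) >= 2:
            a = taxon_idx[i]
            b = rng.choice(len(templates), p=p)
            while b == a:
                b = rng.choice(len(templates), p=p)
            la, lb = len(templates[a].sequence), len(templates[b].sequence)
            bp = int(rng.integers(20, min(la, lb) - 20))
            base = np.concatenate((tpl_bytes[a][: n_primer + bp], seq_to_bytes(templates[b].sequence[bp:])))
            hp = run_mask(base)
            truth, parents, breakpoint = None, (templates[a].taxon_id, templates[b].taxon_id), bp
        else:
            a = taxon_idx[i]
            base = tpl_bytes[a]
            hp = tpl_hp[a]
            truth, parents, breakpoint = templates[a].taxon_id, None, None

        mult = noise.bad_read_multiplier if is_bad[i] else 1.0
        L = base.size
        u = rng.random(L)
        p_sub = noise.substitution_rate * mult
        p_amb = noise.ambiguous_rate * mult
        p_ind = noise.indel_rate * mult * np.where(hp, noise.homopolymer_multiplier, 1.0)
        sub_pos = np.flatnonzero(u < p_sub)
        amb_pos = np.flatnonzero((u >= p_sub) & (u < p_sub + p_amb))
        ind_pos = np.flatnonzero((u >= p_sub + p_amb) & (u < p_sub + p_amb + p_ind))

        seq = base.copy()
        for pos in sub_pos:
            seq[pos] = rng.choice(BASES[BASES != seq[pos]])
        seq[amb_pos] = ord("N")
        err_pos = sorted(set(sub_pos.tolist()) | set(amb_pos.tolist()) | set(ind_pos.tolist()))

        if ind_pos.size:
            parts = seq.tolist()
            for pos in sorted(ind_pos.tolist(), reverse=True):
                if rng.random() < 0.5:
                    parts.insert(pos, parts[pos])  # homopolymer-style duplication
                else:
                    del parts[pos]
            seq = np.array(parts, dtype=np.uint8)

        if is_trunc[i]:
            tlen = int(rng.integers(noise.truncated_min_length, max(noise.truncated_min_length + 1, L - n_primer)))
            seq = seq[: n_primer + tlen]

        Lr = seq.size
        q = rng.normal(noise.quality_mean_good, noise.quality_sd, Lr)
        epos = [e for e in err_pos if e < Lr]
        if epos:
            halo = np.zeros(Lr, dtype=bool)
            for e in epos:
                halo[max(0, e - noise.low_quality_halo) : e + noise.low_quality_halo + 1] = True
            nh = int(halo.sum())
            q[halo] = rng.normal(noise.quality_mean_error, noise.quality_sd, nh)
        quality = np.clip(np.rint(q), 2, 40).astype(np.int16)

        out.append(
            RawRead(
                read_id=f"{sample_id}_{i:05d}",
                sample_id=sample_id,
                bases=bytes_to_seq(seq),
                quality=quality,
                true_taxon=truth,
                chimera_parents=parents,
                error_positions=epos,
                truncated=bool(is_trunc[i]),
                chimera_breakpoint=breakpoint,
                flow_noise=float(rng.normal(0.0, noise.flow_noise_sd)) if noise.flow_noise_sd else 0.0,
            )
        )
    return out


def flows_needed(seq: str, n_bases: int, cycle: str = "TACG") -> float:
    """Pyrosequencing flows required to read the first ``n_bases`` of seq.

    The sequencer cycles through ``cycle``; each flow reads an entire
    homopolymer run of the flowed base.  Flow yield therefore depends on
    sequence composition: homopolymer-rich sequences yield more bases per
    flow.  Returns ``inf`` when the sequence is shorter than ``n_bases``.
    Ambiguous characters are treated as 'A'.
    """
    if len(seq) < n_bases:
        return float("inf")
    pos_of = {c: k for k, c in enumerate(cycle)}
    a = np.array([pos_of.get(c, 0) for c in seq[:n_bases]], dtype=np.int64)
    # run starts; each flow reads a whole homopolymer run of the flowed base
    starts = np.concatenate(([0], np.flatnonzero(a[1:] != a[:-1]) + 1))
    p = a[starts]
    deltas = ((np.diff(p) - 1) % len(cycle)) + 1
    return float(p[0] + 1 + deltas.sum())


def simulate_offtarget_reads(
    decoys: Sequence[TaxonTemplate],
    sample_ids: Sequence[str],
    n_reads: int,
    noise: NoiseModel,
    seed: int,
    primer: str = DEFAULT_PRIMER,
) -> list[RawRead]:
    """Reads from off-target (non-community) templates, spread over samples."""
    if n_reads == 0 or not decoys:
        return []
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x0FF7,)))
    p = np.array([d.relative_abundance for d in decoys])
    p = p / p.sum()
    picks = rng.choice(len(sample_ids), size=n_reads)
    out: list[RawRead] = []
    for j in range(n_reads):
        sid = sample_ids[picks[j]]
        sub = _simulate_sample(decoys, sid, 1, p, noise, primer, rng)[0]
        sub.read_id = f"{sid}_ot{j:04d}"
        out.append(sub)
    return out


def truth_restoring_denoise(
    rawset: RawReadSet, templates: Sequence[TaxonTemplate]
) -> dict[str, str]:
    """Oracle corrector: maps each read back to its true (post-primer) sequence.

    Chimeric reads are restored to the exact parent mosaic.  Used to test
    that the implied-error machinery recovers a configured simulation rate.
    """
    by_id = {t.taxon_id: t.sequence for t in templates}
    out: dict[str, str] = {}
    for r in rawset.reads:
        if r.true_taxon is not None:
            out[r.read_id] = by_id[r.true_taxon]
        else:
            pa, pb = r.chimera_parents
            bp = r.chimera_breakpoint
            out[r.read_id] = by_id[pa][:bp] + by_id[pb][bp:]
    return out


# ---------------------------------------------------------------------------
# flat-file writers
# ---------------------------------------------------------------------------


def write_fasta(path, seqs: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in seqs:
            fh.write(f">{rid}\n{seq}\n")


def write_qual(path, quals: Iterable[tuple[str, np.ndarray]]) -> None:
    with open(path, "w") as fh:
        for rid, q in quals:
            fh.write(f">{rid}\n{' '.join(str(int(v)) for v in q)}\n")


def write_fastq(path, reads: Iterable[RawRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qstr = "".join(chr(int(v) + 33) for v in r.quality)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qstr}\n")


def write_groups(path, reads: Iterable[RawRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.read_id}\t{r.sample_id}\n")


def write_truth(path, reads: Iterable[RawRead]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttaxon_id\terror_positions\tchimera\tparents\ttruncated\n")
        for r in reads:
            parents = f"{r.chimera_parents[0]},{r.chimera_parents[1]}" if r.chimera_parents else ""
            fh.write(
                f"{r.read_id}\t{r.true_taxon or ''}\t"
                f"{','.join(map(str, r.error_positions))}\t"
                f"{int(r.chimera_parents is not None)}\t{parents}\t{int(r.truncated)}\n"
            )
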