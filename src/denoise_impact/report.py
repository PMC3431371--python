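"""End-to-end pipeline comparison and Table-1-style accounting.

Orchestrates: simulate -> screen/denoise -> provenance -> implied error
rate -> OTU clustering -> correspondence -> diversity -> report.  The
standard arm culls low-quality reads, trims, preclusters single-base
variants and removes chimeras/off-target reads; the corrector arm culls
on primer/flow-length, rewrites survivors to group consensi, and applies
the same post screens.  Every arithmetic identity of the accounting table
(net yield, inconsistent-OTU subtraction, rarefied row sums) is asserted
on every run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import run_mask, seq_to_bytes
from .correspondence import build_correspondence, correspondence_summary
from .diversity import (
    alpha_diversity,
    build_nj_tree,
    faith_pd,
    ks_two_sample,
    paired_t,
    pooled_evenness,
    rank_shift,
    rarefy,
    two_way_anova,
)
from .error_rate import error_profile, regress
from .otu import (
    OTUPartition,
    cluster_uniques,
    dereplicate,
    distance_matrix,
    otu_table,
    write_list_file,
    write_shared_file,
)
from .provenance import build_provenance, overlap_stats
from .screening import (
    DenoiserParams,
    ScreeningCriteria,
    best_reference_identity,
    flag_chimeras,
    mock_denoise,
    precluster,
    screen_reads,
    trim_reads,
)
from .synthetic import (
    DEFAULT_PRIMER,
    NoiseModel,
    RawReadSet,
    SimulationDesign,
    generate_community,
    simulate_offtarget_reads,
    simulate_reads,
)

__all__ = ["PipelineConfig", "AccountingTable", "ComparisonReport", "accounting", "run_pipeline_comparison"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Configuration of one full comparison run.

    The defaults are the study conditions the synthetic data emulates:
    60 samples (4 hosts x 5 richness levels x 3 replicates), 3,500 reads
    per sample, ~0.2% clustered per-base error.  ``rarefaction_depth``
    is scaled to the synthetic per-sample retention (the corrector arm
    keeps roughly 1,700-2,100 reads per sample) the way the study's
    3,000-read depth was scaled to its ~4,000-read samples.
    """

    n_taxa: int = 600
    abundance_shape: float = 1.6
    divergence: float = 0.05
    template_length: int = 165
    reads_per_sample: int = 3500
    seed: int = 0
    hosts: tuple = ("host_A", "host_B", "host_C", "host_D")
    richness_levels: tuple = (1, 4, 8, 16, 32)
    replicates: tuple = (1, 2, 3)
    noise: NoiseModel = field(default_factory=NoiseModel)
    denoiser: DenoiserParams = field(default_factory=DenoiserParams)
    primer: str = DEFAULT_PRIMER
    min_length: int = 120
    max_ambiguous: int = 0
    max_homopolymer: int = 6
    min_avg_quality: float = 25.0
    min_reference_identity: float = 0.75
    trim_length: int = 150
    cutoff: float = 0.03
    rarefaction_depth: int = 800
    n_decoys: int = 2
    decoy_reads: int = 24
    chimera_identity: float = 0.99
    compute_phylogenetic: bool = True
    compute_anova: bool = True
    compute_error_profile: bool = True
    compute_correspondence: bool = True

    def criteria(self) -> ScreeningCriteria:
        return ScreeningCriteria(
            primer=self.primer,
            min_length=self.min_length,
            max_ambiguous=self.max_ambiguous,
            max_homopolymer=self.max_homopolymer,
            min_avg_quality=self.min_avg_quality,
            min_reference_identity=self.min_reference_identity,
            trim_length=self.trim_length,
        )

    def design(self) -> SimulationDesign:
        return SimulationDesign.full_crossing(
            reads_per_sample=self.reads_per_sample,
            seed=self.seed,
            hosts=self.hosts,
            richness=self.richness_levels,
            replicates=self.replicates,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        noise = NoiseModel(**raw.pop("noise", {}))
        den = DenoiserParams(**raw.pop("denoiser", {}))
        for key in ("hosts", "richness_levels", "replicates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(noise=noise, denoiser=den, **raw)

    def to_yaml(self, path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(d)), fh)


@dataclass
class AccountingTable:
    """Table-1-style read accounting for one arm."""

    pipeline: str
    initial: int
    failure_counts: dict[str, int]
    dropped_first_stage: int
    remainder: int
    uniques_initial: int
    uniques_after_precluster: int | None
    chimera_reads: int
    off_target_reads: int
    net_yield: int
    reads_per_sample_mean: float
    reads_per_sample_se: float
    unique_reads_final: int
    otus: int
    otus_with_shared_reads: int | None = None
    rarefied_otus_mean: float | None = None
    rarefied_otus_se: float | None = None

    def __post_init__(self) -> None:
        if self.net_yield != self.remainder - self.chimera_reads - self.off_target_reads:
            raise AssertionError(
                f"net yield identity violated: {self.net_yield} != "
                f"{self.remainder} - {self.chimera_reads} - {self.off_target_reads}"
            )
        if self.dropped_first_stage > sum(self.failure_counts.values()):
            raise AssertionError("dropped reads exceed summed per-criterion failures")
        if self.initial - self.dropped_first_stage != self.remainder:
            raise AssertionError("remainder identity violated")


def accounting(
    pipeline: str,
    n_input: int,
    failure_counts: dict[str, int],
    n_kept_first: int,
    uniques_initial: int,
    uniques_after_precluster: int | None,
    chimera_reads: int,
    off_target_reads: int,
    partition: OTUPartition,
    unique_reads_final: int,
    samples: Sequence[str],
    read_sample: dict[str, str],
    otus_with_shared: int | None = None,
    rarefied_richness: pd.Series | None = None,
) -> AccountingTable:
    """Assemble the accounting table for one arm, asserting its identities."""
    net = n_kept_first - chimera_reads - off_target_reads
    per_sample = pd.Series(
        [s for members in partition.otus.values() for s in (read_sample[r] for r in members)]
    ).value_counts()
    per_sample = per_sample.reindex(list(samples), fill_value=0)
    mean = float(per_sample.mean())
    se = float(per_sample.std(ddof=1) / np.sqrt(len(per_sample))) if len(per_sample) > 1 else 0.0
    assert partition.n_reads == net, "partition must contain exactly the net yield"
    return AccountingTable(
        pipeline=pipeline,
        initial=n_input,
        failure_counts=failure_counts,
        dropped_first_stage=n_input - n_kept_first,
        remainder=n_kept_first,
        uniques_initial=uniques_initial,
        uniques_after_precluster=uniques_after_precluster,
        chimera_reads=chimera_reads,
        off_target_reads=off_target_reads,
        net_yield=net,
        reads_per_sample_mean=mean,
        reads_per_sample_se=se,
        unique_reads_final=unique_reads_final,
        otus=partition.n_otus,
        otus_with_shared_reads=otus_with_shared,
        rarefied_otus_mean=float(rarefied_richness.mean()) if rarefied_richness is not None else None,
        rarefied_otus_se=(
            float(rarefied_richness.std(ddof=1) / np.sqrt(len(rarefied_richness)))
            if rarefied_richness is not None and len(rarefied_richness) > 1
            else None
        ),
    )


# ---------------------------------------------------------------------------
# the two arms
# ---------------------------------------------------------------------------


def _finish_arm(kept_pairs, references, decoy_refs, cfg, do_precluster: bool):
    """Dereplicate -> (precluster) -> chimera flag -> off-target -> cluster.

    Returns per-read late-stage flags plus the partition and counts."""
    uniques0 = dereplicate(kept_pairs)
    n_uniques0 = len(uniques0)
    if do_precluster:
        uniques = precluster(uniques0)
        n_after_pre = len(uniques)
    else:
        uniques, n_after_pre = uniques0, None
    chim = flag_chimeras(uniques, identity=cfg.chimera_identity)
    late_flags: dict[str, tuple[str, ...]] = {}
    survivors = []
    chimera_reads = 0
    for u in uniques:
        if chim[u.representative_id]:
            chimera_reads += u.count
            for r in u.members:
                late_flags[r] = ("chimera",)
        else:
            survivors.append(u)
    # off-target: unique is closer to a decoy reference than to any
    # community reference
    off_reads = 0
    kept_uniques = []
    if decoy_refs and survivors:
        seqs = [u.sequence for u in survivors]
        id_comm = best_reference_identity(seqs, references)
        id_decoy = best_reference_identity(seqs, decoy_refs)
        for u, ic, idk in zip(survivors, id_comm, id_decoy):
            if idk > ic:
                off_reads += u.count
                for r in u.members:
                    late_flags[r] = ("off_target",)
            else:
                kept_uniques.append(u)
    else:
        kept_uniques = survivors
    from .otu import UniqueSequenceSet

    final = UniqueSequenceSet(kept_uniques)
    partition = cluster_uniques(final, cutoff=cfg.cutoff)
    return {
        "partition": partition,
        "late_flags": late_flags,
        "uniques_initial": n_uniques0,
        "uniques_after_precluster": n_after_pre,
        "chimera_reads": chimera_reads,
        "off_target_reads": off_reads,
        "unique_reads_final": len(final),
    }


def run_standard_arm(rawset: RawReadSet, references, decoy_refs, cfg: PipelineConfig):
    criteria = cfg.criteria()
    outcome = screen_reads(rawset, criteria, references=list(references) + list(decoy_refs))
    np_ = len(cfg.primer)
    kept_seqs = {r.read_id: r.bases[np_:] for r in rawset if not outcome.failed[r.read_id]}
    trimmed = trim_reads(list(kept_seqs.items()), criteria.trim_length)
    res = _finish_arm(trimmed, references, decoy_refs, cfg, do_precluster=True)
    flags = dict(outcome.failed)
    flags.update(res["late_flags"])
    failure_counts = outcome.failure_counts()
    res.update(
        outcome_flags=flags,
        failure_counts=failure_counts,
        n_kept_first=outcome.n_kept,
        processed={rid: seq for rid, seq in trimmed},
    )
    return res


def run_denoise_arm(rawset: RawReadSet, references, decoy_refs, cfg: PipelineConfig):
    corrected, failed, n_changed = mock_denoise(rawset, cfg.denoiser, cfg.primer)
    # post-correction screens (no quality screen: the corrector consumed it)
    flags = dict(failed)
    failure_counts = {"primer": 0, "length": 0, "ambiguous": 0, "homopolymer": 0, "alignment": 0}
    for f in failed.values():
        for c in f:
            failure_counts[c] += 1
    survivors = {}
    idents = None
    ids_list = [rid for rid, fl in failed.items() if not fl]
    seq_list = [corrected[rid] for rid in ids_list]
    if cfg.min_reference_identity is not None and seq_list:
        idents = best_reference_identity(seq_list, list(references) + list(decoy_refs))
    from ._util import max_run_length

    for k, rid in enumerate(ids_list):
        seq = seq_list[k]
        fl = []
        if sum(seq.count(c) for c in "NRYSWKMBDHV") > cfg.max_ambiguous:
            fl.append("ambiguous")
        if max_run_length(seq) > cfg.max_homopolymer:
            fl.append("homopolymer")
        if idents is not None and idents[k] < cfg.min_reference_identity:
            fl.append("alignment")
        if fl:
            flags[rid] = tuple(fl)
            for c in fl:
                failure_counts[c] += 1
        else:
            survivors[rid] = seq
    res = _finish_arm(list(survivors.items()), references, decoy_refs, cfg, do_precluster=False)
    flags.update(res["late_flags"])
    res.update(
        outcome_flags=flags,
        failure_counts=failure_counts,
        n_kept_first=len(survivors),
        processed=survivors,
        corrected=corrected,
        n_changed=n_changed,
    )
    return res


# ---------------------------------------------------------------------------
# full comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Machine-readable result of one full comparison run."""

    schema_version: int
    config: dict
    overlap: dict
    error: dict
    regressions: dict
    accounting: dict
    correspondence: dict
    diversity: dict
    tests: dict

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=1, default=_jsonify)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "ComparisonReport":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and str(source).endswith(".json") else source
        return cls(**json.loads(text))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline_comparison(config: PipelineConfig | None = None, outdir=None) -> ComparisonReport:
    """Execute the whole comparison; idempotent given the config seed.

    Stage failures abort with the stage name and cause.  When ``outdir``
    is given, the main artifacts (reads, provenance, OTU tables, report)
    are also written there.
    """
    cfg = config or PipelineConfig()
    stage = "simulate"
    try:
        templates = generate_community(
            cfg.n_taxa, cfg.abundance_shape, cfg.divergence, seed=cfg.seed, length=cfg.template_length
        )
        decoys = (
            generate_community(
                cfg.n_decoys, 0.5, min(0.12, 0.49), seed=cfg.seed + 7919, length=cfg.template_length
            )
            if cfg.n_decoys
            else []
        )
        decoys = [dataclasses.replace(d, taxon_id=f"decoy_{k+1:02d}") for k, d in enumerate(decoys)]
        design = cfg.design()
        rawset = simulate_reads(templates, design, cfg.noise, primer=cfg.primer)
        ot = simulate_offtarget_reads(
            decoys, [s.sample_id for s in design.samples], cfg.decoy_reads, cfg.noise, cfg.seed, cfg.primer
        )
        rawset = RawReadSet(rawset.reads + ot, primer=cfg.primer)
        refs = [t.sequence for t in templates]
        decoy_refs = [d.sequence for d in decoys]
        read_sample = rawset.sample_of()
        sample_ids = [s.sample_id for s in design.samples]

        stage = "screen/denoise"
        std = run_standard_arm(rawset, refs, decoy_refs, cfg)
        dnz = run_denoise_arm(rawset, refs, decoy_refs, cfg)

        stage = "provenance"
        db = build_provenance([r.read_id for r in rawset], std["outcome_flags"], dnz["outcome_flags"])
        overlap = overlap_stats(db)

        stage = "error-rate"
        np_ = len(cfg.primer)
        if cfg.compute_error_profile:
            raw_post = {r.read_id: r.bases[np_:] for r in rawset}
            kept_dn = set(db.kept_ids("B"))
            prof = error_profile(
                None,
                raw_post,
                {rid: s for rid, s in dnz["processed"].items() if rid in kept_dn},
                sample_of=read_sample,
            )
            regressions = _error_regressions(prof, rawset, std, np_)
        else:
            prof, regressions = None, {}

        stage = "cluster"
        part_std, part_dn = std["partition"], dnz["partition"]
        table_std = otu_table(part_std, read_sample)
        table_dn = otu_table(part_dn, read_sample)

        stage = "correspond"
        if cfg.compute_correspondence:
            corr_ab = build_correspondence(part_std, part_dn, db, a_is="A")
            corr_ba = build_correspondence(part_dn, part_std, db, a_is="B")
            assert corr_ab.total_shared == corr_ba.total_shared, "shared-read totals must match"
            summ_ab = correspondence_summary(corr_ab)
            summ_ba = correspondence_summary(corr_ba)
        else:
            summ_ab = summ_ba = {"otus_with_shared_reads": None}

        stage = "diversity"
        rare_seed = (cfg.seed + 101) % (2**31)
        rare_std = rarefy(table_std, cfg.rarefaction_depth, seed=rare_seed)
        rare_dn = rarefy(table_dn, cfg.rarefaction_depth, seed=rare_seed)
        alpha_std = alpha_diversity(rare_std.table) if len(rare_std.table) else pd.DataFrame()
        alpha_dn = alpha_diversity(rare_dn.table) if len(rare_dn.table) else pd.DataFrame()
        common = sorted(set(alpha_std.index) & set(alpha_dn.index))
        h_std, e_std, s_std = pooled_evenness(table_std)
        h_dn, e_dn, s_dn = pooled_evenness(table_dn)
        ks = ks_two_sample(
            table_std.sum(axis=0).to_numpy(), table_dn.sum(axis=0).to_numpy()
        )
        tests: dict = {}
        if len(common) >= 2:
            for metric in ("richness", "shannon", "evenness"):
                a = alpha_std.loc[common, metric].to_numpy(dtype=float)
                b = alpha_dn.loc[common, metric].to_numpy(dtype=float)
                ok = ~(np.isnan(a) | np.isnan(b))
                try:
                    t, p = paired_t(a[ok], b[ok])
                    tests[f"paired_t_{metric}"] = {"t": t, "p": p, "n": int(ok.sum())}
                except ValueError as exc:
                    tests[f"paired_t_{metric}"] = {"error": str(exc)}
            shifts, rho = rank_shift(
                alpha_std.loc[common, "shannon"].to_dict(), alpha_dn.loc[common, "shannon"].to_dict()
            )
            tests["shannon_rank_correlation"] = rho
            tests["shannon_max_rank_shift"] = float(shifts.delta.abs().max())

        pd_block = {}
        if cfg.compute_phylogenetic and part_std.rep_sequences and part_dn.rep_sequences:
            stage = "phylogenetic-diversity"
            pd_block = _pd_contrast(part_std, part_dn, rare_std, rare_dn, common, tests)

        anova_block = {}
        if cfg.compute_anova and len(common) >= 8:
            stage = "anova"
            meta = {
                s.sample_id: {"plant_richness": s.plant_richness, "host_species": s.host_species}
                for s in design.samples
            }
            for label, alpha in (("standard", alpha_std), ("denoised", alpha_dn)):
                df = alpha.loc[common, ["shannon"]].copy()
                df["plant_richness"] = [meta[s]["plant_richness"] for s in common]
                df["host_species"] = [meta[s]["host_species"] for s in common]
                try:
                    av = two_way_anova(df)
                    anova_block[label] = {
                        "table": av.table.reset_index().rename(columns={"index": "source"}).to_dict("records"),
                        "warnings": av.warnings,
                    }
                except ValueError as exc:
                    anova_block[label] = {"error": str(exc)}

        stage = "report"
        acc_std = accounting(
            "standard", len(rawset), std["failure_counts"], std["n_kept_first"],
            std["uniques_initial"], std["uniques_after_precluster"], std["chimera_reads"],
            std["off_target_reads"], part_std, std["unique_reads_final"], sample_ids, read_sample,
            otus_with_shared=summ_ab["otus_with_shared_reads"],
            rarefied_richness=alpha_std["richness"] if len(alpha_std) else None,
        )
        acc_dn = accounting(
            "denoised", len(rawset), dnz["failure_counts"], dnz["n_kept_first"],
            dnz["uniques_initial"], dnz["uniques_after_precluster"], dnz["chimera_reads"],
            dnz["off_target_reads"], part_dn, dnz["unique_reads_final"], sample_ids, read_sample,
            otus_with_shared=summ_ba["otus_with_shared_reads"],
            rarefied_richness=alpha_dn["richness"] if len(alpha_dn) else None,
        )

        report = ComparisonReport(
            schema_version=SCHEMA_VERSION,
            config=json.loads(json.dumps(dataclasses.asdict(cfg), default=_jsonify)),
            overlap=overlap.as_dict(),
            error=(
                {
                    "fraction_unchanged": prof.fraction_unchanged,
                    "mean_distance_changed": prof.mean_distance_changed,
                    "corrections_per_sequence": prof.corrections_per_sequence,
                    "overall_rate": prof.overall_rate,
                    "n_reads": prof.n_reads,
                    "per_sample": prof.per_sample.to_dict("records"),
                }
                if prof is not None
                else {}
            ),
            regressions=regressions,
            accounting={
                "standard": dataclasses.asdict(acc_std),
                "denoised": dataclasses.asdict(acc_dn),
            },
            correspondence=(
                {"standard_to_denoised": summ_ab, "denoised_to_standard": summ_ba}
                if cfg.compute_correspondence
                else {}
            ),
            diversity={
                "rarefaction_depth": cfg.rarefaction_depth,
                "rarefaction_seed": rare_seed,
                "excluded_samples": {"standard": rare_std.excluded_samples, "denoised": rare_dn.excluded_samples},
                "pooled": {
                    "standard": {"shannon": h_std, "evenness": e_std, "otus": s_std},
                    "denoised": {"shannon": h_dn, "evenness": e_dn, "otus": s_dn},
                },
                "per_sample": {
                    "standard": alpha_std.reset_index(names="sample").to_dict("records"),
                    "denoised": alpha_dn.reset_index(names="sample").to_dict("records"),
                },
                "ks_rank_abundance": {"D": ks.d, "p": ks.p_value},
                "phylogenetic": pd_block,
                "anova": anova_block,
            },
            tests=tests,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    if outdir is not None:
        _write_artifacts(outdir, cfg, rawset, db, part_std, part_dn, table_std, table_dn, report)
    return report


def _error_regressions(prof, rawset, std, np_):
    """Per-sample covariate regressions of the implied error rate."""
    per = prof.per_sample.set_index("sample_id") if len(prof.per_sample) else pd.DataFrame()
    out = {}
    if not len(per):
        return out
    hp_runs: dict[str, list[int]] = {}
    qual_culled: dict[str, list[int]] = {}
    for r in rawset:
        arr = seq_to_bytes(r.bases[np_:])
        hp_runs.setdefault(r.sample_id, []).append(int(run_mask(arr).sum()))
        qual_culled.setdefault(r.sample_id, []).append(int("quality" in std["outcome_flags"][r.read_id]))
    for name, cov in (
        ("homopolymer_content", {s: float(np.mean(v)) for s, v in hp_runs.items()}),
        ("fraction_quality_culled", {s: float(np.mean(v)) for s, v in qual_culled.items()}),
    ):
        sids = [s for s in per.index if s in cov]
        try:
            slope, r2, p = regress([cov[s] for s in sids], per.loc[sids, "overall_rate"].to_numpy())
            out[name] = {"slope": slope, "r_squared": r2, "p": p, "n": len(sids)}
        except ValueError as exc:
            out[name] = {"error": str(exc)}
    return out


def _pd_contrast(part_std, part_dn, rare_std, rare_dn, common, tests):
    """Faith's PD per sample on NJ trees of OTU representatives."""
    block = {}
    for label, part, rare in (("standard", part_std, rare_std), ("denoised", part_dn, rare_dn)):
        otus = [o for o in part.otus if o in rare.table.columns]
        seqs = [part.rep_sequences[o] for o in otus]
        if len(seqs) < 2:
            block[label] = {}
            continue
        dm = distance_matrix(seqs)
        dm.ids = otus
        tree = build_nj_tree(dm)
        vals = {}
        for sid, row in rare.table.iterrows():
            present = [o for o in otus if row.get(o, 0) > 0]
            vals[sid] = faith_pd(tree, present) if len(present) >= 2 else 0.0
        block[label] = vals
    if block.get("standard") and block.get("denoised"):
        both = [s for s in common if s in block["standard"] and s in block["denoised"]]
        if len(both) >= 2:
            a = [block["standard"][s] for s in both]
            b = [block["denoised"][s] for s in both]
            try:
                t, p = paired_t(a, b)
                tests["paired_t_faith_pd"] = {"t": t, "p": p, "n": len(both)}
            except ValueError as exc:
                tests["paired_t_faith_pd"] = {"error": str(exc)}
            shifts, rho = rank_shift(
                {s: block["standard"][s] for s in both}, {s: block["denoised"][s] for s in both}
            )
            tests["faith_pd_rank_correlation"] = rho
            tests["faith_pd_max_rank_shift"] = float(shifts.delta.abs().max())
    return {"per_sample": block}


def _write_artifacts(outdir, cfg, rawset, db, part_std, part_dn, table_std, table_dn, report):
    from .synthetic import write_fasta, write_groups, write_truth

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "raw_reads.fasta", ((r.read_id, r.bases) for r in rawset))
    write_groups(out / "raw_reads.groups", rawset)
    write_truth(out / "truth.tsv", rawset)
    db.to_tsv(out / "provenance.tsv")
    write_list_file(out / "standard.list", part_std)
    write_list_file(out / "denoised.list", part_dn)
    write_shared_file(out / "standard.shared", table_std)
    write_shared_file(out / "denoised.shared", table_dn)
    report.to_json(out / "report.json")
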