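# denoise-impact

When the same raw pyrosequencing amplicon reads are processed through an
error-**correcting** pipeline (a denoiser that rewrites probable errors
and keeps the reads) versus a quality-**culling** pipeline (screens that
discard suspect reads outright), the two result tables can support
different biological conclusions — different OTU inventories, different
per-sample diversity, different treatment effects.  `denoise-impact` is a
framework for quantifying that processing impact: it implements both
arms, follows every raw read's fate through each, and compares the arms
on read retention, implied error rates, OTU correspondence, and
diversity statistics.  A synthetic-data module generates ground-truth
communities and 454-style noisy reads, so the entire framework runs —
and is tested — without any external data.

It is written for microbial ecologists and methods developers who want
to ask "would my conclusions survive a different pipeline?" on data they
control.

## What it computes

- **Read provenance and overlap** — for every raw read, its fate
  (kept/culled, with criteria) in both arms; the four-cell overlap
  partition and the share of each arm's kept reads culled by the other.
- **Implied error rate** — the per-nucleotide distance between each read
  and its corrected form: mismatched columns plus internal gap *runs*
  (one per run) on the optimal +1/−1/−2/−1 alignment with free one-sided
  terminal gaps, divided by the shorter length.  Aggregated per sample
  and pooled, and regressed on per-sample covariates.
- **OTUs** — dereplication, single-base preclustering, a two-parent
  mosaic chimera test, and average-neighbor (average-linkage) clustering
  at 3% dissimilarity, scalable to tens of thousands of uniques.
- **OTU correspondence** — arms matched strictly by shared reads:
  partner distributions, best-partner fractions, and *inconsistent*
  OTUs built entirely from reads the other arm culled.
- **Diversity** — rarefaction, richness/Shannon/Pielou evenness/Chao1,
  rank-abundance comparison by two-sample Kolmogorov–Smirnov, Faith's
  phylogenetic diversity on a neighbor-joining tree of OTU
  representatives, paired tests, rank-shift analysis, and a Type III
  two-factor ANOVA of diversity against the sampling design.

See `docs/methods.md` for the models, conventions, defaults, and their
rationale.

## Worked example

```python
from denoise_impact import PipelineConfig, run_pipeline_comparison

cfg = PipelineConfig(seed=1)          # 60 samples x 3,500 reads, ~0.2% error
report = run_pipeline_comparison(cfg)

acc = report.accounting
print("total OTUs     std/dn:", acc["standard"]["otus"], "/", acc["denoised"]["otus"])
print("OTUs/sample    std/dn: %.1f / %.1f" % (
    acc["standard"]["rarefied_otus_mean"], acc["denoised"]["rarefied_otus_mean"]))
pooled = report.diversity["pooled"]
print("evenness       std/dn: %.3f / %.3f" % (
    pooled["standard"]["evenness"], pooled["denoised"]["evenness"]))
print("implied error rate: %.3f%%, unchanged reads: %.1f%%" % (
    100 * report.error["overall_rate"], 100 * report.error["fraction_unchanged"]))
```

Output (seed 1):

```
total OTUs     std/dn: 980 / 753
OTUs/sample    std/dn: 263.9 / 283.2
evenness       std/dn: 0.797 / 0.849
implied error rate: 0.201%, unchanged reads: 77.5%
```

Reading it: the corrector arm ends with **fewer OTUs overall** (error
tails and chimera fragments are corrected away rather than left as rare
spurious clusters) yet **more OTUs per sample after rarefaction** and a
**more even** community — because its culling selectively thins the
dominant, flow-expensive taxa, freeing sampling share for the rare tail.
A fifth of reads are changed by correction, at an implied per-base error
rate near the configured 0.2%.

The same pipeline is available from the shell:

```bash
denoise-impact run --seed 1 --outdir results/run1
denoise-impact simulate --seed 1 --outdir results/sim    # reads + truth only
```

plus per-stage subcommands (`screen`, `denoise-mock`, `cluster`,
`provenance`, `error-rate`, `correspond`, `diversity`, `compare-stats`)
operating on FASTA/FASTQ, groups, list and shared files.

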