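# Methods

`denoise-impact` asks a methods question: when the same raw pyrosequencing
amplicon reads are processed once through an error-*correcting* pipeline
("denoised" arm) and once through a quality-*culling* pipeline ("standard"
arm), how do read retention, implied error rates, OTU structure and the
downstream diversity conclusions change?  The package implements both
arms, a provenance layer that follows every raw read through each, the
statistics that compare them, and a synthetic-data generator that makes
the whole framework testable without external data.

## The two processing arms

**Standard arm** — classic quality screening on each read: exact 5'
primer match, post-primer length ≥ 120 nt, no ambiguous bases,
homopolymer runs ≤ 6, mean quality ≥ 25, and identity ≥ 0.75 to the best
reference sequence.  Survivors are trimmed to 150 nt, dereplicated,
*preclustered* (any unique sequence within edit distance 1 of a more
abundant unique is merged into it, with chain merging in descending
abundance order), screened for chimeras, and cleared of off-target reads.

**Corrector arm** — a deliberately simple consensus corrector stands in
for flowgram-likelihood denoisers (which are out of scope): reads are
culled on primer match and a flow-space length screen, truncated to
150 nt, and then rewritten in two stages that mirror the fine-then-coarse
structure of the real tools.  A fine pass (radius 0.02) rewrites each
read to the consensus of any more abundant unique within the radius that
holds at least `min_cluster_size` = 2 reads; a coarse pass (radius 0.05)
then absorbs leftover near-singleton uniques.  Because absorption always
requires a more abundant partner, genuinely distinct sequences — held
apart by the community's 5% divergence floor — are never erased, while
error tails collapse onto their sources.

The flow-space length screen reflects the one screening difference the
two real pipelines cannot share: the standard arm counts *bases*, a
flowgram pipeline counts *flows*.  `flows_needed` computes, from the
sequence alone, how many flows of the TACG cycle are needed to read the
first 150 bases (a flow reads a whole homopolymer run, so homopolymer-poor
sequences are flow-expensive); a read is kept only if that number is
within the flow budget (default 238) plus the read's own flow-yield
jitter.

## Distance convention

All sequence comparisons use one distance: align the two sequences
globally with +1/−1 match/mismatch, −2 gap open, −1 gap extend, and free
*one-sided* terminal gaps (an overhang may sit on one sequence at each
end); on the score-optimal alignment, count mismatched columns plus
internal gap *runs* (a run of any length counts once), and divide by the
length of the shorter sequence.  Ties among score-optimal alignments are
broken toward fewer gap runs, then fewer mismatches, which pins the
count down deterministically.  `implied_distance` implements this as an
exact dynamic program; it is verified against an independent exhaustive
enumeration of the alignment space for short sequences.

At pipeline scale (10⁴–10⁵ pairwise comparisons and more), the exact DP
is replaced by a fast engine: plain Hamming counts for equal-length
pairs, with an edlib alignment converted to the same convention whenever
a pair may contain indels.  Pairs that can profit from gaps are found by
marking *sequences* that carry a frameshift against their most abundant
neighbor (one bounded alignment per sequence), rather than probing every
pair.  The two engines can differ by one difference on alignment-score
ties near sequence ends (they optimize slightly different objectives);
the property suite asserts agreement within that tolerance and exactness
in the large majority of random pairs.

## OTU clustering

OTUs are average-neighbor (average-linkage) clusters at 3% dissimilarity:
merging proceeds in ascending order of the unweighted mean of all
between-cluster pair distances and stops when the smallest mean exceeds
0.03; a partition labelled 0.03 means the last completed merge was at or
below it.  `average_neighbor_cluster` clusters a full distance matrix
(scipy's average linkage behind the package's interface) and is checked
against a brute-force implementation that recomputes every between-cluster
mean at every step.

`cluster_uniques` scales this to tens of thousands of uniques through an
exact decomposition: a merge at ≤ 0.03 implies at least one sequence pair
at ≤ 0.03, so connected components of the ≤ 0.03 pair graph can be
clustered independently — and each component (one error cloud around a
community member, in practice) is small enough for its complete distance
matrix.  Candidate close pairs come from an 8-mer sharing screen (an
edit operation destroys at most eight overlapping 8-mers); k-mers carried
by many sequences at once (shared ancestry) are routed through a dense
BLAS product because their cost in a sparse product grows quadratically
with their frequency.  Distant truncation pairs inside a component keep a
slightly conservative prefix count; the resulting partitions agree with
the full-matrix route to an adjusted Rand index above 0.98 in the test
suite, with identical behavior wherever the engines agree pair by pair.

## The synthetic study

The generator emulates the structure of a 454-style amplicon survey of a
soil community across a factorial design, with these defaults (chosen
once to match the study conditions the package models, and then left
alone):

| parameter | default | why |
|---|---|---|
| samples | 4 host species × 5 plant-richness levels × 3 replicates = 60 | the study layout |
| reads/sample | 3,500 | desk-scale version of the study's ~6,800 raw reads/sample |
| community | 600 templates, 165 nt, lognormal rank abundance (σ = 1.6), ≥ 5% pairwise divergence | a long rare tail plus dominance, without pairs the 3% cutoff could merge |
| per-base error | substitutions 7.5×10⁻⁴, indels 8×10⁻⁵ (×5 inside homopolymer runs ≥ 3), ambiguity 10⁻⁴; 30% of reads carry 5.7× all rates | overall ≈ 0.2% with ≈ 21% of reads carrying ≥ 1 error, errors clustered in a minority of reads |
| quality model | N(35, 5) at correct positions; N(15, 5) inside a ±15 nt halo of each error; clamped [2, 40] | errors sit in low-quality read regions, making the mean-quality screen selective for error-rich reads rather than blind to them |
| short reads | 30% terminate early, uniform 40..165 nt | the dominant length-screen cull in flow sequencing |
| chimeras | 0.5% of reads, single uniform breakpoint, parents ∝ abundance | the dominant PCR artifact class |
| flow model | ancestor flow cost pinned to 214–224 flows per 150 bases; flow-cost/abundance coupling 0.7 (winsorized at ±1.2 σ); flow budget 238 flows; per-read jitter σ = 12 flows | see below |
| rarefaction depth | 800 (pipeline default; `rarefy` itself defaults to the study's 3,000) | scaled so every sample clears the depth even on heavy-cull seeds |

One master seed drives everything; per-sample generators derive from it
by fixed arithmetic, so each sample is independently reproducible.

**Flow-cost/abundance coupling.**  The study this generator emulates
observed that denoising reduced the *membership of the most abundant*
phylotypes while increasing intermediate ones — its dominant organisms
were evidently vulnerable to the corrector's flow-length cut.  Under
taxon-proportional culling this cannot happen: rarefying both arms to a
fixed depth makes per-sample detection depend only on each taxon's share
of the raw pool, so any read screen that thins all taxa equally leaves
per-sample rarefied richness untouched.  The generator therefore builds
the observed condition in: the ancestor sequence is drawn so the
amplicon's flow usage sits in a standard band (as real amplicon designs
target a sequencing budget), and template sequences are assigned to abundance
ranks so that flow cost correlates with abundance (coupling 0.7), making
the corrector's flow screen selectively thin dominant taxa.  That frees
share for the rare tail, which is what raises per-sample rarefied
richness and evenness in the corrector arm — the study's central
phenomenon.  Setting `flow_cost_coupling=0` removes the mechanism and,
with it, the per-sample richness direction.

**What the generator does not model.**  Flowgram signal intensities
(errors are injected in base space), position-dependent error rates
along the read, PCR amplification bias, barcode/primer artifacts beyond
a fixed prepended primer, and multi-breakpoint chimeras.  Passing tests
therefore show that the *comparison machinery* behaves correctly and
that the study's qualitative phenomenon follows from the modelled
mechanisms — not that those mechanisms are a complete account of real
454 data.

## Statistics

Rarefaction draws without replacement (multivariate hypergeometric) to a
fixed depth, excluding samples below it.  Per-sample alpha diversity:
richness S, Shannon H (natural log), Pielou evenness H/ln S (undefined
at S = 1 and reported missing), bias-corrected Chao1
S + n₁(n₁−1)/(2(n₂+1)) with the classical form as an option.  Pooled
("overall") evenness is computed on the table summed over samples.
Rank-abundance distributions are compared with a two-sample
Kolmogorov–Smirnov test in which each OTU contributes its count as one
observation.  Faith's PD uses a neighbor-joining tree built on OTU
representative sequences (vectorized NJ with negative branch lengths
clamped to zero, the deficit moved to the sister branch) under the
unrooted convention: the PD of a single taxon is 0 and selecting every
leaf sums all branch lengths.  Arm contrasts use classical paired t
tests and Spearman rank correlations of per-sample rankings; treatment
effects are tested with a two-factor fixed-effects ANOVA using Type III
sums of squares via sum-to-zero contrasts, which handles the unbalanced
design left after sample exclusion.

## Numerical and design choices

- Preclustering finds edit-distance-1 neighbors by hashing every
  single-deletion variant (31-bit rolling hashes; collisions verified
  directly); ties between equal counts merge the lexicographically later
  representative into the earlier.
- Chimera flagging tests every breakpoint of a candidate against the
  more abundant sequences: flagged iff both sides match distinct parents
  at ≥ 99% identity while no single parent reaches 99% full-length.
  Parents are limited to the 300 most abundant uniques and candidates of
  unmatched length are never flagged (conservative).
- The corrector compares reads against at most `max_centers` = 2,000
  most abundant uniques; rarer centers cannot absorb reads, which only
  leaves very rare variants uncorrected.
- The denoiser's headline percentages (share of one arm's kept reads
  culled by the other) use each arm's kept set as denominator, and are
  reported as undefined — never zero — when a kept set is empty.
- Zero-variance paired differences, all-zero samples, constant
  regressors, single-level factors and empty factorial cells are all
  explicit errors rather than silent NaNs.

## Problem sizes and runtimes

The default comparison (60 × 3,500 reads, 600 taxa) runs in roughly
2–3 minutes per seed with every analysis enabled, and 70–90 seconds per
seed in the core mode used for the repeated direction-of-effect check
(which skips trees, ANOVA, the error profile and correspondence —
none of which enter that criterion).  The test suite runs the 10-seed
direction check at full scale; all other tests use scaled-down designs
(tens of taxa, hundreds of reads per sample) chosen to exercise every
code path in seconds.

## Known limitations

- The fast distance engine and the exact DP can disagree by one
  difference on score ties; partitions can differ in a handful of
  boundary OTUs as a result.
- `cluster_uniques` treats distant truncation pairs with a prefix count
  rather than a full alignment, a conservative approximation that only
  enters averages already far above the cutoff.
- The corrector stand-in is abundance-greedy consensus, not a
  likelihood model; its corrections are idealized (exact rewrites to the
  local consensus) and its per-read change counts should be read as the
  stand-in's implied errors, not a reconstruction of any specific tool.
- The per-sample "evenness" the framework reports is Pielou's H/ln S,
  which is bounded by 1 by construction; per-sample Shannon H is
  reported alongside it for comparisons with sources that print
  unbounded per-sample values.
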