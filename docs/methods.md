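# Methods

This note documents the models and procedures `triplimeth` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where the design was genuinely
open.  No empirical number appears here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Statistical kernel

All analysis stages share one kernel (`triplimeth.stats`).

**Wilcoxon rank-sum.**  The statistic is the Mann–Whitney U of the first
sample.  When `min(|x|, |y|) ≤ 8` and no tied value spans the two groups,
the p-value comes from the exact permutation distribution, computed by a
subset-sum dynamic program over the pooled mid-ranks — mathematically
identical to enumerating all C(n+m, n) label assignments, which the test
suite verifies against an independent brute-force enumeration.  Otherwise
a normal approximation with tie correction and a 0.5 continuity
correction is used.  The `method` field of every `TestResult` records
which path produced the p-value.

**Wilcoxon signed-rank.**  Zero differences are discarded before ranking
(Wilcoxon's convention); `n_effective` reports the remainder, and the
all-zero case returns p = 1 with a warning rather than an error (no
evidence, not invalid input).  For n ≤ 12 the p-value enumerates all 2ⁿ
sign patterns exactly (ties handled by mid-ranks); above that, the
tie-corrected normal approximation applies.  The 8/12 exactness
thresholds keep the enumerations in the millisecond range.

**ANOVA and t.**  One-way fixed-effects ANOVA with F on (k−1, N−k)
degrees of freedom; the two-group pooled-variance t test satisfies
t² = F, which the suite checks to 1e-9 relative.  Fully degenerate inputs
(zero between- and within-group variance) return F = 0, p = 1.  The
`method` enum gains a `t_distribution` value for the t test, since the
three-value enum used elsewhere has no slot for it.

**Benjamini–Hochberg.**  The step-up formula
q₍ᵢ₎ = min⁠_{j≥i} (p₍ⱼ₎·n/j), capped at 1 and mapped back to input order.
Note that BH is *not* idempotent in general (re-adjusting adjusted
q-values can only inflate them further); the property suite asserts the
correct weaker statement.

## DMR calling

Contexts (CG, CHG, CHH) are analyzed separately.  Per chromosome, 200-bp
windows slide at a 100-bp step (the sliding convention is a half-window
step; both are configurable).  For each replicate, the window level is the
weighted level Σmeth / Σ(meth+unmeth) over context cytosines with coverage
≥ `min_cov` (default 4 reads).  Windows with fewer than `min_sites`
(default 4) qualifying cytosines in **any** replicate are untested — this
is what makes the tested-window denominator well defined.  The two groups
(≥ 2 replicates each) are compared by one-way ANOVA on the per-replicate
window levels; the replicate observation unit is a declared choice, as is
`min_cov`/`min_sites` — none of these is dictated by the procedure's
published outline.  BH runs across all tested windows of the context;
candidates must pass both |Δ of group means| ≥ cutoff (0.5 for CG/CHG,
0.1 for CHH) and q < 0.05.  Overlapping or adjacent (gap ≤ step)
same-direction candidates merge into DMRs; levels are recomputed over the
merged span, p/q are the minima over merged windows, and a merged span
whose recomputed |Δ| falls below the cutoff is dropped so every reported
DMR satisfies its stored thresholds exactly.  Direction is relative to
the first (treatment) group: *hyper* means group A is more methylated.
Both the merged DMRs and the full window table are returned, since either
granularity can be the object of interest.

DMR annotation assigns each DMR to gene body, 2-kb upstream of the TSS,
2-kb downstream of the TTS, TE, or TE-free intergenic space by largest
overlap, with ties broken by that precedence order — making the five
categories a partition.  Gene association uses body ± 2 kb with ≥ 1 bp
overlap, listing a DMR under every gene it touches.

## Metaprofiles

Features are aligned 5′→3′ (minus-strand features flipped), flanks split
into fixed 100-bp bins over ±2 kb, and bodies into 20 equal fractions
(`scaled_body`) or fixed 100-bp bins (`absolute`).  Per-bin levels pool
all covered cytosines of all contributing features (weighted level, so
doubling coverage changes nothing).  Features shorter than the body bin
count are skipped in scaled mode and counted.

Breakpoint profiles use ±8 kb in 200-bp bins around single breakpoint
positions: an insertion is anchored at its POS; deletions, duplications
and inversions contribute POS and END; translocations contribute both
mates.  The significance test pairs, per breakpoint, the weighted level
within ±400 bp of the breakpoint against the outermost 400 bp of its own
flanks (signed-rank across breakpoints); the central/distal widths are
configurable since published profile figures do not define test windows.
Breakpoints within one flank of a contig end are dropped — partial
windows would bias bin means.  Boundary density profiles count
breakpoints per feature per 100-bp bin around each feature boundary
(right boundary flipped so "outside" is always negative), and pair each
feature's boundary-zone count (|offset| ≤ 200 bp) with its distal-zone
count (|offset| > 1800 bp) — equal-width zones, signed-rank across
features.  Density is per feature per bin; no per-bp normalization is
applied.

## Duplicate-gene classification

Genes are ranked 0-based by start within each chromosome (ties by end,
then id).  Homolog pairs become anchors on the rank dot-plot; chaining is
dynamic programming per chromosome pair and orientation with strict rank
monotonicity in both genomes and rank gaps ≤ `max_gap` (default 25),
extracting chains of ≥ `min_anchors` (default 5) greedily without anchor
reuse — MCScanX-like defaults, since no classifier parameters are
published for this analysis.  Same-chromosome anchors within `max_gap`
ranks of the diagonal are excluded from chaining: tandem/proximal arrays
otherwise chain into spurious "blocks", which would contradict the
definition of tandem duplicates as non-syntenic.

Classification precedence: block anchor → `wgt`; else rank-adjacent
same-chromosome paralog → `tandem`; else paralog within `proximal_gap`
(default 10) intervening genes → `proximal`; else any paralog →
`dispersed`; no paralog → `singleton`.  WGT genes join groups by
transitive closure over block anchors; a group's copy number is its count
of distinct loci.  Groups with ≥ 4 loci are reported as-is and excluded
from the 2-copy/3-copy dichotomy unless explicitly folded.

Class-wise expression uses per-gene mean FPKM and the **unpaired**
rank-sum test with BH across class pairs.  Published figure legends cite
the signed-rank (paired) test for these unpaired class comparisons; with
no pairing defined between, say, 3-copy and singleton genes, the unpaired
test is the defensible reading, and this discrepancy is deliberately
documented rather than silently resolved.

## m⁶A profiling

A consensus site must appear at the **same transcript position** with
probability ≥ 0.9 in every replicate (both the threshold — m6anet's
conventional cutoff — and exact-position matching are declared defaults;
a window-matched variant was considered and rejected as
under-determined).  DRACH matching treats T as U and requires
D ∈ {A,G,U}, R ∈ {A,G}, the modified A, C, H ∈ {A,C,U}; the matcher is
verified against brute-force alphabet expansion over all 4⁵ 5-mers.  The
metagene axis concatenates the normalized 5′UTR (10 bins), CDS (20) and
3′UTR (20); sites on transcripts lacking any region are excluded and
counted.  The High/Low-m⁶A expression split assigns, within each
homoeologous group having both kinds of members, modified genes to High
and unmodified to Low, pooling groups for one rank-sum test; a site-count
median split is a possible alternative operationalization but the
membership split is the default.

## Synthetic-data generator

The generator (`triplimeth.synthetic_data`) is first-class, tested code.
One RNG stream per sub-generator derives from the master seed, so outputs
are byte-reproducible and adding a generator never perturbs the others.

**Genome and annotation.**  Uniform-random ACGT sequences; single-exon
genes (1.2–3 kb, UTRs 12%/25% of length) laid out to realize the
duplication plan by construction: tandem mates adjacent in rank, proximal
mates separated by 1–10 intervening genes (inserted only at unit
boundaries so tandem adjacency is never broken), dispersed mates on
different chromosomes with at most 4 pairs per chromosome pair (below the
chaining threshold, so they can never form blocks), and syntenic segments
as order-preserving 10-gene runs copied to 2 or 3 chromosomes with all
copy-pairs emitted in the homolog table.  WGT segments live on three
dedicated chromosomes, small-scale genes on the rest.  TEs are placed in
intergenic space.  An infeasible plan errors before anything is written.

**Methylomes.**  Every cytosine on both strands is extracted from the
actual sequence with its CG/CHG/CHH context.  Site mean = the baseline of
the covering feature class (TE class overrides genic overrides
intergenic); the per-site, per-replicate methylation probability is
Beta(mν, (1−m)ν) with concentration ν = 60 — beta-binomial rather than
pure binomial so replicate overdispersion exists and the window ANOVA is
non-degenerate.  Coverage is Poisson (default mean 20); methylated counts
are Binomial(coverage, p).  Planted DMRs shift the group-B mean by Δ
inside their intervals; placement rejects locations where the shifted
mean would clip outside [0, 1].  Default baselines are generic
plant-methylome values (high CG/CHG on retrotransposons, low CHH
everywhere, gene-body CG between); the DMR-recovery scenario uses a flat
CG baseline of 0.2 so the planted Δ = +0.6 is representable.  Flagged SV
breakpoints add a CHH elevation (default scenario: Δ = 0.3 within
±500 bp) in both groups.  Planted contexts are *not* force-edited into
the sequence: a random sequence already carries ~25 CG sites per 200-bp
window, far above the 4-site testing threshold, so forcing would add
machinery without changing behavior.

**Expression and m⁶A.**  Log-normal FPKM with additive log-scale shifts
per duplication class (defaults ordered 3-copy > 2-copy > small-scale >
singleton) and for m⁶A-modified genes (+0.8).  m⁶A sites are placed per
modified transcript (1 + Poisson site counts) with region probabilities
(5′UTR 0.08, 3′UTR 0.67, remainder CDS), carry DRACH 5-mers with a 5%
non-DRACH remainder, and are observed per replicate with the detection
probability plus Poisson false positives.  Site 5-mers are table
attributes; the genome FASTA is not edited to spell them out, because no
downstream operation reads transcript sequence.

**What passing tests do and do not show.**  The generator reproduces the
*statistical* structure the analyses assume — replicate noise, planted
effect sizes, class geometry — not real data's sequence composition,
methylation autocorrelation along the genome, TE nesting,
alternative splicing, multi-exon gene structure, or mapping artifacts.
Recovery at the planted effect sizes therefore demonstrates correctness
of the procedures, not expected sensitivity on real methylomes.

## Problem sizes and numerics

The recovery suites run at desk scale as the package's own study
conditions: DMR recovery on a 1-Mb genome with 200 planted CG DMRs
(Δ = 0.6, 400 bp) across 2×3 replicates at depth 20, seeds 1–5; the null
calibration on the same generator with nothing planted, 20 seeds;
breakpoint profiles with 300 insertions on 3 Mb (null controls: 60
insertions on 0.5 Mb × 20 seeds); metaprofiles over 500 non-overlapping
2-kb features; the m⁶A suite at ~2,100 sites over 700 transcripts.
Module tests use further-reduced sizes with tolerances widened to the
corresponding binomial/beta standard errors.

Numerical conventions: percentages round half-up at 2 decimals via exact
decimal arithmetic; undefined levels (no covered cytosine) are NaN,
deliberately distinct from 0; exact test p-values use integer-doubled
mid-ranks so tied ranks stay integral; window/step must divide evenly;
merge recomputation guards the cutoff invariant.

## Known limitations

- The DMR caller tests two groups only (the ANOVA is general, the window
  machinery is not); single-replicate designs are rejected rather than
  falling back to paired per-cytosine tests.
- Exact rank-sum p-values fall back to the normal approximation when a
  tied value spans groups, even when enumeration would be feasible.
- `absolute`-mode metaprofile bodies are ragged (features contribute up to
  their own length), so far-body bins average fewer features.
- The generator's single-exon transcripts make spliced and genomic
  coordinates coincide; code paths that would differ on multi-exon
  models (metagene mapping from genomic alignments) are out of scope.
- Translocation records carry only two breakpoint positions; breakend
  orientation is not modeled.
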