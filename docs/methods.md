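# Methods

This note documents the models, rules, and numerical choices behind
`lncland`, what the synthetic-data generator does and does not emulate, and
the decisions made where the design was genuinely open.

## Coverage segmentation

Input is per-base, per-strand read density (hits/bp). Internally all
coordinates are 0-based half-open; GFF3 conversion happens only at I/O
(bedGraph and BED are half-open on disk as well). Coverage is stored as
dense vectors: at the genome sizes this package targets (compact fungal
genomes and desk-scale simulations) dense arrays are smaller than the
bookkeeping run-length encodings would need, and they make the
segmentation rules direct array operations.

The heuristic, applied per chromosome and strand to pooled coverage:

1. **Call**: maximal runs of bases with density strictly greater than
   `density_cutoff` (default 10 hits/bp). The comparison is strict, so a
   track sitting exactly at the cutoff yields nothing.
2. **Merge**: a single deterministic left-to-right pass. The current
   (possibly already fused) segment A merges with the next segment B iff
   their gap is `< max_gap` (default 100 bp) and, when the fold rule is
   enabled, `max(dA,dB)/min(dA,dB) < max_fold` (default 10) where dA is
   A's *current* mean density, recomputed over A's full span including
   previously absorbed gap bases. Recomputing before the next comparison
   is one of two defensible readings of the fusing rule (the other
   compares original run densities); it was chosen because it is
   order-stable and makes the merged object's density meaningful on its
   own. The fold rule exists to keep lncRNAs near, but distinct from,
   highly expressed mRNA neighbourhoods separate.
3. **Subtract**: any segment sharing ≥ 1 base with a same-strand annotated
   transcript (UTR-inclusive extents) is removed whole, not trimmed.
   Opposite-strand overlap never removes.
4. **Filter**: keep segments with length ≥ `min_length` = 201, i.e.
   strictly longer than 200 bp, matching the conventional > 200 nt lncRNA
   definition and resolving the off-by-one tension between "discard
   < 200 bp" and "keep > 200 bp" in favour of the definition.

**Pooling** sums raw densities with no depth normalization, as sequencing
runs are pooled read-level in the source protocol. A consequence worth
stating: the effective background of a pooled track scales with the number
of samples, so the per-sample default cutoff of 10 hits/bp is not
appropriate for a deep pooled track. The pipeline therefore optimizes the
cutoff on a small grid (10–160 hits/bp by default) against reference
lncRNAs — exactly the calibration-against-annotation procedure the
heuristic is designed for — scoring each grid point by the harmonic mean
of (a) mean percent of each reference lncRNA covered by segments and
(b) mean percent of each segment covered by reference lncRNAs. Ties go to
the earlier grid point.

**Validation utilities.** `validate_candidates` checks an external
transcript set for ≥ 1-nt same-strand overlap with candidates and flags
likely strand *leak-through* artifacts: mean sense density below
`sense_floor` (default 1 hit/bp) with mean antisense density above
`antisense_ceiling` (default 10 hits/bp). The two thresholds quantify
"no signal"/"strong signal" and are configurable; nothing in the package
depends on their exact values. `single_sample_retention` reports the
fraction of pooled candidates overlapped by a raw segment called in at
least one single sample at the same cutoff — the check that pooling
inflates sensitivity but not the final candidate count.

## Expression

**RPKM** = count / (length/10³) / (library/10⁶), library size defaulting to
the per-sample column sum of the supplied matrix (true mapped-read totals
can be passed when known).

**Confidence tiers** use the maximum RPKM over all samples: high ≥ 10 in at
least one sample, medium ≥ 1, low otherwise, boundaries inclusive.

**Differential expression.** The built-in test is deliberately a
transparent approximation rather than a reimplementation of a full DE
framework, and externally computed tables (feature, log2fc, padj) are
accepted everywhere DE results are consumed. The test: median-of-ratios
size factors (features positive in all samples; a pseudo-reference
fallback exists for sparse matrices); a *single* negative-binomial
dispersion α shared by all features, estimated from the aggregate moment
equation Σ(n−1)(v − m̄) = α Σ(n−1)m̄² pooled within groups, with the
denominator de-biased by replacing m̄² with m̄² − v/n (E[m̄²] = µ² +
Var(m̄); without the correction α is systematically underestimated at 2–5
replicates and the test becomes anticonservative). A per-feature moment
estimate was tried first and rejected: with five replicates its sampling
noise inflated the null false-positive rate to ≈ 0.09 at α = 0.05, while
the common estimator calibrates to 0.043–0.063 across seeds. The Wald
statistic is the difference of log normalized group means with
delta-method standard error Var(log m̄) ≈ (µ/n + αµ²/n)/(µ + 0.5)²,
two-sided normal p, Benjamini–Hochberg adjustment within the contrast.
Reported log2 fold-change uses pseudocount 0.5 on normalized means. The
dispersion floor is 10⁻⁸. Limitations: no shrinkage, no per-feature
dispersion trend, normal rather than t reference — adequate for planted
8-fold effects, not a DESeq2 substitute for subtle real-data contrasts.

**DE calling** is strict: induced iff fold-change > 2 *and* adjusted
p < 0.05; repressed symmetrically; the cutoffs are arguments.

**Presence by signal** (for sparse nascent-transcription data): a feature
is present iff its summed same-strand signal is > 0 in at least one
replicate of any condition.

## Decay-pathway classification

Candidates are features induced in ≥ 1 of the three mutants. The
clustering space is the replicate-level RPKM over the mutant samples only
(6 columns at 2 replicates) — wild-type columns are excluded because the
class signature is *where* a transcript is derepressed, not its baseline.
Rows are z-scored (sample sd, ddof = 1); constant rows cannot be
standardized and are dropped with a warning rather than perturbed.

Fuzzy c-means (c = 3, m = 1.25, tolerance 10⁻⁹ on the objective change,
≤ 1000 iterations) starts from a seeded random stochastic membership
matrix; the seed is a recorded parameter because the optimum reached can
depend on it. Memberships are computed as (d_min/d)^(1/(m−1)) normalized
per row, which is algebraically the textbook update but cannot overflow
when a point approaches a centroid; an exact hit gets membership 1
(shared on ties). The alternating updates make the objective
non-increasing, which the test suite asserts on every trace.

Clusters are mapped to mutants by enumerating all 3! one-to-one
assignments of clusters to mutants and maximizing the summed matched
centroid mean z-score — unlike independent per-cluster argmax this cannot
produce collisions, and it makes final CUT/DUT/XUT calls invariant to
cluster relabeling. Coincident centroids abort with the centroid table in
the error. A feature receives its cluster's class only at membership
≥ 0.7; below that it is `unclassified/ambiguous`, and non-induced features
are `unclassified/not_induced`.

## Positional classification

Raw criteria are evaluated independently per lncRNA (sense overlap ≥ 1 nt,
antisense overlap ≥ 1 nt, TSS-to-TSS distance strictly < 300 nt to an
opposite-strand mRNA, distance measured as unsigned offset so "up- or
downstream" need not be resolved), then the precedence
bidirectional > antisense > sense > intergenic produces the single final
class. Partners: nearest qualifying TSS (bidirectional) or largest overlap
(antisense/sense), remaining ties by lexicographic mRNA id for
determinism. mRNA extents are full transcript coordinates; the
antisense-coverage-of-coding statistic (mRNAs overlapped ≥ 10 nt by
opposite-strand lncRNAs) uses whatever intervals are supplied as coding
regions, so CDS can be substituted for transcript extents when available.
The implementation is verified against an all-pairs base-level oracle on
1000 random layouts, including the exact-300-nt and 1-nt boundaries.

## Correlations, translation, enrichment

Pair correlations are Pearson r of raw RPKM between each
bidirectional/antisense lncRNA and its resolved partner mRNA over the
samples of one condition group (genetic or physiological, from the sample
sheet; reference samples belong to neither). Raw RPKM is the default
because that is the scale the class-level signal is defined on; a
log2(RPKM+1) switch is provided since "normalized expression" is also a
defensible reading. Groups need ≥ 3 samples; zero-variance vectors give
NaN and are excluded from summaries rather than coerced to 0.

Translation flags are same-strand ≥ 1-base overlaps with translated
regions, reported at two tiers (any region; regions of ≥ 10 codons).
Enrichment per class uses the two-proportion chi-square with Yates
continuity correction (matching R's `prop.test`; correction can be
disabled), class vs all-other-features background; a class equal to the
whole universe is skipped with a note.

## The synthetic-data generator

The generator is the package's test bed: it emulates the *design* of a
decay-mutant lncRNA study, not the read-level physics of sequencing.

**Layout.** The genome is tiled with self-contained blocks — one mRNA
(1000–2000 bp, random strand), optionally with an attached planted lncRNA,
or one lone intergenic lncRNA (300–600 bp) — separated by ≥ 400-bp
margins. Placement is deterministic given the seed (no rejection
sampling); a genome too small for the requested features raises an error
naming the constraint. Bidirectional lncRNAs sit head-to-head with their
mRNA at TSS distances of 61–251 nt; antisense lncRNAs sit inside the mRNA
body with their TSS ≥ 300 nt from the mRNA TSS (so the antisense rule,
not the bidirectional one, fires); intergenic lncRNAs are ≥ 300 nt from
every TSS and overlap nothing. The margins guarantee same-strand features
never fall within the 100-bp fusing distance and cross-block TSS
distances always exceed the 300-nt window, so the planted positional
classes are recoverable by construction (asserted by the brute-force
oracle in the tests).

**Expression program.** Planted decay classes: the class-defining mutant
induces `induction_fold_primary` (default 8), the other two mutants
`induction_fold_secondary` (default 2) — the cross-pathway leakage that
makes classification non-trivial — and a "stable" class with no mutant
response represents the unclassified population. Physiological profiles
cycle over the physiological conditions per positional class;
antisense induction is concentrated in a single late-meiosis-like
condition (8-fold) with exact reciprocal repression of the sense mRNA, so
the planted lncRNA and mRNA deviations are anti-proportional before
noise. Bidirectional pairs share a lognormal promoter-activity factor
(σ = 0.4 in genetic/reference conditions, 0.8 in physiological ones) and
the mRNA co-responds to the mutants with the lncRNA's fold^0.75. The
split σ encodes that the decay mutants perturb degradation rather than
transcription: an early draft with σ = 0.8 everywhere scrambled the
mutant signature of bidirectional lncRNAs and cut decay-class accuracy to
≈ 0.94. No coupling links antisense pairs in the genetic conditions —
that contrast (anticorrelation under physiological but not genetic
perturbation) is precisely the planted structure the correlation stage
must recover.

**Noise.** Coverage: per-base Poisson around background (default
2 hits/bp) plus the summed expected density of covering same-strand
transcripts. Counts: gamma-Poisson (negative binomial) with dispersion
0.1 around expected density × length × a per-sample library factor
(uniform 0.8–1.2). `noise=False` returns exact means for analytic tests.
All randomness flows from a single seed through named `SeedSequence`
spawns; identical configs are byte-identical.

**What is not emulated** — and hence what passing tests do not show about
real data: no read-level simulation (no mapping ambiguity, no positional
coverage bias), no splicing or poly(A)-site heterogeneity, no overlapping
same-strand transcription, no condition-dependent library quality, and
counts are generated per annotated feature rather than by assigning reads,
so an antisense lncRNA's counts are uncontaminated by its host mRNA. The
planted effect sizes (8- vs 2-fold at dispersion 0.1) are chosen to be
solvable but not trivial; real mutant panels contain weaker and
correlated responses that would lower every recovery metric.

## Problem sizes and determinism

The default benchmark is one 200-kb chromosome, 60 mRNAs, 40 planted
lncRNAs, 7 conditions × 2 replicates; the decay benchmark uses a 2.5-Mb
genome with 800 planted lncRNAs (600 unstable); calibration experiments
use 2000 features at 5 vs 5 replicates. These sizes exercise every code
path while keeping the full test suite and the acceptance script in the
tens of seconds. Every stochastic step (simulation, clustering
initialization, calibration draws) takes an explicit seed, and the
pipeline manifest records a content hash of every output file, so a rerun
with the same config is verifiably identical.

## Known limitations

- Segment boundaries approximate transcript ends; no TSS/TTS refinement
  or isoform resolution is attempted.
- The NB test is a teaching-grade approximation (see above); use external
  DESeq2 tables for production contrasts.
- Fuzzy c-means is run at fixed c = 3; no model selection over c.
- Whole-interval overlap logic only: nested gene models (introns, UTR
  substructure) are not interpreted.
- The positional classifier assumes TSS annotations are trustworthy;
  errors in TSS placement propagate directly to the bidirectional class.
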