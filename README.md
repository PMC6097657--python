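# lncland

Discovery and classification of long noncoding RNAs (lncRNAs) from
strand-specific RNA-seq coverage.

Most lncRNAs are cryptic: they are rapidly degraded and barely detectable in
wild-type cells, but accumulate when the responsible RNA-decay pathway is
removed or when cells enter specialized states such as meiosis. Studies in
fission yeast therefore discover lncRNAs by sequencing panels of
RNA-processing mutants — the nuclear exosome (*rrp6Δ*), the RNAi machinery
(*dcr1Δ*), and the cytoplasmic 5′→3′ exonuclease (*exo2Δ*/Xrn1) — together
with physiological time courses, and then ask three questions about every
transcript found: *which pathway degrades it*, *where does it sit relative to
protein-coding genes*, and *how does its expression relate to its neighbours*.
`lncland` implements that complete computational workflow as a tested,
reusable library with a command-line interface, and ships a synthetic-data
generator that plants lncRNAs with known decay programs and genomic
positions so every stage can be scored against ground truth.

## The method

**Discovery by coverage segmentation.** Per-strand read densities (hits/bp)
from all samples are pooled, and candidate transcripts are the maximal runs
of bases with density strictly above a cutoff (default 10 hits/bp).
Neighbouring segments less than 100 bp apart whose mean densities differ by
less than 10-fold are fused (the fused density is recomputed over the full
span, gap included, before the next comparison); segments overlapping
same-strand annotation are removed whole; segments of ≤ 200 bp are
discarded, leaving novel lncRNA candidates (> 200 nt by the conventional
definition). The four parameters (cutoff, fusing distance, fold rule
on/off, fold threshold) can be optimized on a grid against reference
lncRNAs, scored by the harmonic mean of reference coverage and segment
precision.

**Decay-pathway classification (CUT / DUT / XUT).** Features induced
(> 2-fold, Benjamini–Hochberg adjusted *p* < 0.05) in at least one of the
three mutants are clustered on row-standardized (z-scored) replicate-level
RPKM profiles over the mutant samples with fuzzy c-means (c = 3, fuzzifier
m = 1.25), minimizing

J = Σᵢ Σₖ uᵢₖᵐ ‖xᵢ − vₖ‖².

Clusters are mapped one-to-one to mutants by maximizing the total matched
centroid mean, giving CUTs (exosome, *rrp6*), DUTs (Dicer, *dcr1*), and
XUTs (Xrn1/Exo2, *exo2*). A feature is called only when its maximum
membership uᵢₖ ≥ 0.7; otherwise it stays unclassified (not induced, or
ambiguous).

**Positional classification.** A lncRNA is *bidirectional* if its TSS lies
strictly within 300 nt of an opposite-strand mRNA TSS, *antisense* if it
shares ≥ 1 nt with an opposite-strand mRNA, *sense* if it overlaps a
same-strand mRNA, and *intergenic* otherwise, with precedence
bidirectional > antisense > sense > intergenic.

**Expression analyses.** RPKM with column-sum library sizes; confidence
tiers (high ≥ 10 RPKM in ≥ 1 sample; medium ≥ 1; low otherwise); a
transparent negative-binomial Wald test with median-of-ratios size factors
and a pooled method-of-moments dispersion (externally computed DESeq2-style
tables are accepted as first-class input); Pearson correlations of
lncRNA–partner-mRNA RPKM within condition groups; translated-region overlap
and two-proportion chi-square enrichment tests (R `prop.test` semantics).

## Worked example

Simulate the default study (one 200-kb chromosome, 60 mRNAs, 40 planted
lncRNAs of the four decay classes, 2 replicates of 7 conditions) and run
every stage:

```python
from lncland.pipeline import RunConfig, run_all

out = run_all(RunConfig())
print(out["recovery"].round(3).to_string())
```

```
                                         value   n
metric
segmentation_sensitivity                 1.000  40
segmentation_precision                   1.000  40
decay_class_accuracy                     1.000  30
decay_fraction_assigned                  1.000  30
positional_class_accuracy                1.000  40
correlation_sign_recovery_antisense      1.000  13
correlation_sign_recovery_bidirectional  0.964  28
```

All 40 planted lncRNAs are rediscovered by segmentation at ≥ 80% reciprocal
overlap with no false candidates; the 30 unstable ones all receive their
planted CUT/DUT/XUT class at membership ≥ 0.7 (the 10 stable ones stay
unclassified); every positional class is recovered. Correlation medians
show the planted regulatory structure:

```python
print(out["correlations"].groupby(["positional_class", "group"])["r"]
      .median().round(3).to_string())
```

```
positional_class  group
antisense         genetic         -0.153
                  physiological   -0.835
bidirectional     genetic          0.845
                  physiological    0.845
```

Antisense lncRNAs anticorrelate with their sense mRNA in the physiological
conditions but not in the decay-mutant conditions — accumulation caused by
removing a degradation pathway does not repress the mRNA — while
bidirectional pairs co-vary positively everywhere, as expected for a shared
promoter.

The same pipeline is available from the shell:

```bash
lncland simulate --outdir sim/ --seed 1
lncland run --outdir run/ --seed 1
lncland de --counts sim/counts.tsv --samples sim/samples.tsv \
        --contrast rrp6:reference --out de_rrp6.tsv
```

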