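"""Synthetic genomes, coverage tracks, and count matrices with planted truth.

The generator emulates the study design that motivates the pipeline: a
compact genome transcribed on both strands, strand-specific read-density
tracks for a panel of RNA-processing mutants (*rrp6*, *dcr1*, *exo2*) plus
physiological conditions, and planted lncRNAs whose decay program (CUT-,
DUT-, XUT-like, or stable) and genomic position (bidirectional, antisense,
intergenic) are known by construction, so every downstream stage can be
scored against ground truth.

Decay programs follow the derepression signature of unstable lncRNAs: a
transcript of a given class is most strongly induced in the mutant that
defines the class (``induction_fold_primary``) and more weakly induced in
the other two mutants (``induction_fold_secondary``), reflecting the
partial redundancy of the three degradation pathways.  A "stable" class
with no mutant induction represents lncRNAs that stay unclassified.

Positional placement enforces the classification rules downstream code
must recover: bidirectional lncRNAs start head-to-head within the 300-nt
TSS window of an mRNA on the opposite strand, antisense lncRNAs lie inside
an opposite-strand mRNA (with their TSS kept >=300 nt away from the mRNA
TSS so the antisense rule, not the bidirectional one, applies), and
intergenic lncRNAs overlap nothing with all TSS distances >=300 nt.

Expression coupling between planted lncRNAs and their partner mRNAs plants
the correlation structure reported for real data: bidirectional pairs
share promoter activity and co-vary positively in every condition group,
while antisense lncRNA induction in the physiological conditions represses
the sense mRNA (reciprocal fold), with no such coupling in the genetic
conditions.

Noise model: per-base Poisson for coverage, gamma-Poisson (negative
binomial) for feature counts; ``noise=False`` switches both to their exact
means for analytic tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import CoverageTrack, ExpressionMatrix, Transcript, write_annotation, \
    write_bedgraph, write_counts

DECAY_CLASSES = ("CUT", "DUT", "XUT", "stable")
POSITIONAL_CLASSES = ("bidirectional", "antisense", "intergenic")
MUTANT_CONDITIONS = ("rrp6", "dcr1", "exo2")
#: mutant whose loss derepresses each class
CLASS_MUTANT = {"CUT": "rrp6", "DUT": "dcr1", "XUT": "exo2"}

# physiological induction profiles, cycled over the physiological conditions
# in config order; values multiply the base expression.  Antisense induction
# is concentrated in a single (late-meiosis-like) condition: with the
# reciprocal repression of the sense mRNA this makes the planted lncRNA and
# mRNA deviations exactly anti-proportional before noise.
_PHYS_PROFILE = {
    "bidirectional": (2.0, 4.0, 1.0),
    "antisense": (1.0, 8.0, 1.0),
    "intergenic": (1.0, 6.0, 1.0),
}
# lognormal sd of the promoter activity shared by a bidirectional pair.
# The decay mutants perturb degradation, not transcription, so activity
# varies only mildly across the genetic/reference conditions but strongly
# across physiological states; the physiological value is large enough
# that planted co-expression dominates count noise at the default NB
# dispersion, while the genetic value stays well below the log fold gap
# between primary and secondary derepression.
_BIDIR_ACTIVITY_SIGMA_GENETIC = 0.4
_BIDIR_ACTIVITY_SIGMA_PHYS = 0.8


class PlacementError(RuntimeError):
    """Raised when planted features cannot be placed under the constraints."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults define the standard benchmark: one 200-kb chromosome, 60
    mRNAs, 10 planted lncRNAs per decay class, signal ~50 hits/bp against
    background 2 hits/bp, 8-fold primary vs 2-fold secondary derepression,
    two replicates per condition, NB dispersion 0.1.
    """

    genome_size: int = 200_000
    n_chromosomes: int = 1
    n_mrna: int = 60
    n_lncrna_per_class: int = 10
    conditions: tuple[str, ...] = (
        "reference", "rrp6", "dcr1", "exo2", "mei_early", "mei_late", "stat",
    )
    replicates_per_condition: int = 2
    base_expression_mrna: float = 50.0
    base_expression_lnc: float = 50.0
    induction_fold_primary: float = 8.0
    induction_fold_secondary: float = 2.0
    background_rate: float = 2.0
    nb_dispersion: float = 0.1
    antisense_anticorrelation: bool = True
    noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.replicates_per_condition < 2:
            raise ValueError("replicates_per_condition must be >= 2")
        for name in ("genome_size", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("n_mrna", "n_lncrna_per_class", "base_expression_mrna",
                     "base_expression_lnc", "background_rate", "nb_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.induction_fold_primary > self.induction_fold_secondary >= 1:
            raise ValueError(
                "need induction_fold_primary > induction_fold_secondary >= 1"
            )
        self.conditions = tuple(self.conditions)
        missing = {"reference", *MUTANT_CONDITIONS} - set(self.conditions)
        if missing:
            raise ValueError(f"conditions must include {sorted(missing)}")
        if not self.physiological_conditions:
            raise ValueError("conditions must include >=1 physiological label")

    @property
    def physiological_conditions(self) -> tuple[str, ...]:
        return tuple(
            c for c in self.conditions
            if c != "reference" and c not in MUTANT_CONDITIONS
        )

    def condition_group(self, condition: str) -> str:
        if condition == "reference":
            return "reference"
        if condition in MUTANT_CONDITIONS:
            return "genetic"
        return "physiological"

    @property
    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            {"sample": f"{cond}_r{rep}", "condition": cond, "replicate": rep,
             "group": self.condition_group(cond)}
            for cond in self.conditions
            for rep in range(1, self.replicates_per_condition + 1)
        ]
        return pd.DataFrame(rows).set_index("sample")


@dataclass
class GroundTruth:
    """Construction record of a simulated genome.

    ``features`` is indexed by transcript id with columns chromosome,
    strand, start, end, biotype, decay_class, positional_class, partner.
    ``expected_expression`` holds the per-condition mean density (hits/bp)
    of every transcript, before background.
    """

    features: pd.DataFrame
    expected_expression: pd.DataFrame

    @property
    def lncrna_ids(self) -> list[str]:
        return list(self.features.index[self.features["biotype"] == "lncRNA"])

    @property
    def mrna_ids(self) -> list[str]:
        return list(self.features.index[self.features["biotype"] == "mRNA"])


def _decay_fold(decay_class: str, condition: str, config: SimConfig) -> float:
    if condition not in MUTANT_CONDITIONS or decay_class == "stable":
        return 1.0
    if CLASS_MUTANT[decay_class] == condition:
        return config.induction_fold_primary
    return config.induction_fold_secondary


def simulate_genome(config: SimConfig) -> tuple[list[Transcript], GroundTruth]:
    """Place mRNAs and planted lncRNAs and derive expected expression.

    The genome is tiled with non-overlapping blocks, each holding one mRNA
    (optionally with an attached bidirectional or antisense lncRNA) or one
    intergenic lncRNA, separated by >=400-bp margins so that same-strand
    features never abut and cross-block TSS distances always exceed the
    bidirectional window.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    margin = 400

    lnc_specs = []  # (decay_class, positional_class)
    for decay in DECAY_CLASSES:
        for _ in range(config.n_lncrna_per_class):
            lnc_specs.append(decay)
    lnc_specs = [
        (decay, POSITIONAL_CLASSES[i % len(POSITIONAL_CLASSES)])
        for i, decay in enumerate(lnc_specs)
    ]
    n_paired = sum(1 for _, p in lnc_specs if p != "intergenic")
    if n_paired > config.n_mrna:
        raise PlacementError(
            f"need {n_paired} mRNAs to host bidirectional/antisense lncRNAs "
            f"but n_mrna={config.n_mrna}"
        )

    # build blocks: (width, placer) where placer(offset, chrom) -> features
    paired = [spec for spec in lnc_specs if spec[1] != "intergenic"]
    intergenic = [spec for spec in lnc_specs if spec[1] == "intergenic"]

    blocks = []
    feature_rows = []
    counters = {"mrna": 0, "lnc": 0}

    def new_id(kind: str) -> str:
        counters[kind] += 1
        return f"{kind}{counters[kind]:04d}"

    def add_feature(fid, chrom, strand, start, end, biotype,
                    decay=None, pos=None, partner=None):
        feature_rows.append(dict(
            id=fid, chromosome=chrom, strand=strand, start=start, end=end,
            biotype=biotype, decay_class=decay, positional_class=pos,
            partner=partner,
        ))

    for i in range(config.n_mrna):
        mrna_len = int(rng.integers(1000, 2001))
        mrna_strand = "+" if rng.random() < 0.5 else "-"
        spec = paired[i] if i < len(paired) else None
        if spec is None:
            width = margin + mrna_len + margin

            def placer(off, chrom, L=mrna_len, s=mrna_strand):
                mid = new_id("mrna")
                add_feature(mid, chrom, s, off + margin, off + margin + L, "mRNA")
        elif spec[1] == "bidirectional":
            lnc_len = int(rng.integers(300, 601))
            gap = int(rng.integers(60, 250))
            width = margin + lnc_len + gap + mrna_len + margin

            def placer(off, chrom, L=mrna_len, s=mrna_strand, ll=lnc_len,
                       g=gap, sp=spec):
                mid, lid = new_id("mrna"), new_id("lnc")
                if s == "+":
                    # lncRNA on '-' to the left, tail-to-head with the mRNA TSS
                    ls, le = off + margin, off + margin + ll
                    ms, me = le + g, le + g + L
                    add_feature(mid, chrom, "+", ms, me, "mRNA")
                    add_feature(lid, chrom, "-", ls, le, "lncRNA", sp[0], sp[1], mid)
                else:
                    ms, me = off + margin, off + margin + L
                    ls, le = me + g, me + g + ll
                    add_feature(mid, chrom, "-", ms, me, "mRNA")
                    add_feature(lid, chrom, "+", ls, le, "lncRNA", sp[0], sp[1], mid)
        else:  # antisense: lncRNA inside the mRNA on the opposite strand
            lnc_len = int(rng.integers(300, 601))
            width = margin + mrna_len + margin

            def placer(off, chrom, L=mrna_len, s=mrna_strand, ll=lnc_len, sp=spec):
                mid, lid = new_id("mrna"), new_id("lnc")
                ms, me = off + margin, off + margin + L
                add_feature(mid, chrom, s, ms, me, "mRNA")
                if s == "+":
                    le = me - 50
                    ls = le - ll
                    lstrand = "-"
                else:
                    ls = ms + 50
                    le = ls + ll
                    lstrand = "+"
                add_feature(lid, chrom, lstrand, ls, le, "lncRNA", sp[0], sp[1], mid)
        blocks.append((width, placer))

    for spec in intergenic:
        lnc_len = int(rng.integers(300, 601))
        strand = "+" if rng.random() < 0.5 else "-"
        width = margin + lnc_len + margin

        def placer(off, chrom, ll=lnc_len, s=strand, sp=spec):
            lid = new_id("lnc")
            add_feature(lid, chrom, s, off + margin, off + margin + ll,
                        "lncRNA", sp[0], sp[1], None)
        blocks.append((width, placer))

    # distribute blocks over chromosomes, greedy fill in order
    order = rng.permutation(len(blocks))
    per_chrom: dict[str, list] = {c: [] for c in config.chromosome_names}
    used = {c: 0 for c in config.chromosome_names}
    for idx in order:
        width, placer = blocks[idx]
        target = None
        for chrom in config.chromosome_names:
            if used[chrom] + width <= config.genome_size:
                target = chrom
                break
        if target is None:
            raise PlacementError(
                f"genome too small: block of width {width} bp does not fit in any "
                f"chromosome of {config.genome_size} bp with 400-bp margins; "
                f"increase genome_size or reduce feature counts"
            )
        per_chrom[target].append((width, placer))
        used[target] += width

    for chrom, chrom_blocks in per_chrom.items():
        if not chrom_blocks:
            continue
        slack = (config.genome_size - used[chrom]) // (len(chrom_blocks) + 1)
        offset = 0
        for width, placer in chrom_blocks:
            offset += slack
            placer(offset, chrom)
            offset += width

    if not feature_rows:
        features = pd.DataFrame(
            columns=["chromosome", "strand", "start", "end", "biotype",
                     "decay_class", "positional_class", "partner"],
        )
        features.index.name = "id"
        truth = GroundTruth(
            features=features,
            expected_expression=pd.DataFrame(columns=list(config.conditions)),
        )
        return [], truth

    features = pd.DataFrame(feature_rows).set_index("id").sort_values(
        ["chromosome", "start"]
    )
    expected = _expected_expression(features, config, rng)
    truth = GroundTruth(features=features, expected_expression=expected)
    annotation = [
        Transcript(id=fid, chromosome=row.chromosome, strand=row.strand,
                   start=int(row.start), end=int(row.end), biotype=row.biotype)
        for fid, row in features.iterrows()
    ]
    return annotation, truth


def _expected_expression(features: pd.DataFrame, config: SimConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    conditions = list(config.conditions)
    phys = list(config.physiological_conditions)
    mu = pd.DataFrame(0.0, index=features.index, columns=conditions)

    is_mrna = features["biotype"] == "mRNA"
    mu.loc[is_mrna, :] = config.base_expression_mrna
    mu.loc[~is_mrna, :] = config.base_expression_lnc

    for fid, row in features[~is_mrna].iterrows():
        for cond in MUTANT_CONDITIONS:
            mu.loc[fid, cond] *= _decay_fold(row.decay_class, cond, config)
        profile = _PHYS_PROFILE[row.positional_class]
        for j, cond in enumerate(phys):
            f = profile[j % len(profile)]
            mu.loc[fid, cond] *= f
            if row.positional_class == "antisense" and config.antisense_anticorrelation:
                mu.loc[row.partner, cond] /= f
        if row.positional_class == "bidirectional":
            partner = row.partner
            # co-induction with the divergent mRNA: damped mutant response
            # (three-quarter power of the lncRNA fold), same physiological
            # profile, shared promoter activity
            for cond in MUTANT_CONDITIONS:
                mu.loc[partner, cond] *= (
                    _decay_fold(row.decay_class, cond, config) ** 0.75
                )
            for j, cond in enumerate(phys):
                mu.loc[partner, cond] *= profile[j % len(profile)]
            sigma = np.array([
                _BIDIR_ACTIVITY_SIGMA_PHYS if c in phys
                else _BIDIR_ACTIVITY_SIGMA_GENETIC
                for c in conditions
            ])
            activity = np.exp(rng.normal(0.0, 1.0, size=len(conditions)) * sigma)
            mu.loc[fid, :] *= activity
            mu.loc[partner, :] *= activity
    return mu


CoverageMap = dict  # (condition, replicate) -> chrom -> (fwd, rev) CoverageTrack


def simulate_coverage(annotation: list[Transcript], truth: GroundTruth,
                      config: SimConfig) -> CoverageMap:
    """Per-sample strand-specific coverage: background + covering transcripts.

    Per base the density is Poisson with mean ``background_rate`` plus the
    summed expected expression of transcripts covering the base on that
    strand in that condition (exact means when ``noise=False``).
    """
    ss = np.random.SeedSequence([int(config.seed), 1])
    by_strand_chrom: dict[tuple[str, str], list[Transcript]] = {}
    for t in annotation:
        by_strand_chrom.setdefault((t.chromosome, t.strand), []).append(t)

    out: CoverageMap = {}
    for cond in config.conditions:
        for rep in range(1, config.replicates_per_condition + 1):
            rng = np.random.default_rng(ss.spawn(1)[0])
            sample = {}
            for chrom in config.chromosome_names:
                pair = []
                for strand in "+-":
                    mean = np.full(config.genome_size, float(config.background_rate))
                    for t in by_strand_chrom.get((chrom, strand), []):
                        mean[t.start:t.end] += truth.expected_expression.loc[t.id, cond]
                    if config.noise:
                        density = rng.poisson(mean).astype(float)
                    else:
                        density = mean
                    pair.append(CoverageTrack(chrom, strand, density))
                sample[chrom] = tuple(pair)
            out[(cond, rep)] = sample
    return out


def simulate_counts(annotation: list[Transcript], truth: GroundTruth,
                    config: SimConfig) -> ExpressionMatrix:
    """Feature x sample raw counts, NB(mean = density x length x size factor)."""
    ss = np.random.SeedSequence([int(config.seed), 2])
    rng = np.random.default_rng(ss)
    sheet = config.sample_sheet
    lengths = pd.Series({t.id: t.length for t in annotation}, dtype=float)
    ids = [t.id for t in annotation]
    lib_factors = {
        s: f for s, f in zip(sheet.index, rng.uniform(0.8, 1.2, size=len(sheet)))
    }
    data = {}
    for sample, row in sheet.iterrows():
        mean = (
            truth.expected_expression.loc[ids, row.condition].to_numpy()
            * lengths[ids].to_numpy()
            * lib_factors[sample]
        )
        if not config.noise:
            data[sample] = mean
            continue
        if config.nb_dispersion > 0:
            n = 1.0 / config.nb_dispersion
            counts = np.zeros(len(mean))
            pos = mean > 0
            p = n / (n + mean[pos])
            counts[pos] = rng.negative_binomial(n, p)
        else:
            counts = rng.poisson(mean).astype(float)
        data[sample] = counts
    counts_df = pd.DataFrame(data, index=pd.Index(ids, name="feature"))
    if config.noise:
        counts_df = counts_df.astype(int)
    return ExpressionMatrix(counts=counts_df, samples=sheet, lengths=lengths)


def write_simulation(annotation, truth: GroundTruth, coverage: CoverageMap,
                     matrix: ExpressionMatrix, outdir) -> list[Path]:
    """Write all simulation outputs in the standard dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    p = outdir / "annotation.gff3"
    write_annotation(annotation, p)
    written.append(p)

    for (cond, rep), per_chrom in coverage.items():
        for chrom, (fwd, rev) in per_chrom.items():
            for track, tag in ((fwd, "fwd"), (rev, "rev")):
                p = outdir / f"coverage_{cond}_r{rep}_{chrom}_{tag}.bedgraph"
                write_bedgraph(track, p)
                written.append(p)

    p = outdir / "counts.tsv"
    write_counts(matrix, p)
    written.append(p)

    p = outdir / "samples.tsv"
    matrix.samples.reset_index().to_csv(p, sep="\t", index=False)
    written.append(p)

    p = outdir / "truth.tsv"
    truth.features.join(
        truth.expected_expression.add_prefix("mu_")
    ).to_csv(p, sep="\t", index_label="id")
    written.append(p)
    return written
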