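"""Domain types and file I/O with fixed coordinate conventions.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based inclusive GFF3 convention happens only at I/O boundaries (delegated
to pyranges, which reads GFF3 into 0-based starts and writes them back).
bedGraph and BED are 0-based half-open on disk, matching the internal
convention. Strand is encoded by file pairing for bedGraph (one file per
strand) and by column for GFF3/BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

VALID_BIOTYPES = ("mRNA", "lncRNA")
VALID_GROUPS = ("genetic", "physiological", "reference")


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class Transcript:
    """A stranded genomic interval with biotype and derived TSS/TTS.

    Coordinates are 0-based half-open.  The transcription start site (TSS)
    is ``start`` on the plus strand and ``end - 1`` on the minus strand;
    the termination site (TTS) is the opposite boundary.
    """

    id: str
    chromosome: str
    strand: str
    start: int
    end: int
    biotype: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(
                f"{self.id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.biotype not in VALID_BIOTYPES:
            raise FormatError(
                f"{self.id}: unknown biotype {self.biotype!r}; "
                f"accepted values: {', '.join(VALID_BIOTYPES)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def overlap(self, other: "Transcript") -> int:
        """Shared bases with another interval on any strand."""
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "Transcript":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class CoverageTrack:
    """Per-chromosome, per-strand base-level read density (hits/bp)."""

    chromosome: str
    strand: str
    density: np.ndarray

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 1:
            raise ValueError("density must be a 1-D vector")
        if np.any(self.density < 0):
            raise ValueError("density values must be nonnegative")

    def __len__(self) -> int:
        return len(self.density)


@dataclass(frozen=True)
class TranslatedRegion:
    """A ribosome-occupied interval with the length of its ORF in codons."""

    chromosome: str
    strand: str
    start: int
    end: int
    codon_count: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if self.codon_count < 1:
            raise ValueError("codon_count must be >= 1")


@dataclass
class ExpressionMatrix:
    """Features x samples raw counts, optional RPKM, and sample metadata.

    ``counts`` is a DataFrame indexed by feature id with sample-id columns.
    ``samples`` has one row per sample with columns condition, replicate,
    group (genetic | physiological | reference).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    rpkm: pd.DataFrame | None = None
    lengths: pd.Series | None = None

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup}")
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicate sample ids in count matrix")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise FormatError(
                f"samples in matrix missing from sample sheet: {sorted(missing)}"
            )
        bad = set(self.samples["group"]) - set(VALID_GROUPS)
        if bad:
            raise FormatError(
                f"unknown sample group(s) {sorted(bad)}; accepted: {VALID_GROUPS}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        sheet = self.samples.loc[self.counts.columns]
        return list(sheet.index[sheet["group"] == group])

    def samples_in_condition(self, condition: str) -> list[str]:
        sheet = self.samples.loc[self.counts.columns]
        return list(sheet.index[sheet["condition"] == condition])


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _prescan_gff3(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(f"{path}: malformed GFF3 line {lineno}: {line!r}")


def read_annotation(path) -> list[Transcript]:
    """Read transcripts from GFF3 (1-based inclusive on disk -> 0-based half-open)."""
    _prescan_gff3(path)
    try:
        df = pr.read_gff3(str(path)).df
    except Exception as exc:  # empty file or parser failure
        with open(path) as fh:
            if not any(l.strip() and not l.startswith("#") for l in fh):
                return []
        raise FormatError(f"{path}: cannot parse GFF3: {exc}") from exc
    if df.empty:
        return []
    for col in ("ID", "biotype"):
        if col not in df.columns:
            raise FormatError(f"{path}: GFF3 attributes must carry {col}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Transcript(
                id=row.ID,
                chromosome=str(row.Chromosome),
                strand=str(row.Strand),
                start=int(row.Start),
                end=int(row.End),
                biotype=str(row.biotype),
            )
        )
    ids = [t.id for t in out]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate transcript id {dup!r}")
    return out


def write_annotation(transcripts: Iterable[Transcript], path) -> None:
    rows = [
        dict(
            Chromosome=t.chromosome,
            Source="lncland",
            Feature="transcript",
            Start=t.start,
            End=t.end,
            Score=".",
            Strand=t.strand,
            Frame=".",
            ID=t.id,
            biotype=t.biotype,
        )
        for t in transcripts
    ]
    if not rows:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
        return
    pr.PyRanges(pd.DataFrame(rows)).to_gff3(str(path))


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def _read_bedgraph(path, chromosome: str, strand: str, length: int) -> CoverageTrack:
    density = np.zeros(length, dtype=float)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": int, "end": int, "value": float},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    df = df[df["chrom"] == chromosome]
    if (df["value"] < 0).any():
        raise FormatError(f"{path}: negative coverage value")
    if len(df):
        if df["end"].max() > length or df["start"].min() < 0:
            raise FormatError(
                f"{path}: interval beyond chromosome length {length}"
            )
        srt = df.sort_values(["start", "end"])
        if (srt["end"].shift().fillna(-1)[1:] > srt["start"][1:]).any():
            raise FormatError(f"{path}: overlapping bedGraph records")
        for s, e, v in zip(srt["start"], srt["end"], srt["value"]):
            density[s:e] = v
    return CoverageTrack(chromosome=chromosome, strand=strand, density=density)


def read_bedgraph_pair(
    path_fwd, path_rev, chromosome: str, length: int
) -> tuple[CoverageTrack, CoverageTrack]:
    """Read a forward/reverse bedGraph pair into dense per-base vectors.

    Unspecified intervals are zero.  Files are 0-based half-open.
    """
    fwd = _read_bedgraph(path_fwd, chromosome, "+", length)
    rev = _read_bedgraph(path_rev, chromosome, "-", length)
    return fwd, rev


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a dense track as run-length bedGraph, omitting zero runs."""
    d = track.density
    with open(path, "w") as fh:
        if len(d) == 0:
            return
        breaks = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [len(d)]])
        for s, e in zip(starts, ends):
            v = d[s]
            if v != 0:
                fh.write(f"{track.chromosome}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Count matrices, sample sheets, DE tables, BED
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition", "replicate", "group"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet lacks columns {sorted(missing)}")
    sheet = sheet.set_index("sample")
    sheet["replicate"] = sheet["replicate"].astype(int)
    return sheet


def read_counts(path, sample_sheet: pd.DataFrame | str) -> ExpressionMatrix:
    """Read a TSV count matrix (header row = sample ids) plus sample sheet."""
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = read_sample_sheet(sample_sheet)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    if (counts.values < 0).any():
        raise FormatError(f"{path}: negative counts")
    return ExpressionMatrix(counts=counts, samples=sample_sheet)


def write_counts(matrix: ExpressionMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="feature")


def read_de_table(path) -> pd.DataFrame:
    """Read an externally computed differential-expression table.

    Must provide feature id, log2 fold-change, and adjusted p-value columns
    so that DESeq2-style output is consumable directly.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"feature", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: DE table lacks column(s) {sorted(missing)}; "
            f"required: {sorted(required)}"
        )
    if "pvalue" not in df.columns:
        df["pvalue"] = df["padj"]
    return df.set_index("feature")


def write_bed(intervals: Sequence, path, names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None) -> None:
    """Write stranded intervals as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else getattr(iv, "id", f"iv{i}")
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def read_translated_regions(path) -> list[TranslatedRegion]:
    """Read translated regions (BED-like TSV with a codon count column)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "codons", "strand"],
    )
    return [
        TranslatedRegion(
            chromosome=str(r.chrom), strand=str(r.strand),
            start=int(r.start), end=int(r.end), codon_count=int(r.codons),
        )
        for r in df.itertuples(index=False)
    ]


def write_translated_regions(regions: Iterable[TranslatedRegion], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(
                f"{r.chromosome}\t{r.start}\t{r.end}\ttr{i}\t{r.codon_count}\t{r.strand}\n"
            )
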