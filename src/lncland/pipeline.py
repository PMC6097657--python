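"""End-to-end orchestration: simulate -> segment -> express -> classify -> associate.

``run_all`` executes the stages in dependency order from a single
``RunConfig``, records every parameter and output-file hash in a JSON
manifest, and (on simulated data) scores every stage against the planted
ground truth with ``recovery_report``.

Stage order follows the analysis flow: discovery of transcribed segments
from pooled coverage, expression quantification and differential
expression against the reference, decay-pathway classification, positional
classification, and lncRNA-mRNA correlation analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, decayclass, expression, position, segment
from .decayclass import FcmParams
from .formats import Transcript, write_bed
from .position import PositionParams
from .segment import SegmentationParams, Segment
from .sim import (GroundTruth, SimConfig, simulate_counts, simulate_coverage,
                  simulate_genome, write_simulation)


@dataclass
class RunConfig:
    """One config object reaching every module parameter."""

    sim: SimConfig = field(default_factory=SimConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    #: density cutoffs scanned when optimizing against reference lncRNAs;
    #: pooled coverage scales with the number of samples, so the scan spans
    #: an order of magnitude above the per-sample default
    cutoff_grid: tuple[float, ...] = (10.0, 20.0, 40.0, 80.0, 160.0)
    optimize_cutoff: bool = True
    fcm: FcmParams = field(default_factory=FcmParams)
    position: PositionParams = field(default_factory=PositionParams)
    de_fold_cutoff: float = 2.0
    de_alpha: float = 0.05
    reciprocal_overlap: float = 0.8
    outdir: str | None = None


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage; return all stage outputs plus the run manifest."""
    out: dict = {"stages": []}

    def stage(name):
        out["stages"].append(name)
        return name

    try:
        stage("simulate")
        annotation, truth = simulate_genome(config.sim)
        coverage = simulate_coverage(annotation, truth, config.sim)
        matrix = simulate_counts(annotation, truth, config.sim)
        out.update(annotation=annotation, truth=truth, coverage=coverage,
                   matrix=matrix)
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    mrnas = [t for t in annotation if t.biotype == "mRNA"]
    lncrnas = [t for t in annotation if t.biotype == "lncRNA"]

    try:
        stage("segment")
        params = config.segmentation
        if config.optimize_cutoff:
            grid = segment.make_grid(
                density_cutoffs=config.cutoff_grid,
                max_gaps=(params.max_gap,),
                fold_rule=(params.fold_rule_enabled,),
                max_folds=(params.max_fold,),
                min_length=params.min_length,
            )
            grid_table, params = segment.optimize_parameters(
                coverage, lncrnas, grid, annotation=mrnas,
            )
            out["grid_table"] = grid_table
        candidates = segment.segment_genome(coverage, params, annotation=mrnas)
        out.update(segmentation_params=params, candidates=candidates)
        out["coverage_metrics"] = segment.coverage_metrics(candidates, lncrnas)
        out["single_sample_retention"] = segment.single_sample_retention(
            coverage, candidates, config.segmentation,
        )
    except Exception as exc:
        raise StageError("segment", exc) from exc

    try:
        stage("express")
        matrix = expression.compute_rpkm(matrix)
        out["confidence"] = expression.confidence_classes(matrix.rpkm)
        reference = matrix.samples_in_condition("reference")
        de = {}
        for mutant in ("rrp6", "dcr1", "exo2"):
            de[mutant] = expression.nb_test(
                matrix.counts, reference, matrix.samples_in_condition(mutant),
            )
        out["de"] = de
    except Exception as exc:
        raise StageError("express", exc) from exc

    try:
        stage("classify_decay")
        lnc_ids = [t.id for t in lncrnas]
        out["decay"] = decayclass.classify_decay(
            matrix.rpkm, matrix.samples, de["rrp6"], de["dcr1"], de["exo2"],
            params=config.fcm, feature_ids=lnc_ids,
        )
    except Exception as exc:
        raise StageError("classify_decay", exc) from exc

    try:
        stage("classify_position")
        out["positional"] = position.classify_positions(
            lncrnas, mrnas, config.position,
        )
        _, out["antisense_coding_fraction"] = position.antisense_coverage_of_coding(
            mrnas, lncrnas, config.position,
        )
    except Exception as exc:
        raise StageError("classify_position", exc) from exc

    try:
        stage("correlate")
        correlations = []
        for group in ("genetic", "physiological"):
            correlations.append(
                assoc.pair_correlations(matrix, out["positional"], group)
            )
        out["correlations"] = pd.concat(correlations)
    except Exception as exc:
        raise StageError("correlate", exc) from exc

    stage("recovery")
    out["recovery"] = recovery_report(out, truth,
                                      reciprocal=config.reciprocal_overlap)

    if config.outdir is not None:
        out["manifest"] = _write_outputs(config, out)
    return out


def _write_outputs(config: RunConfig, out: dict) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = list(write_simulation(out["annotation"], out["truth"],
                                  out["coverage"], out["matrix"], outdir))

    p = outdir / "candidates.bed"
    cands = out["candidates"]
    write_bed(cands, p, names=[f"cand{i:04d}" for i in range(len(cands))],
              scores=[c.mean_density for c in cands])
    files.append(p)

    for name in ("decay", "positional", "correlations", "recovery"):
        p = outdir / f"{name}.tsv"
        out[name].to_csv(p, sep="\t")
        files.append(p)

    manifest = {
        "config": _config_dict(config),
        "stages": out["stages"],
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        return obj

    return convert(config)


def match_candidates(candidates: list[Segment], planted: list[Transcript],
                     reciprocal: float = 0.8) -> tuple[float, float]:
    """Sensitivity and precision of candidates against planted transcripts.

    A pair matches when each covers >= ``reciprocal`` of the other on the
    same strand.  Sensitivity = matched planted / planted; precision =
    matched candidates / candidates.
    """
    def matches(c: Segment, t: Transcript) -> bool:
        if (c.chromosome, c.strand) != (t.chromosome, t.strand):
            return False
        ov = min(c.end, t.end) - max(c.start, t.start)
        return ov >= reciprocal * t.length and ov >= reciprocal * c.length

    if planted:
        sens = sum(
            any(matches(c, t) for c in candidates) for t in planted
        ) / len(planted)
    else:
        sens = 1.0
    if candidates:
        prec = sum(
            any(matches(c, t) for t in planted) for c in candidates
        ) / len(candidates)
    else:
        prec = 0.0
    return sens, prec


def recovery_report(out: dict, truth: GroundTruth,
                    reciprocal: float = 0.8) -> pd.DataFrame:
    """Per-stage recovery metrics against the planted ground truth."""
    lnc = truth.features[truth.features["biotype"] == "lncRNA"]
    planted = [
        Transcript(id=i, chromosome=r.chromosome, strand=r.strand,
                   start=int(r.start), end=int(r.end), biotype="lncRNA")
        for i, r in lnc.iterrows()
    ]
    rows = []

    sens, prec = match_candidates(out["candidates"], planted, reciprocal)
    rows.append(("segmentation_sensitivity", sens, len(planted)))
    rows.append(("segmentation_precision", prec, len(out["candidates"])))

    decay = out["decay"]
    if not set(decay.index) <= set(truth.features.index):
        raise ValueError("decay assignment ids missing from ground truth")
    unstable = lnc[lnc["decay_class"] != "stable"]
    assigned = decay.loc[
        decay.index.intersection(unstable.index)
    ]
    assigned = assigned[assigned["decay_class"] != "unclassified"]
    if len(assigned):
        acc = float(
            (assigned["decay_class"] == unstable.loc[assigned.index,
                                                     "decay_class"]).mean()
        )
    else:
        acc = 0.0
    rows.append(("decay_class_accuracy", acc, len(assigned)))
    rows.append((
        "decay_fraction_assigned",
        len(assigned) / len(unstable) if len(unstable) else 1.0,
        len(unstable),
    ))

    pos = out["positional"]
    if not set(pos.index) <= set(truth.features.index):
        raise ValueError("positional assignment ids missing from ground truth")
    pos_acc = float(
        (pos["positional_class"] == lnc.loc[pos.index, "positional_class"]).mean()
    ) if len(pos) else 1.0
    rows.append(("positional_class_accuracy", pos_acc, len(pos)))

    corr = out["correlations"]
    anti_phys = corr[(corr["positional_class"] == "antisense")
                     & (corr["group"] == "physiological")]["r"].dropna()
    bidir = corr[corr["positional_class"] == "bidirectional"]["r"].dropna()
    rows.append((
        "correlation_sign_recovery_antisense",
        float((anti_phys < 0).mean()) if len(anti_phys) else 0.0,
        len(anti_phys),
    ))
    rows.append((
        "correlation_sign_recovery_bidirectional",
        float((bidir > 0).mean()) if len(bidir) else 0.0,
        len(bidir),
    ))
    return pd.DataFrame(rows, columns=["metric", "value", "n"]).set_index("metric")
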