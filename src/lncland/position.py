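"""Positional classification of lncRNAs relative to mRNAs.

Raw criteria are computed independently for each lncRNA: sense overlap
(>= 1 shared base with a same-strand mRNA), antisense overlap (>= 1 base
with an opposite-strand mRNA), and the bidirectional window (TSS strictly
closer than 300 nt to an opposite-strand mRNA TSS, up- or downstream
measured as unsigned offset).  The final class applies the precedence
bidirectional > antisense > sense > intergenic, which encodes the
reassignment of doubly-matching lncRNAs to a single class.

Partners are deterministic: nearest qualifying TSS for bidirectional,
largest overlap for antisense/sense, remaining ties broken by
lexicographic mRNA id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import Transcript


@dataclass(frozen=True)
class PositionParams:
    bidirectional_window: int = 300   # bases, strict <
    min_antisense_overlap: int = 1    # shared bases
    min_sense_overlap: int = 1
    coding_antisense_min_overlap: int = 10

    def __post_init__(self):
        for name in ("bidirectional_window", "min_antisense_overlap",
                     "min_sense_overlap", "coding_antisense_min_overlap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def classify_positions(lncrnas: list[Transcript], mrnas: list[Transcript],
                       params: PositionParams | None = None) -> pd.DataFrame:
    """Classify each lncRNA as bidirectional / antisense / sense / intergenic.

    Returns a DataFrame indexed by lncRNA id with the final class, the
    partner mRNA id (absent for intergenic), the raw criterion flags, and
    the quantities behind the partner choice (TSS distance or overlap).
    """
    params = params or PositionParams()
    known_chroms = {m.chromosome for m in mrnas}
    rows = []
    for lnc in lncrnas:
        if mrnas and lnc.chromosome not in known_chroms:
            raise ValueError(
                f"lncRNA {lnc.id} lies on unknown chromosome {lnc.chromosome!r}"
            )
        sense_hits, anti_hits, bidir_hits = [], [], []
        for m in mrnas:
            if m.chromosome != lnc.chromosome:
                continue
            ov = lnc.overlap(m)
            if m.strand == lnc.strand:
                if ov >= params.min_sense_overlap:
                    sense_hits.append((m.id, ov))
            else:
                if ov >= params.min_antisense_overlap:
                    anti_hits.append((m.id, ov))
                tss_dist = abs(lnc.tss - m.tss)
                if tss_dist < params.bidirectional_window:
                    bidir_hits.append((m.id, tss_dist))

        flags = dict(
            flag_bidirectional=bool(bidir_hits),
            flag_antisense=bool(anti_hits),
            flag_sense=bool(sense_hits),
        )
        if bidir_hits:
            cls = "bidirectional"
            partner, metric = min(bidir_hits, key=lambda h: (h[1], h[0]))
        elif anti_hits:
            cls = "antisense"
            partner, metric = min(anti_hits, key=lambda h: (-h[1], h[0]))
        elif sense_hits:
            cls = "sense"
            partner, metric = min(sense_hits, key=lambda h: (-h[1], h[0]))
        else:
            cls = "intergenic"
            partner, metric = None, np.nan
        rows.append(dict(
            id=lnc.id, positional_class=cls, partner=partner,
            partner_metric=metric, **flags,
        ))
    out = pd.DataFrame(
        rows,
        columns=["id", "positional_class", "partner", "partner_metric",
                 "flag_bidirectional", "flag_antisense", "flag_sense"],
    )
    return out.set_index("id")


def antisense_coverage_of_coding(mrnas: list[Transcript],
                                 lncrnas: list[Transcript],
                                 params: PositionParams | None = None
                                 ) -> tuple[pd.Series, float]:
    """Flag coding regions overlapped >= 10 nt by an opposite-strand lncRNA.

    Returns (per-mRNA boolean Series, fraction flagged).
    """
    params = params or PositionParams()
    flags = {}
    for m in mrnas:
        flags[m.id] = any(
            l.strand != m.strand and m.overlap(l) >= params.coding_antisense_min_overlap
            for l in lncrnas
        )
    series = pd.Series(flags, dtype=bool)
    fraction = float(series.mean()) if len(series) else 0.0
    return series, fraction


def class_composition(positional: pd.DataFrame,
                      decay: pd.DataFrame) -> pd.DataFrame:
    """Contingency table of positional class x decay class.

    Both inputs are indexed by feature id and must cover the same features
    (columns ``positional_class`` and ``decay_class``).
    """
    if set(positional.index) != set(decay.index):
        raise ValueError("positional and decay assignments cover different features")
    decay = decay.loc[positional.index]
    return pd.crosstab(
        positional["positional_class"], decay["decay_class"], margins=True,
        margins_name="total",
    )
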