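"""lncRNA-mRNA expression correlations, translation overlap, enrichment.

Pair correlations: for every bidirectional and antisense lncRNA with a
resolved partner mRNA, the Pearson correlation of their RPKM values over
the samples of one condition group (genetic or physiological).  With
multiple candidate partners the positional classifier has already picked
the nearest/largest-overlap one.  Zero-variance vectors give an undefined
(NaN) correlation, reported but excluded from summaries.

Translation: a lncRNA is flagged translated when it shares >= 1 base on
the same strand with a ribosome-profiling translated region; a second,
conservative tier restricts to regions of at least ten codons.

Enrichment: per-class two-proportion chi-square tests (R prop.test
semantics, Yates continuity correction by default) of the class's flagged
fraction against the background of all other lncRNAs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ExpressionMatrix, TranslatedRegion, Transcript


def pair_correlations(matrix: ExpressionMatrix, positional: pd.DataFrame,
                      group: str, log_transform: bool = False) -> pd.DataFrame:
    """Pearson r of lncRNA-partner RPKM over one condition group's samples.

    ``positional`` is the classifier output (indexed by lncRNA id with
    ``positional_class`` and ``partner``).  ``log_transform`` switches the
    correlation input from raw RPKM to log2(RPKM + 1).
    """
    if matrix.rpkm is None:
        raise ValueError("RPKM not computed; run compute_rpkm first")
    samples = matrix.samples_in_group(group)
    if len(samples) < 3:
        raise ValueError(
            f"group {group!r} has {len(samples)} samples; >= 3 required"
        )
    values = matrix.rpkm[samples]
    if log_transform:
        values = np.log2(values + 1.0)

    rows = []
    paired = positional[positional["positional_class"].isin(
        ["bidirectional", "antisense"])]
    for lnc_id, row in paired.iterrows():
        partner = row["partner"]
        if lnc_id not in values.index or partner not in values.index:
            raise ValueError(f"pair ({lnc_id}, {partner}) missing from matrix")
        x = values.loc[lnc_id].to_numpy(dtype=float)
        y = values.loc[partner].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append(dict(
            lncrna=lnc_id, partner=partner,
            positional_class=row["positional_class"],
            group=group, r=r, n=len(samples),
        ))
    return pd.DataFrame(
        rows, columns=["lncrna", "partner", "positional_class", "group", "r", "n"],
    ).set_index("lncrna")


def overlap_translated(lncrnas: list[Transcript],
                       translated: list[TranslatedRegion],
                       min_codons: int = 10) -> pd.DataFrame:
    """Same-strand overlap flags against translated regions, two tiers.

    ``translated_any``: >= 1 shared base with a region of >= 1 codon;
    ``translated_conservative``: same but regions of >= ``min_codons``.
    """
    rows = []
    for lnc in lncrnas:
        any_tier, conservative = False, False
        for reg in translated:
            if reg.chromosome != lnc.chromosome or reg.strand != lnc.strand:
                continue
            if min(reg.end, lnc.end) <= max(reg.start, lnc.start):
                continue
            any_tier = True
            if reg.codon_count >= min_codons:
                conservative = True
        rows.append(dict(id=lnc.id, translated_any=any_tier,
                         translated_conservative=conservative))
    return pd.DataFrame(
        rows, columns=["id", "translated_any", "translated_conservative"],
    ).set_index("id")


def proportion_test(k1: int, n1: int, k2: int, n2: int,
                    correction: bool = True) -> tuple[float, float]:
    """Two-proportion chi-square test (R prop.test semantics).

    Tests k1/n1 against k2/n2 on the induced 2x2 table with 1 df, Yates
    continuity correction unless disabled.  Returns (statistic, p).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        # a zero margin: proportions are identical (both 0 or both 1)
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def enrichment_report(flags: pd.Series, classes: pd.Series,
                      correction: bool = True) -> pd.DataFrame:
    """Per-class enrichment of a boolean flag against all other features.

    ``flags`` and ``classes`` are indexed by feature id over the same
    universe.  Each class is tested with ``proportion_test`` against the
    background of the remaining features; a class equal to the whole
    universe has no background and is skipped with a note.
    """
    if set(flags.index) != set(classes.index):
        raise ValueError("flags and classes cover different feature universes")
    flags = flags.loc[classes.index].astype(bool)
    rows = []
    for cls in sorted(classes.unique()):
        in_cls = classes == cls
        k_in, n_in = int(flags[in_cls].sum()), int(in_cls.sum())
        k_bg, n_bg = int(flags[~in_cls].sum()), int((~in_cls).sum())
        if n_in == 0 or n_bg == 0:
            rows.append(dict(
                class_label=cls, k_in=k_in, n_in=n_in, k_bg=k_bg, n_bg=n_bg,
                statistic=np.nan, pvalue=np.nan,
                note="skipped: empty class or no background",
            ))
            continue
        stat, p = proportion_test(k_in, n_in, k_bg, n_bg, correction=correction)
        rows.append(dict(
            class_label=cls, k_in=k_in, n_in=n_in, k_bg=k_bg, n_bg=n_bg,
            statistic=stat, pvalue=p, note="",
        ))
    return pd.DataFrame(rows).set_index("class_label")
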