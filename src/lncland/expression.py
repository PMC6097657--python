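"""Expression quantification and differential expression.

RPKM = count / (length/1000) / (library size/1e6), with library size taken
as the per-sample column sum unless totals are supplied.  Confidence tiers
follow the maximum RPKM over samples: high >= 10, medium in [1, 10), low
< 1 in all samples.

The built-in differential-expression test is a transparent negative-
binomial Wald approximation: counts are normalized by median-of-ratios
size factors, a single dispersion common to all features and both groups
is estimated by a bias-corrected method of moments pooled within groups,
and the difference of log group means is tested with a delta-method
standard error, two-sided, with Benjamini-Hochberg adjustment across
features.  It deliberately omits
shrinkage; externally computed DESeq2-style tables are accepted as
first-class inputs wherever DE results are consumed (``formats.read_de_table``).

A transcript is called induced when its fold-change exceeds 2 (strictly,
on the mean of replicates after normalization) at adjusted p < 0.05, and
repressed symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import CoverageTrack, ExpressionMatrix, Transcript

_DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


def compute_rpkm(matrix: ExpressionMatrix, lengths: pd.Series | None = None,
                 library_sizes: pd.Series | None = None) -> ExpressionMatrix:
    """Fill the RPKM matrix: count / (kb of transcript) / (millions mapped)."""
    if lengths is None:
        lengths = matrix.lengths
    if lengths is None:
        raise ValueError("feature lengths are required to compute RPKM")
    lengths = lengths.reindex(matrix.counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:3]
        raise ValueError(f"missing lengths for features {missing}")
    if (lengths < 1).any():
        raise ValueError("feature lengths must be >= 1")
    if library_sizes is None:
        library_sizes = matrix.counts.sum(axis=0)
    library_sizes = library_sizes.reindex(matrix.counts.columns)
    if (library_sizes <= 0).any():
        bad = list(library_sizes.index[library_sizes <= 0])
        raise ValueError(f"zero library size for sample(s) {bad}")
    rpkm = matrix.counts.div(lengths / 1e3, axis=0).div(library_sizes / 1e6, axis=1)
    matrix.rpkm = rpkm
    matrix.lengths = lengths
    return matrix


@dataclass(frozen=True)
class ConfidenceClass:
    feature_id: str
    tier: str  # high | medium | low
    max_rpkm: float


def confidence_classes(rpkm: pd.DataFrame) -> pd.DataFrame:
    """Tier each feature by its maximum RPKM across samples.

    high: >= 10 in at least one sample; medium: >= 1 but < 10 in all;
    low: < 1 in all samples.
    """
    max_rpkm = rpkm.max(axis=1)
    tier = pd.Series("low", index=rpkm.index)
    tier[max_rpkm >= 1] = "medium"
    tier[max_rpkm >= 10] = "high"
    return pd.DataFrame({"tier": tier, "max_rpkm": max_rpkm})


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios normalization factors.

    Each sample's factor is the median, over features with nonzero counts
    in all samples, of the ratio of its count to the feature's geometric
    mean.  ``pseudo_reference=True`` falls back to features positive in at
    least one sample, adding 0.5 before the geometric mean.
    """
    mat = counts.to_numpy(dtype=float)
    if pseudo_reference:
        keep = (mat > 0).any(axis=1)
        mat = mat[keep] + 0.5
    else:
        keep = (mat > 0).all(axis=1)
        if not keep.any():
            raise ValueError(
                "no feature has nonzero counts in all samples; "
                "rerun with pseudo_reference=True"
            )
        mat = mat[keep]
    geomean = np.exp(np.log(mat).mean(axis=1))
    ratios = mat / geomean[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


def nb_test(counts: pd.DataFrame, group_a: list[str], group_b: list[str],
            factors: pd.Series | None = None) -> pd.DataFrame:
    """NB Wald test of group B versus group A on normalized counts.

    Returns a DataFrame indexed by feature with columns base_mean_a,
    base_mean_b, log2fc, se, pvalue, padj.  log2fc is computed on the mean
    of replicates with pseudocount 0.5.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates for the NB test")
    cols = list(group_a) + list(group_b)
    if factors is None:
        factors = size_factors(counts[cols])
    norm = counts[cols].div(factors[cols], axis=1).to_numpy(dtype=float)
    na, nb = len(group_a), len(group_b)
    a, b = norm[:, :na], norm[:, na:]

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    # common dispersion: Var = mu + alpha mu^2, so alpha solves an aggregate
    # moment equation pooled within groups across all features.  The
    # denominator replaces the squared sample mean by its unbiased version
    # (E[mhat^2] = mu^2 + Var(mhat), Var(mhat) estimated by v/n); with few
    # replicates the uncorrected ratio underestimates alpha and inflates
    # the test.
    num = ((na - 1) * (var_a - mean_a) + (nb - 1) * (var_b - mean_b)).sum()
    den = (
        (na - 1) * (mean_a**2 - var_a / na)
        + (nb - 1) * (mean_b**2 - var_b / nb)
    ).sum()
    alpha = max(num / den, _DISPERSION_FLOOR) if den > 0 else _DISPERSION_FLOOR

    la = np.log(mean_a + _PSEUDOCOUNT)
    lb = np.log(mean_b + _PSEUDOCOUNT)
    # delta method on log mean: Var(log mean) ~ Var(mean) / mean^2
    va = (mean_a / na + alpha * mean_a**2 / na) / (mean_a + _PSEUDOCOUNT) ** 2
    vb = (mean_b / nb + alpha * mean_b**2 / nb) / (mean_b + _PSEUDOCOUNT) ** 2
    se = np.sqrt(va + vb)

    with np.errstate(invalid="ignore"):
        z = np.where(se > 0, (lb - la) / se, 0.0)
    pvalue = 2 * stats.norm.sf(np.abs(z))
    padj = multipletests(pvalue, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "base_mean_a": mean_a,
            "base_mean_b": mean_b,
            "log2fc": (lb - la) / np.log(2),
            "se": se,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=counts.index,
    )


def call_de(de: pd.DataFrame, fold_cutoff: float = 2.0,
            alpha: float = 0.05) -> pd.DataFrame:
    """Attach status: induced / repressed / unchanged.

    Induced iff fold-change > fold_cutoff (strict) and adjusted p < alpha;
    repressed iff fold-change < 1/fold_cutoff and adjusted p < alpha.
    """
    if "padj" not in de.columns:
        raise ValueError("DE table lacks adjusted p-values")
    fc = np.power(2.0, de["log2fc"])
    status = pd.Series("unchanged", index=de.index)
    sig = de["padj"] < alpha
    status[sig & (fc > fold_cutoff)] = "induced"
    status[sig & (fc < 1.0 / fold_cutoff)] = "repressed"
    out = de.copy()
    out["status"] = status
    return out


def presence_by_signal(coverage_by_sample, features: list[Transcript]) -> pd.Series:
    """Present iff summed same-strand signal > 0 in >= 1 replicate anywhere.

    Mirrors the low-threshold presence rule used with sparse nascent-
    transcription (NET-seq) data.
    """
    present = pd.Series(False, index=[t.id for t in features])
    for per_chrom in coverage_by_sample.values():
        for t in features:
            if present[t.id]:
                continue
            pair = per_chrom.get(t.chromosome)
            if pair is None:
                continue
            track = pair[0] if t.strand == "+" else pair[1]
            if track.density[t.start:t.end].sum() > 0:
                present[t.id] = True
    return present
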