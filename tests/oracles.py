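"""Independent brute-force reference implementations used as test oracles.

Everything here is written naively — per-base scans, all-pairs loops,
textbook update formulas — and stays independent of the library code paths
it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def brute_runs(density, cutoff):
    """Maximal runs of bases strictly above the cutoff, one base at a time."""
    runs, cur = [], None
    for i, d in enumerate(density):
        if d > cutoff:
            if cur is None:
                cur = [i, i + 1, float(d)]
            else:
                cur[1] = i + 1
                cur[2] += float(d)
        else:
            if cur is not None:
                runs.append(tuple(cur))
                cur = None
    if cur is not None:
        runs.append(tuple(cur))
    return runs  # (start, end, total_hits)


def brute_merge(runs, max_gap, max_fold, fold_rule):
    out = []
    for run in runs:
        if not out:
            out.append(list(run))
            continue
        prev = out[-1]
        gap = run[0] - prev[1]
        ok = gap < max_gap
        if ok and fold_rule:
            da = prev[2] / (prev[1] - prev[0])
            db = run[2] / (run[1] - run[0])
            lo, hi = min(da, db), max(da, db)
            ok = lo > 0 and hi / lo < max_fold
        if ok:
            prev[1] = run[1]
            prev[2] += run[2]
        else:
            out.append(list(run))
    return [tuple(r) for r in out]


def brute_segment(density, cutoff, max_gap, max_fold, fold_rule, min_length,
                  same_strand_annotation):
    """Full reference segmentation on one strand of one chromosome.

    ``same_strand_annotation`` is a list of (start, end) intervals.
    Returns (start, end, total_hits) tuples.
    """
    runs = brute_merge(brute_runs(density, cutoff), max_gap, max_fold, fold_rule)
    kept = []
    for s, e, total in runs:
        overlapping = any(
            len(set(range(s, e)) & set(range(a, b))) > 0
            for a, b in same_strand_annotation
        )
        if not overlapping and (e - s) >= min_length:
            kept.append((s, e, total))
    return kept


def brute_pct_covered(start, end, intervals):
    """Percent of [start, end) bases inside any of the intervals."""
    bases = set(range(start, end))
    covered = set()
    for a, b in intervals:
        covered |= bases & set(range(a, b))
    return 100.0 * len(covered) / len(bases)


# ---------------------------------------------------------------------------
# Positional classification
# ---------------------------------------------------------------------------

def brute_classify(lnc, mrnas, window=300, min_anti=1, min_sense=1):
    """All-pairs base-level positional classification of one lncRNA.

    ``lnc``/``mrnas`` are objects with chromosome/strand/start/end/tss/id.
    Returns (class, partner_id or None).
    """
    sense, anti, bidir = [], [], []
    lnc_bases = set(range(lnc.start, lnc.end))
    for m in mrnas:
        if m.chromosome != lnc.chromosome:
            continue
        shared = len(lnc_bases & set(range(m.start, m.end)))
        if m.strand == lnc.strand:
            if shared >= min_sense:
                sense.append((m.id, shared))
        else:
            if shared >= min_anti:
                anti.append((m.id, shared))
            if abs(lnc.tss - m.tss) < window:
                bidir.append((m.id, abs(lnc.tss - m.tss)))
    if bidir:
        best = sorted(bidir, key=lambda h: (h[1], h[0]))[0]
        return "bidirectional", best[0]
    if anti:
        best = sorted(anti, key=lambda h: (-h[1], h[0]))[0]
        return "antisense", best[0]
    if sense:
        best = sorted(sense, key=lambda h: (-h[1], h[0]))[0]
        return "sense", best[0]
    return "intergenic", None


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------

def naive_fcm(X, u0, m, tol=1e-9, max_iter=1000):
    """Plain-loop fuzzy c-means from a given initial membership matrix.

    Returns (centers, memberships, objectives list).
    """
    X = np.asarray(X, dtype=float)
    u = np.asarray(u0, dtype=float).copy()
    u = u / u.sum(axis=1, keepdims=True)
    n, p = X.shape
    c = u.shape[1]
    objectives = []
    centers = np.zeros((c, p))
    for _ in range(max_iter):
        for k in range(c):
            w = u[:, k] ** m
            centers[k] = (w[:, None] * X).sum(axis=0) / w.sum()
        d2 = np.zeros((n, c))
        for i in range(n):
            for k in range(c):
                d2[i, k] = ((X[i] - centers[k]) ** 2).sum()
        for i in range(n):
            zero = d2[i] <= 0
            if zero.any():
                u[i] = zero / zero.sum()
                continue
            for k in range(c):
                u[i, k] = 1.0 / np.sum((d2[i, k] / d2[i]) ** (1.0 / (m - 1.0)))
        j = float(sum(
            u[i, k] ** m * d2[i, k] for i in range(n) for k in range(c)
        ))
        objectives.append(j)
        if len(objectives) > 1 and abs(objectives[-2] - objectives[-1]) < tol:
            break
    return centers, u, objectives


# ---------------------------------------------------------------------------
# Two-proportion chi-square (prop.test formula, hand-coded)
# ---------------------------------------------------------------------------

def prop_test_formula(k1, n1, k2, n2, correction=True):
    """Textbook 2x2 chi-square with optional Yates continuity correction."""
    observed = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    total = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    diff = np.abs(observed - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))
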