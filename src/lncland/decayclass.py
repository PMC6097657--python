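"""Classification of lncRNAs into CUTs, DUTs, and XUTs by fuzzy clustering.

Transcripts significantly induced in at least one of the three pathway
mutants (*rrp6*: nuclear exosome, *dcr1*: RNAi, *exo2*: cytoplasmic
exonuclease) are clustered on row-standardized replicate-level RPKM
profiles over the mutant samples with fuzzy c-means (c = 3, fuzzifier
m = 1.25).  A transcript is assigned the class of its highest-membership
cluster only when that membership reaches 0.7; otherwise it stays
unclassified (reason "ambiguous").  Transcripts induced in no mutant are
unclassified with reason "not_induced".

Clusters are mapped to pathways data-driven: each centroid's mean z-score
per mutant is computed and the one-to-one cluster-to-mutant assignment
maximizing the total matched mean is chosen (all 6 permutations of a 3x3
table are enumerated), so relabeling clusters can never change the final
CUT/DUT/XUT calls.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import call_de
from .sim import CLASS_MUTANT

MUTANT_CLASS = {mutant: cls for cls, mutant in CLASS_MUTANT.items()}


@dataclass
class FcmParams:
    n_clusters: int = 3
    m: float = 1.25
    membership_threshold: float = 0.7
    max_iterations: int = 1000
    tolerance: float = 1e-9
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if not 0 < self.membership_threshold <= 1:
            raise ValueError("membership_threshold must be in (0, 1]")


class FuzzyCMeans:
    """Fuzzy c-means clustering (Bezdek), scikit-learn estimator style.

    Minimizes J = sum_i sum_k u_ik^m ||x_i - v_k||^2 by alternating
    centroid and membership updates from a seeded random stochastic
    membership matrix, until the objective changes by less than ``tol``
    or ``max_iter`` is reached.  A point coinciding exactly with a
    centroid receives membership 1 for that centroid.

    Attributes (after ``fit``): ``cluster_centers_`` (c x p),
    ``memberships_`` (n x c, rows sum to 1), ``objective_trace_``,
    ``n_iter_``, ``labels_`` (argmax memberships).
    """

    def __init__(self, n_clusters: int = 3, m: float = 1.25,
                 max_iter: int = 1000, tol: float = 1e-9,
                 random_state: int | None = None,
                 init: np.ndarray | None = None):
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.init = init

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_clusters": self.n_clusters, "m": self.m,
            "max_iter": self.max_iter, "tol": self.tol,
            "random_state": self.random_state, "init": self.init,
        }

    def set_params(self, **params) -> "FuzzyCMeans":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    @staticmethod
    def _memberships(dist2: np.ndarray, m: float) -> np.ndarray:
        """u_ik = 1 / sum_j (d_ik / d_ij)^(1/(m-1)) on squared distances.

        Computed as (dmin/d)^(1/(m-1)) normalized per row, which keeps all
        powers in [0, 1] and cannot overflow; a point coinciding with a
        centroid (dmin = 0) gets membership 1 there (shared on ties).
        """
        dmin = dist2.min(axis=1, keepdims=True)
        exact = dist2 <= 0
        hit = exact.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = (dmin / dist2) ** (1.0 / (m - 1.0))
        u = np.empty_like(w)
        ok = ~hit
        u[ok] = w[ok] / w[ok].sum(axis=1, keepdims=True)
        if hit.any():
            u[hit] = exact[hit] / exact[hit].sum(axis=1, keepdims=True)
        return u

    def fit(self, X: np.ndarray, y=None) -> "FuzzyCMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (features x columns)")
        if np.isnan(X).any():
            raise ValueError("X must not contain missing values")
        n, _ = X.shape
        c = self.n_clusters
        if n < c:
            raise ValueError(f"need at least {c} rows to fit {c} clusters, got {n}")
        if self.init is not None:
            u = np.asarray(self.init, dtype=float).copy()
            if u.shape != (n, c):
                raise ValueError(f"init must have shape {(n, c)}, got {u.shape}")
        else:
            rng = np.random.default_rng(self.random_state)
            u = rng.random((n, c))
        u /= u.sum(axis=1, keepdims=True)

        trace = []
        centers = None
        for _ in range(self.max_iter):
            um = u ** self.m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            dist2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            u = self._memberships(dist2, self.m)
            j = float((u ** self.m * dist2).sum())
            trace.append(j)
            if len(trace) > 1 and abs(trace[-2] - trace[-1]) < self.tol:
                break

        self.cluster_centers_ = centers
        self.memberships_ = u
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        self.labels_ = u.argmax(axis=1)
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        dist2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return self._memberships(dist2, self.m)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def select_induced(de_rrp6: pd.DataFrame, de_dcr1: pd.DataFrame,
                   de_exo2: pd.DataFrame, fold_cutoff: float = 2.0,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Flag features induced (>2-fold, adjusted p < 0.05) in >= 1 mutant."""
    tables = {"rrp6": de_rrp6, "dcr1": de_dcr1, "exo2": de_exo2}
    universe = None
    flags = {}
    for mutant, de in tables.items():
        if universe is None:
            universe = de.index
        elif not universe.equals(de.index):
            raise ValueError("DE tables cover different feature universes")
        called = call_de(de, fold_cutoff=fold_cutoff, alpha=alpha)
        flags[f"induced_{mutant}"] = called["status"] == "induced"
    out = pd.DataFrame(flags, index=universe)
    out["candidate"] = out.any(axis=1)
    return out


def standardize_rows(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row z-scores (sample sd, ddof=1); constant rows are dropped with a warning.

    Returns (standardized matrix, ids of dropped constant rows).
    """
    values = X.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    dropped = list(X.index[constant])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant row(s) that cannot be standardized",
            stacklevel=2,
        )
    z = (values[~constant] - mean[~constant]) / sd[~constant]
    return pd.DataFrame(z, index=X.index[~constant], columns=X.columns), dropped


def fuzzy_cmeans(X: np.ndarray, params: FcmParams) -> FuzzyCMeans:
    """Functional wrapper: fit a FuzzyCMeans estimator with FcmParams."""
    return FuzzyCMeans(
        n_clusters=params.n_clusters, m=params.m,
        max_iter=params.max_iterations, tol=params.tolerance,
        random_state=params.seed,
    ).fit(X)


def map_clusters_to_mutants(centers: np.ndarray,
                            column_mutants: list[str]) -> dict[int, str]:
    """One-to-one cluster-to-mutant assignment maximizing total matched mean z.

    ``column_mutants`` labels each column of the clustered matrix with its
    mutant.  Raises on degenerate (coincident) centroids.
    """
    mutants = list(MUTANT_CLASS)
    col_mut = np.asarray(column_mutants)
    score = np.zeros((len(centers), len(mutants)))
    for k, center in enumerate(centers):
        for j, mutant in enumerate(mutants):
            cols = col_mut == mutant
            if not cols.any():
                raise ValueError(f"no columns labeled for mutant {mutant!r}")
            score[k, j] = center[cols].mean()
    for a, b in itertools.combinations(range(len(centers)), 2):
        if np.allclose(centers[a], centers[b]):
            raise ValueError(
                "degenerate clustering: two centroids coincide; "
                f"centroid mean-z table:\n{score}"
            )
    best, best_total = None, -np.inf
    for perm in itertools.permutations(range(len(mutants))):
        total = sum(score[k, perm[k]] for k in range(len(centers)))
        if total > best_total:
            best, best_total = perm, total
    return {k: mutants[best[k]] for k in range(len(centers))}


def assign_decay_classes(memberships: pd.DataFrame, centers: np.ndarray,
                         column_mutants: list[str],
                         params: FcmParams,
                         not_induced: list[str] | None = None) -> pd.DataFrame:
    """Turn memberships into CUT/DUT/XUT calls with an unclassified reason.

    ``memberships`` is features x clusters.  Features listed in
    ``not_induced`` are appended as unclassified with that reason.
    """
    mapping = map_clusters_to_mutants(centers, column_mutants)
    u = memberships.to_numpy()
    argmax = u.argmax(axis=1)
    maxu = u[np.arange(len(u)), argmax]
    klass = np.array(
        [MUTANT_CLASS[mapping[k]] for k in argmax], dtype=object
    )
    reason = np.where(maxu >= params.membership_threshold, "", "ambiguous")
    klass[maxu < params.membership_threshold] = "unclassified"

    cols = {MUTANT_CLASS[mapping[k]]: memberships.iloc[:, k] for k in mapping}
    out = pd.DataFrame({
        "decay_class": klass,
        "max_membership": maxu,
        "reason": reason,
        "u_CUT": cols["CUT"],
        "u_DUT": cols["DUT"],
        "u_XUT": cols["XUT"],
    }, index=memberships.index)
    if not_induced:
        extra = pd.DataFrame({
            "decay_class": "unclassified",
            "max_membership": np.nan,
            "reason": "not_induced",
            "u_CUT": np.nan, "u_DUT": np.nan, "u_XUT": np.nan,
        }, index=pd.Index(not_induced, name=memberships.index.name))
        out = pd.concat([out, extra])
    return out


def classify_decay(rpkm: pd.DataFrame, samples: pd.DataFrame,
                   de_rrp6: pd.DataFrame, de_dcr1: pd.DataFrame,
                   de_exo2: pd.DataFrame, params: FcmParams | None = None,
                   feature_ids: list[str] | None = None) -> pd.DataFrame:
    """Full decay classification for a set of features (default: all in DE).

    Column space is the replicate-level RPKM over the three mutant
    conditions only.  Returns one row per feature: decay_class,
    memberships, reason.
    """
    params = params or FcmParams()
    induced = select_induced(de_rrp6, de_dcr1, de_exo2)
    if feature_ids is not None:
        induced = induced.loc[[f for f in feature_ids if f in induced.index]]
    candidates = list(induced.index[induced["candidate"]])
    not_induced = list(induced.index[~induced["candidate"]])

    mutant_samples = [
        s for s in rpkm.columns
        if samples.loc[s, "condition"] in MUTANT_CLASS
    ]
    column_mutants = [samples.loc[s, "condition"] for s in mutant_samples]
    sub = rpkm.loc[candidates, mutant_samples]
    z, dropped = standardize_rows(sub)
    not_induced += dropped  # constant rows cannot be clustered

    if len(z) < params.n_clusters:
        return assign_decay_classes(
            pd.DataFrame(np.empty((0, params.n_clusters)),
                         index=pd.Index([], name=rpkm.index.name)),
            centers=np.eye(params.n_clusters, len(mutant_samples)),
            column_mutants=column_mutants, params=params,
            not_induced=not_induced,
        ) if not_induced else pd.DataFrame()

    model = fuzzy_cmeans(z.to_numpy(), params)
    memberships = pd.DataFrame(model.memberships_, index=z.index)
    return assign_decay_classes(
        memberships, model.cluster_centers_, column_mutants, params,
        not_induced=not_induced,
    )
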