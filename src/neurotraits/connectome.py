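"""Connectome-based decoding of questionnaire traits ("neurotraits").

The protocol follows the connectome-based predictive-modeling family:

1. Fisher-z connectivity matrices (one per subject) are vectorized over
   the strict upper triangle of the parcellation (272 nodes -> 36,856
   edges by default).
2. Within each of k=3 cross-validation folds, every edge is regressed
   (robustly) on the trait score of the training subjects; edges with
   p < alpha are split by slope sign into a positive and a negative set.
3. A leave-one-out stability filter keeps only edges that remain
   significant, with the same sign, in every n-1 refit of the training
   fold.
4. Each left-out subject is scored by the sum of their Fisher-z values
   over the selected edges (per sign); pooled left-out scores are
   correlated with the observed trait, giving one r^2 per sign.
5. Significance comes from a permutation test that re-runs the whole
   procedure on trait scores permuted across subjects.
6. Edges from the three folds are merged into consensus weights
   {1.0, 0.66, 0.33} for presence in 3/2/1 folds; weight-1.0 edges are
   the "most stable links".  The consensus-weighted edge sum applied to
   later sessions gives the subject's neurotrait score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .robust import edgewise_regression, loo_stable_mask

log = logging.getLogger(__name__)

#: Fisher z is clipped at arctanh(1 - 1e-7) for |r| -> 1 so degenerate
#: inputs cannot poison edge sums.
Z_CLIP = float(np.arctanh(1 - 1e-7))

#: Consensus weight per number of folds an edge was selected in.  Stored
#: exactly as printed (0.66, not 2/3).
CONSENSUS_WEIGHTS = {3: 1.0, 2: 0.66, 1: 0.33}


# ---------------------------------------------------------------------------
# Matrices


def truncate_volumes(timeseries: np.ndarray, n_drop: int = 120) -> np.ndarray:
    """Drop the leading ``n_drop`` volumes (magnetic-field stabilization)."""
    ts = np.asarray(timeseries)
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if ts.shape[0] <= n_drop:
        raise ValueError(
            f"cannot drop {n_drop} volumes from a series of length {ts.shape[0]}"
        )
    return ts[n_drop:]


@dataclass
class ConnectivityMatrix:
    """Symmetric zero-diagonal Fisher-z connectivity of one scan."""

    values: np.ndarray
    subject: Optional[str] = None
    session: Optional[str] = None
    clipped_edges: List[Tuple[int, int]] = field(default_factory=list)
    missing_edges: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def edge_vector(self) -> np.ndarray:
        iu, ju = np.triu_indices(self.n_nodes, 1)
        return self.values[iu, ju]


def connectivity_from_timeseries(
    timeseries: np.ndarray,
    subject: Optional[str] = None,
    session: Optional[str] = None,
) -> ConnectivityMatrix:
    """Pairwise Pearson r of parcel time courses, Fisher-z transformed.

    Columns are parcel-averaged time courses.  r = +/-1 maps to the
    clipped z value (flagged); constant columns yield missing edges
    (NaN, flagged), never zeros.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a T x P matrix with at least 3 time points")
    P = ts.shape[1]
    sd = ts.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 0.0)

    clipped = []
    iu, ju = np.triu_indices(P, 1)
    hit = np.abs(r[iu, ju]) >= 1 - 1e-12
    for i, j in zip(iu[hit], ju[hit]):
        clipped.append((int(i), int(j)))
    z = np.arctanh(np.clip(r, -(1 - 1e-7), 1 - 1e-7))
    np.fill_diagonal(z, 0.0)

    missing = []
    for c in constant:
        z[c, :] = np.nan
        z[:, c] = np.nan
        z[c, c] = 0.0
        for other in range(P):
            if other != c:
                missing.append((min(c, other), max(c, other)))
    return ConnectivityMatrix(z, subject, session, clipped, sorted(set(missing)))


def stack_edges(matrices: Sequence[ConnectivityMatrix]) -> np.ndarray:
    """Stack per-subject matrices into an (n_subjects, E) edge array."""
    return np.vstack([m.edge_vector() for m in matrices])


def edge_pair(edge_idx: int, n_nodes: int) -> Tuple[int, int]:
    """Map a flat upper-triangle edge index to its (i, j) node pair."""
    iu, ju = np.triu_indices(n_nodes, 1)
    return int(iu[edge_idx]), int(ju[edge_idx])


# ---------------------------------------------------------------------------
# Feature selection


@dataclass
class EdgeSelection:
    """Signed edge sets selected against one trait on one training set."""

    positive: np.ndarray            # flat edge indices, sorted
    negative: np.ndarray
    pvalues: Dict[int, float] = field(default_factory=dict)
    slopes: Dict[int, float] = field(default_factory=dict)
    fold: Optional[int] = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if np.intersect1d(self.positive, self.negative).size:
            raise ValueError("positive and negative edge sets must be disjoint")

    @property
    def n_selected(self) -> int:
        return len(self.positive) + len(self.negative)

    def edges(self, sign: str) -> np.ndarray:
        if sign == "positive":
            return self.positive
        if sign == "negative":
            return self.negative
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")


def select_edges_robust(
    train_edges: np.ndarray,
    train_traits: np.ndarray,
    alpha: float = 0.05,
    method: str = "bisquare",
) -> EdgeSelection:
    """Edge-wise (robust) regression screen at two-sided p < alpha.

    ``train_edges`` is (n_train, E).  Edges are partitioned by slope
    sign; "positively correlating with the trait" refers to the slope,
    not to the sign of the underlying functional connection.
    """
    Y = np.asarray(train_edges, dtype=float)
    x = np.asarray(train_traits, dtype=float)
    if Y.shape[0] < 10:
        raise ValueError("need at least 10 training subjects for edge selection")
    slope, p, ok = edgewise_regression(x, Y, method=method)
    n_bad = int((~ok).sum())
    if n_bad:
        log.info("skipped %d zero-variance/degenerate edges", n_bad)
    sig = ok & (p < alpha)
    pos = np.flatnonzero(sig & (slope > 0))
    neg = np.flatnonzero(sig & (slope < 0))
    sel = EdgeSelection(pos, neg, alpha=alpha)
    for e in np.concatenate([pos, neg]):
        sel.pvalues[int(e)] = float(p[e])
        sel.slopes[int(e)] = float(slope[e])
    return sel


def loo_stability_filter(
    train_edges: np.ndarray,
    train_traits: np.ndarray,
    alpha: float = 0.05,
    method: str = "bisquare",
    selection: Optional[EdgeSelection] = None,
) -> EdgeSelection:
    """Keep edges significant (same sign, p < alpha) in every n-1 refit.

    The output is necessarily a subset of the full-sample selection, so
    only those candidate edges are re-fit, with early termination on the
    first failing leave-out.
    """
    Y = np.asarray(train_edges, dtype=float)
    x = np.asarray(train_traits, dtype=float)
    if selection is None:
        selection = select_edges_robust(Y, x, alpha=alpha, method=method)
    cand = np.concatenate([selection.positive, selection.negative]).astype(int)
    if cand.size == 0:
        return EdgeSelection(np.array([], int), np.array([], int),
                             fold=selection.fold, alpha=alpha)
    sign_req = np.concatenate(
        [np.ones(len(selection.positive)), -np.ones(len(selection.negative))]
    )
    stable = loo_stable_mask(x, Y[:, cand], sign_req, alpha, method=method)
    keep = cand[stable]
    keep_sign = sign_req[stable]
    pos = np.sort(keep[keep_sign > 0])
    neg = np.sort(keep[keep_sign < 0])
    out = EdgeSelection(pos, neg, fold=selection.fold, alpha=alpha)
    out.pvalues = {int(e): selection.pvalues[int(e)] for e in keep}
    out.slopes = {int(e): selection.slopes[int(e)] for e in keep}
    return out


# ---------------------------------------------------------------------------
# Scoring


def edge_sum_score(
    edge_values: np.ndarray,
    edges: Sequence[int],
    weights: Optional[Sequence[float]] = None,
    n_nodes: Optional[int] = None,
) -> float:
    """Sum of (optionally weighted) Fisher-z values over an edge set.

    ``edge_values`` is the flat upper-triangle vector of one scan.
    Uniform weights score within-fold; consensus weights score repeat
    sessions.  Referencing an edge outside the matrix raises with the
    offending pair named.
    """
    v = np.asarray(edge_values, dtype=float)
    edges = np.asarray(list(edges), dtype=int)
    if edges.size == 0:
        return 0.0
    if edges.max(initial=-1) >= v.shape[-1] or edges.min(initial=0) < 0:
        bad = int(edges[(edges >= v.shape[-1]) | (edges < 0)][0])
        if n_nodes is not None and 0 <= bad:
            raise KeyError(f"edge index {bad} (pair {edge_pair(bad, n_nodes) if bad < n_nodes*(n_nodes-1)//2 else '?'}) not in matrix")
        raise KeyError(f"edge index {bad} not in matrix")
    if weights is None:
        return math.fsum(v[edges])
    w = np.asarray(list(weights), dtype=float)
    if w.shape != edges.shape:
        raise ValueError("weights and edges must align")
    # exactly rounded summation: invariant to edge order
    return math.fsum(v[edges] * w)


# ---------------------------------------------------------------------------
# Cross-validation


def fold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    """Deterministic fold labels: subjects shuffled by seed, cut into k
    contiguous blocks with sizes differing by at most 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 3 * k:
        raise ValueError("need at least 3 subjects per fold (n >= 3k)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, block in enumerate(np.array_split(perm, k)):
        folds[block] = f
    return folds


@dataclass
class CVResult:
    """Pooled left-out predictions of one trait, per edge sign."""

    predicted: Dict[str, np.ndarray]      # sign -> (n,) normalized edge sums
    observed: np.ndarray                  # (n,) trait scores
    available: Dict[str, np.ndarray]      # sign -> bool mask (fold had edges)
    folds: np.ndarray
    fold_selections: List[EdgeSelection]
    r2: Dict[str, float] = field(default_factory=dict)
    pvalues: Dict[str, float] = field(default_factory=dict)
    n_perm: Optional[int] = None

    def pooled_r2(self, sign: str) -> float:
        mask = self.available[sign]
        if mask.sum() < 3 or np.ptp(self.predicted[sign][mask]) == 0:
            return 0.0
        r = np.corrcoef(self.predicted[sign][mask], self.observed[mask])[0, 1]
        return float(r * r)


def crossval_predict(
    edge_matrix: np.ndarray,
    traits: np.ndarray,
    k: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "bisquare",
    normalization: str = "train",
    folds: Optional[np.ndarray] = None,
) -> CVResult:
    """k-fold cross-validated edge-sum prediction of one trait.

    Per fold: stability-filtered selection on the training 2/3; each
    left-out subject scored by the sum of z(r) over the selected edges,
    per sign; scores normalized by the training-fold edge-sum mean/SD
    (``normalization='train'``, default, leakage-free) or within the
    test fold (``'test'``).  Pooled left-out scores are correlated with
    the observed traits; r^2 reported per sign.
    """
    Y = np.asarray(edge_matrix, dtype=float)
    x = np.asarray(traits, dtype=float)
    n = Y.shape[0]
    if x.shape[0] != n:
        raise ValueError("traits and matrices misaligned")
    if folds is None:
        folds = fold_assignment(n, k, seed)
    else:
        folds = np.asarray(folds, dtype=int)
        k = int(folds.max()) + 1

    predicted = {s: np.full(n, np.nan) for s in ("positive", "negative")}
    available = {s: np.zeros(n, dtype=bool) for s in ("positive", "negative")}
    selections: List[EdgeSelection] = []

    for f in range(k):
        test = folds == f
        train = ~test
        sel = loo_stability_filter(Y[train], x[train], alpha=alpha, method=method)
        sel.fold = f
        selections.append(sel)
        for sign in ("positive", "negative"):
            edges = sel.edges(sign)
            if edges.size == 0:
                log.info("fold %d: empty %s-edge selection; prediction "
                         "unavailable for this fold/sign", f, sign)
                continue
            train_sums = Y[np.ix_(train, edges)].sum(axis=1)
            test_sums = Y[np.ix_(test, edges)].sum(axis=1)
            if normalization == "train":
                mu, sd = train_sums.mean(), train_sums.std(ddof=1)
            elif normalization == "test":
                mu, sd = test_sums.mean(), test_sums.std(ddof=1)
            else:
                raise ValueError(f"unknown normalization {normalization!r}")
            sd = sd if sd > 0 else 1.0
            predicted[sign][test] = (test_sums - mu) / sd
            available[sign][test] = True

    res = CVResult(predicted, x, available, folds, selections)
    for sign in ("positive", "negative"):
        res.r2[sign] = res.pooled_r2(sign)
    return res


def permutation_test(
    edge_matrix: np.ndarray,
    traits: np.ndarray,
    observed: Optional[CVResult] = None,
    n_perm: int = 10000,
    k: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "bisquare",
    mode: str = "full",
) -> Dict[str, float]:
    """Permutation p-values for the cross-validated r^2, per sign.

    ``mode='full'`` (default) re-runs selection, stability filtering and
    scoring for every permutation of the trait vector — the statistically
    correct null.  ``mode='score'`` permutes only the observed/predicted
    pairing of the already-fitted result; it is cheap but approximate
    (it does not propagate selection noise) and is intended for quick
    checks only.

    p = (1 + #{perm r^2 >= observed r^2}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Y = np.asarray(edge_matrix, dtype=float)
    x = np.asarray(traits, dtype=float)
    if observed is None:
        observed = crossval_predict(Y, x, k=k, alpha=alpha, seed=seed, method=method)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))

    exceed = {"positive": 0, "negative": 0}
    if mode == "full":
        for _ in range(n_perm):
            xp = rng.permutation(x)
            res = crossval_predict(
                Y, xp, k=k, alpha=alpha, seed=seed, method=method,
                folds=observed.folds,
            )
            for sign in exceed:
                if res.r2[sign] >= observed.r2[sign]:
                    exceed[sign] += 1
    elif mode == "score":
        for _ in range(n_perm):
            perm = rng.permutation(len(x))
            for sign in exceed:
                mask = observed.available[sign]
                pred = observed.predicted[sign]
                xs = x[perm]
                m = mask & np.isfinite(pred)
                if m.sum() < 3 or np.ptp(pred[m]) == 0 or np.ptp(xs[m]) == 0:
                    r2 = 0.0
                else:
                    r = np.corrcoef(pred[m], xs[m])[0, 1]
                    r2 = r * r
                if r2 >= observed.r2[sign]:
                    exceed[sign] += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")

    p = {s: (1 + exceed[s]) / (n_perm + 1) for s in exceed}
    observed.pvalues = p
    observed.n_perm = n_perm
    return p


# ---------------------------------------------------------------------------
# Consensus model


@dataclass
class NeurotraitModel:
    """Consensus-weighted signed edge network decoding one trait."""

    trait: str
    sign: str                         # "positive" or "negative"
    weights: Dict[int, float]         # edge index -> {1.0, 0.66, 0.33}
    n_nodes: int

    @property
    def edges(self) -> np.ndarray:
        return np.array(sorted(self.weights), dtype=int)

    @property
    def most_stable(self) -> np.ndarray:
        """Edges selected in all folds (weight 1.0)."""
        return np.array(sorted(e for e, w in self.weights.items() if w == 1.0),
                        dtype=int)

    @property
    def n_edges(self) -> int:
        return len(self.weights)


def consensus_weights(
    fold_selections: Sequence[EdgeSelection],
    sign: str,
    trait: str = "trait",
    n_nodes: int = 272,
) -> NeurotraitModel:
    """Merge per-fold selections into consensus weights {1.0, 0.66, 0.33}.

    An edge present in 3/2/1 of the three folds gets weight 1.0/0.66/
    0.33, exactly as printed (not k/3 fractions).  An edge that appears
    with opposite signs in different folds is dropped and logged.
    """
    if len(fold_selections) != 3:
        raise ValueError("consensus weighting is defined for exactly 3 folds")
    counts: Dict[int, int] = {}
    for sel in fold_selections:
        for e in sel.edges(sign):
            counts[int(e)] = counts.get(int(e), 0) + 1
    # sign-conflict check against the opposite list
    other = "negative" if sign == "positive" else "positive"
    conflict = set()
    for sel in fold_selections:
        conflict.update(int(e) for e in sel.edges(other))
    weights = {}
    for e, c in counts.items():
        if e in conflict:
            log.warning("edge %d selected with opposite signs across folds; "
                        "excluded from consensus", e)
            continue
        weights[e] = CONSENSUS_WEIGHTS[c]
    return NeurotraitModel(trait, sign, weights, n_nodes)


def apply_model(model: NeurotraitModel, edge_matrix: np.ndarray) -> np.ndarray:
    """Consensus-weighted edge-sum score per subject of a session.

    ``edge_matrix`` is (n_subjects, E) for the same parcellation the
    model was fit on.  An empty model scores everyone 0.
    """
    Y = np.asarray(edge_matrix, dtype=float)
    edges = model.edges
    if edges.size == 0:
        return np.zeros(Y.shape[0])
    w = np.array([model.weights[int(e)] for e in edges])
    return np.array([edge_sum_score(Y[i], edges, w) for i in range(Y.shape[0])])


# ---------------------------------------------------------------------------
# Summaries


def community_edge_summary(
    model: NeurotraitModel, community: np.ndarray, n_communities: Optional[int] = None
) -> pd.DataFrame:
    """Count model edges within/between communities, ignoring weights.

    Returns a symmetric n_communities x n_communities count matrix whose
    upper triangle plus diagonal sums to the model's edge count.
    """
    community = np.asarray(community)
    if n_communities is None:
        n_communities = int(community.max()) + 1
    M = np.zeros((n_communities, n_communities), dtype=int)
    iu, ju = np.triu_indices(model.n_nodes, 1)
    for e in model.edges:
        a, b = community[iu[e]], community[ju[e]]
        if a < 0 or b < 0:
            raise ValueError(f"edge {int(e)} touches an unlabeled node")
        lo, hi = min(a, b), max(a, b)
        M[lo, hi] += 1
        if lo != hi:
            M[hi, lo] += 1
    return pd.DataFrame(M)


def neurotrait_overlap(model_a: NeurotraitModel, model_b: NeurotraitModel
                       ) -> Dict[str, float]:
    """Shared edges between two neurotraits.

    Reports the intersection count, its ratio to |A| (the convention used
    when quoting "x% of A's edges"), and the symmetric Jaccard ratio.
    """
    if model_a.n_nodes != model_b.n_nodes:
        raise ValueError("models use different parcellations")
    a = set(model_a.weights)
    b = set(model_b.weights)
    inter = len(a & b)
    return {
        "n_shared": inter,
        "fraction_of_a": inter / len(a) if a else 0.0,
        "jaccard": inter / len(a | b) if (a | b) else 0.0,
    }


# ---------------------------------------------------------------------------
# Motion controls


def motion_edge_filter(
    edge_matrix: np.ndarray, motion: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Boolean mask of edges NOT related to head motion.

    Edges whose Fisher-z values correlate with mean framewise
    displacement at p < alpha (Pearson) are flagged for removal before
    feature selection.
    """
    Y = np.asarray(edge_matrix, dtype=float)
    fd = np.asarray(motion, dtype=float)
    if fd.shape[0] != Y.shape[0]:
        raise ValueError("motion vector misaligned with subjects")
    if np.isnan(fd).any():
        raise ValueError("missing motion values")
    slope, p, ok = edgewise_regression(fd, Y, method="ols")
    keep = ~(ok & (p < alpha))
    return keep


def motion_partial_scores(
    scores: np.ndarray, traits: np.ndarray, motion: np.ndarray
) -> Tuple[float, float]:
    """Neurotrait-trait partial correlation controlling mean FD."""
    from .associations import partial_correlation

    if np.isnan(np.asarray(motion, float)).any():
        raise ValueError("missing motion values")
    return partial_correlation(scores, traits, np.asarray(motion)[:, None])
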