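"""Questionnaire scoring and trait extraction.

The battery yields 36 subscale scores per subject.  Traits are derived
two ways, mirroring common practice in questionnaire phenotyping:

* a binarized covariance network built from the strongest correlations
  (10% density) with modularity-based community detection, and
* a principal component analysis of the z-scored subscales, retaining
  components with eigenvalue > 2, orthogonalized by varimax rotation.

Both views are kept because they answer different questions: the network
shows which subscales cluster, the rotated components give per-subject
trait scores for downstream decoding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Scoring


def score_questionnaires(
    item_table: pd.DataFrame,
    scoring_spec: Mapping[str, Mapping],
    missing_threshold: float = 0.2,
) -> pd.DataFrame:
    """Sum items into subscale scores with the >20% missingness rule.

    ``scoring_spec`` maps subscale id to a dict with keys:

    ``items``
        list of item column names;
    ``reverse`` (optional)
        list of reverse-coded item names;
    ``range`` (required if ``reverse`` given)
        ``[min, max]`` of the item response scale; a reverse-coded item
        x becomes ``min + max - x``.

    Per subscale (the scoring unit): if the fraction of missing items
    exceeds ``missing_threshold`` the subscale is left missing for that
    subject; otherwise each missing item is imputed with the mean of the
    observed items of the same subscale before summing.
    """
    out = {}
    for sub, spec in scoring_spec.items():
        items = list(spec["items"])
        for it in items:
            if it not in item_table.columns:
                raise KeyError(
                    f"scoring spec for {sub!r} references item {it!r} "
                    "absent from the item table"
                )
        vals = item_table[items].astype(float).copy()
        for it in spec.get("reverse", []):
            lo, hi = spec["range"]
            vals[it] = lo + hi - vals[it]
        n_items = len(items)
        n_missing = vals.isna().sum(axis=1)
        row_mean = vals.mean(axis=1)  # mean of observed items
        filled = vals.apply(lambda col: col.fillna(row_mean))
        score = filled.sum(axis=1)
        score[n_missing / n_items > missing_threshold] = np.nan
        score[n_missing == n_items] = np.nan
        out[sub] = score
    return pd.DataFrame(out, index=item_table.index)


# ---------------------------------------------------------------------------
# Covariance network


def correlation_matrix(subscales: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between subscales.

    Constant columns yield undefined correlations, left as NaN (flagged
    missing, never coerced to 0).
    """
    if subscales.shape[1] < 2:
        raise ValueError("need at least two subscales")
    return subscales.corr(method="pearson", min_periods=min_periods)


@dataclass
class SubscaleNetwork:
    """Binary covariance network over subscales at a fixed edge density."""

    adjacency: pd.DataFrame
    density: float
    communities: Dict[str, int] = field(default_factory=dict)

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        labels = list(self.adjacency.index)
        g.add_nodes_from(labels)
        a = self.adjacency.values
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if a[i, j]:
                    g.add_edge(labels[i], labels[j])
        return g

    @property
    def degree(self) -> pd.Series:
        return self.adjacency.sum(axis=1)


def build_subscale_network(
    r_matrix: pd.DataFrame, density: float = 0.10, mode: str = "positive"
) -> SubscaleNetwork:
    """Keep the strongest ``density`` fraction of correlations as edges.

    ``mode='positive'`` (default) ranks signed r values, so the network
    keeps the largest positive correlations; ``mode='absolute'`` ranks
    |r|.  The cutoff keeps ``floor(density * n_pairs)`` edges; exact ties
    straddling the cutoff are broken by lexicographic pair order and
    logged.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    labels = list(r_matrix.index)
    p = len(labels)
    iu, ju = np.triu_indices(p, 1)
    r = r_matrix.values[iu, ju]
    if mode == "absolute":
        strength = np.abs(r)
    elif mode == "positive":
        strength = r.copy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    strength = np.where(np.isnan(strength), -np.inf, strength)

    n_keep = int(np.floor(density * len(r)))
    # sort by strength desc, ties by (i, j) ascending
    order = np.lexsort((ju, iu, -strength))
    keep = order[:n_keep]
    if n_keep and n_keep < len(r):
        cut = strength[order[n_keep - 1]]
        n_tied = int((strength == cut).sum())
        if n_tied > 1 and strength[order[n_keep]] == cut:
            log.info(
                "tie at the density cutoff (%d pairs at r=%.4f); "
                "resolved by lexicographic pair order", n_tied, cut,
            )
    adj = np.zeros((p, p), dtype=int)
    adj[iu[keep], ju[keep]] = 1
    adj += adj.T
    return SubscaleNetwork(pd.DataFrame(adj, index=labels, columns=labels), density)


def detect_communities(
    network: SubscaleNetwork, seed: int = 0, method: str = "greedy"
) -> Dict[str, int]:
    """Modularity-maximizing partition of the subscale network.

    ``greedy`` (default) is deterministic greedy modularity maximization;
    ``louvain`` is available for larger graphs.  Community ids are
    relabeled deterministically by (size desc, smallest member) so the
    partition is invariant to node order up to nothing at all.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if method == "greedy":
        comms = nx.algorithms.community.greedy_modularity_communities(g)
    elif method == "louvain":
        comms = nx.algorithms.community.louvain_communities(g, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    order = sorted(comms, key=lambda c: (-len(c), sorted(c)[0]))
    mapping = {}
    for cid, members in enumerate(order):
        for m in members:
            mapping[m] = cid
    network.communities = mapping
    return mapping


# ---------------------------------------------------------------------------
# PCA traits


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Returns (rotated loadings, rotation matrix T) with L_rot = L @ T.
    With Kaiser normalization the rows are scaled to unit communality
    before rotating and rescaled after, the convention of the major
    statistics packages.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt((L**2).sum(axis=1))
    if kaiser_normalize:
        h_safe = np.where(h > 0, h, 1.0)
        L = L / h_safe[:, None]
    T = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = L @ T
        u, s, vt = np.linalg.svd(
            L.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        )
        T = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    L_rot = L @ T
    if kaiser_normalize:
        L_rot = L_rot * h[:, None]
    return L_rot, T


@dataclass
class TraitModel:
    """Rotated principal-component trait model of the subscale battery."""

    loadings: pd.DataFrame          # subscales x components, rotated
    eigenvalues: np.ndarray         # unrotated, retained components
    all_eigenvalues: np.ndarray     # full spectrum (descending)
    variance_explained: float       # retained eigenvalue sum / n_subscales
    scores: pd.DataFrame            # subjects x components, standardized
    retention_rule: float
    column_means: np.ndarray
    column_sds: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def salient(self, cutoff: float = 0.4) -> pd.DataFrame:
        """Loadings with |loading| >= cutoff (display convention)."""
        return self.loadings.where(self.loadings.abs() >= cutoff)


def pca_traits(
    subscales: pd.DataFrame,
    eigen_min: float = 2.0,
    rotation: str = "varimax",
    n_components: Optional[int] = None,
) -> TraitModel:
    """Varimax-rotated PCA of z-scored subscales.

    Components with unrotated eigenvalue > ``eigen_min`` are retained
    (or exactly ``n_components`` if given), rotated, and sign-fixed so
    each component's largest-|loading| subscale loads positively.
    Component scores are computed by the regression method on the
    standardized data and are exactly orthogonal on the fitting sample.
    """
    X = subscales.values.astype(float)
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("pca_traits requires a complete (or imputed) matrix")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [subscales.columns[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant subscale(s): {bad}")
    Z = (X - mu) / sd

    Rm = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(Rm)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if n_components is not None:
        k = int(n_components)
    else:
        k = int((eigval > eigen_min).sum())
    if k == 0:
        warnings.warn(
            f"no component has eigenvalue > {eigen_min}; returning empty model"
        )
        empty = pd.DataFrame(index=subscales.columns)
        return TraitModel(empty, np.array([]), eigval, 0.0,
                          pd.DataFrame(index=subscales.index), eigen_min, mu, sd)
    if n <= k:
        raise ValueError("need more subjects than retained components")

    lam = eigval[:k]
    V = eigvec[:, :k]
    L = V * np.sqrt(lam)

    # unrotated standardized scores are white: F = Z V lam^-1/2
    F = Z @ V / np.sqrt(lam)
    if rotation == "varimax" and k > 1:
        L_rot, T = varimax(L)
    elif rotation in (None, "none") or k == 1:
        L_rot, T = L, np.eye(k)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")
    S = F @ T

    # sign convention: the largest-|loading| entry of each component is positive
    flip = np.sign(L_rot[np.abs(L_rot).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    L_rot = L_rot * flip
    S = S * flip

    # normalize score SD to 1 (sample ddof=1)
    S = S / S.std(axis=0, ddof=1)

    comp_names = [f"trait{j + 1}" for j in range(k)]
    return TraitModel(
        loadings=pd.DataFrame(L_rot, index=subscales.columns, columns=comp_names),
        eigenvalues=lam,
        all_eigenvalues=eigval,
        variance_explained=float(lam.sum() / p),
        scores=pd.DataFrame(S, index=subscales.index, columns=comp_names),
        retention_rule=eigen_min,
        column_means=mu,
        column_sds=sd,
    )


def project_scores(model: TraitModel, subscales: pd.DataFrame) -> pd.DataFrame:
    """Score new subjects with a fitted model (projection alternative to
    refitting; the default replication analysis refits per cohort)."""
    X = subscales[model.loadings.index].values.astype(float)
    Z = (X - model.column_means) / model.column_sds
    # regression-method weights: R^-1 L
    R = np.corrcoef(Z, rowvar=False)
    W = np.linalg.solve(R, model.loadings.values)
    S = Z @ W
    S = S / S.std(axis=0, ddof=1)
    return pd.DataFrame(S, index=subscales.index, columns=model.loadings.columns)


def match_components(model_a: TraitModel, model_b: TraitModel) -> pd.DataFrame:
    """Pair components of two models by loading similarity.

    Components are matched by Hungarian assignment on -|r| of their
    loading vectors; each pair's Pearson r is reported after sign
    alignment.  Both models must cover the same subscales in the same
    order.
    """
    if list(model_a.loadings.index) != list(model_b.loadings.index):
        raise ValueError("models cover different subscale sets")
    A = model_a.loadings.values
    B = model_b.loadings.values
    ka, kb = A.shape[1], B.shape[1]
    C = np.zeros((ka, kb))
    for i in range(ka):
        for j in range(kb):
            C[i, j] = np.corrcoef(A[:, i], B[:, j])[0, 1]
    rows, cols = linear_sum_assignment(-np.abs(C))
    recs = []
    for i, j in zip(rows, cols):
        sign = 1.0 if C[i, j] >= 0 else -1.0
        recs.append(
            {
                "component_a": model_a.loadings.columns[i],
                "component_b": model_b.loadings.columns[j],
                "r": sign * C[i, j],
                "sign": sign,
            }
        )
    return pd.DataFrame(recs)


def congruence(loadings: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Tucker congruence of each estimated component with its best-matched
    ground-truth column (Hungarian assignment on |phi|)."""
    A = np.asarray(loadings, float)
    B = np.asarray(truth, float)
    na = np.sqrt((A**2).sum(axis=0))
    nb = np.sqrt((B**2).sum(axis=0))
    phi = (A.T @ B) / np.outer(na, nb)
    rows, cols = linear_sum_assignment(-np.abs(phi))
    return np.abs(phi[rows, cols])
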