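"""Associations between traits, neurotraits, pain measures, and SES.

Covers the correlational surface of the analysis: Pearson/Spearman
correlations with Bonferroni correction, partial correlations,
cross-visit/cross-cohort consensus maps, a 3-component PCA of the pain
battery, income (socioeconomic) comparisons with covariates, and the
trait-placebo screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .traits import TraitModel, pca_traits


# ---------------------------------------------------------------------------
# Correlation machinery


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str
    alpha_adjusted: Optional[float] = None
    significant_corrected: Optional[bool] = None


def correlate(
    x,
    y,
    method: str = "pearson",
    correction: Optional[str] = None,
    m_comparisons: int = 1,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pairwise correlation with optional Bonferroni-adjusted threshold.

    Incomplete pairs are dropped; at least 4 complete pairs are required.
    Constant input yields an undefined correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    res = CorrelationResult(float(r), float(p), int(x.size), method)
    if correction == "bonferroni":
        res.alpha_adjusted = alpha / m_comparisons
        res.significant_corrected = bool(p < res.alpha_adjusted)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return res


def bonferroni_threshold(alpha: float, m_comparisons: int) -> float:
    """Per-test significance threshold alpha / m."""
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    return alpha / m_comparisons


def partial_correlation(x, y, covariates) -> Tuple[float, float]:
    """Pearson correlation of x and y after linearly removing covariates.

    Residualizes both variables on [1, covariates] and correlates the
    residuals; the t test uses n - 2 - n_cov degrees of freedom.  An
    empty covariate set reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    C = np.asarray(covariates, dtype=float)
    if C.size == 0:
        C = np.empty((n, 0))
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariates misaligned")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates")
    q = X.shape[1] - 1  # number of covariates
    beta_x, *_ = np.linalg.lstsq(X, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    rx = x - X @ beta_x
    ry = y - X @ beta_y
    df = n - 2 - q
    if df < 1:
        raise ValueError("not enough observations for the covariate count")
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("constant residuals; partial correlation undefined")
    r = float((rx @ ry) / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# Consensus map


def consensus_map(
    cells: Mapping[Tuple[str, str], Sequence[Mapping]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Replication consensus across visits and cohorts.

    ``cells`` maps (trait, measure) to the list of replication cells
    available for it (e.g. Group 1 V1, Group 1 V2, Group 2 V1), each a
    dict with keys ``r`` and ``p`` and optionally ``label``.  Consensus
    holds iff every available cell is significant at the uncorrected
    ``alpha`` with a common sign.  Measures missing in a cohort simply
    contribute fewer cells.
    """
    rows = []
    for (trait, measure), cell_list in cells.items():
        if len(cell_list) == 0:
            raise ValueError(f"no cells for ({trait}, {measure})")
        ps = [c["p"] for c in cell_list]
        rs = [c["r"] for c in cell_list]
        all_sig = all(p < alpha for p in ps)
        same_sign = len({np.sign(r) for r in rs if r != 0}) == 1 and all(
            r != 0 for r in rs
        )
        consensus = bool(all_sig and same_sign)
        rows.append(
            {
                "trait": trait,
                "measure": measure,
                "n_cells": len(cell_list),
                "consensus": consensus,
                "direction": int(np.sign(rs[0])) if consensus else 0,
                "max_p": max(ps),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pain PCA


def pain_pca(pain_measures: pd.DataFrame, n_components: int = 3) -> TraitModel:
    """Data reduction of the pain battery to a fixed component count.

    Uses the same z-scoring / varimax machinery as the trait PCA but
    retains exactly ``n_components`` components (pain intensity, pain
    quality, negative affect & physical health in the emulated data).
    """
    return pca_traits(pain_measures, rotation="varimax", n_components=n_components)


# ---------------------------------------------------------------------------
# Socioeconomic analyses


def income_analysis(
    scores,
    demographics: pd.DataFrame,
    alpha: float = 0.05,
    split_threshold_code: int = 2,
) -> Dict:
    """Income-group comparison of a trait/neurotrait score.

    Fits an ANCOVA-style linear model of the score on the income bracket
    with race/ethnicity (categorical) and years of education (numeric)
    as covariates, reports the omnibus income effect (type-III style,
    sum-coded), all C(4,2)=6 pairwise bracket contrasts Bonferroni-
    corrected, and the binary comparison at the $25,000 threshold
    (brackets with ``income_code >= split_threshold_code``, i.e.
    >$25,000, vs the rest).  Subjects with missing income are dropped
    and the analysis n is reported.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    from itertools import combinations

    df = demographics.copy()
    df["score"] = np.asarray(scores, dtype=float)
    df = df.dropna(subset=["score", "income_code"])
    n_used = len(df)
    df["income_cat"] = df["income_code"].astype(int)

    model = smf.ols(
        "score ~ C(income_cat, Sum) + C(ethnicity, Sum) + education_years",
        data=df,
    ).fit()
    aov = anova_lm(model, typ=3)
    omnibus_p = float(aov.loc["C(income_cat, Sum)", "PR(>F)"])

    groups = sorted(df["income_cat"].unique())
    contrasts = []
    m = 6  # C(4,2), the printed correction count
    for a, b in combinations(range(4), 2):
        ga = df.loc[df["income_cat"] == a, "score"]
        gb = df.loc[df["income_cat"] == b, "score"]
        if len(ga) < 2 or len(gb) < 2:
            contrasts.append({"groups": (a, b), "p": np.nan,
                              "p_bonferroni": np.nan, "mean_diff": np.nan})
            continue
        t, p = stats.ttest_ind(ga, gb)
        contrasts.append(
            {
                "groups": (a, b),
                "mean_diff": float(ga.mean() - gb.mean()),
                "p": float(p),
                "p_bonferroni": float(min(1.0, p * m)),
            }
        )

    hi = df["income_cat"] >= split_threshold_code
    t_split, p_split = stats.ttest_ind(df.loc[hi, "score"], df.loc[~hi, "score"])
    split = {
        "mean_high": float(df.loc[hi, "score"].mean()),
        "mean_low": float(df.loc[~hi, "score"].mean()),
        "t": float(t_split),
        "p": float(p_split),
        "n_high": int(hi.sum()),
        "n_low": int((~hi).sum()),
    }
    return {
        "n": n_used,
        "omnibus_p": omnibus_p,
        "pairwise": contrasts,
        "split_25k": split,
        "group_means": {g: float(df.loc[df["income_cat"] == g, "score"].mean())
                        for g in groups},
    }


def income_subscale_screen(
    subscales: pd.DataFrame, income_code, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman screen of every subscale against the income bracket.

    Uncorrected by design (a display screen, mirroring how subscale-SES
    links are browsed); returns all subscales with their rho/p and a
    significance flag at ``alpha``.
    """
    inc = np.asarray(income_code, dtype=float)
    rows = []
    for col in subscales.columns:
        res = correlate(subscales[col], inc, method="spearman")
        rows.append({"subscale": col, "rho": res.r, "p": res.p,
                     "significant": res.p < alpha})
    return pd.DataFrame(rows)


def placebo_trait_screen(
    trait_scores: pd.DataFrame, placebo_response, alpha: float = 0.05
) -> pd.DataFrame:
    """Correlate each trait with treatment response (% analgesia).

    The response column is supplied externally (computed in the trial
    analysis, not here).  Bonferroni correction over the number of
    traits (m=4 for the standard four-trait model).
    """
    resp = np.asarray(placebo_response, dtype=float)
    m = trait_scores.shape[1]
    rows = []
    for col in trait_scores.columns:
        res = correlate(trait_scores[col], resp, correction="bonferroni",
                        m_comparisons=m, alpha=alpha)
        rows.append(
            {
                "trait": col,
                "r": res.r,
                "p": res.p,
                "alpha_adjusted": res.alpha_adjusted,
                "significant_corrected": res.significant_corrected,
            }
        )
    return pd.DataFrame(rows)
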