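"""Test-retest reliability of neurotrait scores across imaging sessions.

Reliability is quantified with intraclass correlations under a two-way
random-effects ANOVA (subjects x sessions, both random).  Because the
common software labels conflate variants, all four standard forms are
computed — absolute agreement vs consistency, single vs average
measures (ICC(2,1), ICC(2,k), ICC(C,1), ICC(C,k) in the
McGraw & Wong taxonomy) — and the absolute-agreement average-measures
form is reported as the headline.  Confidence intervals follow the
F-distribution constructions of McGraw & Wong (1996); numerical
agreement with pingouin's implementation is enforced by the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class ICCResult:
    """One ICC estimate with its 95% CI and model tag."""

    icc: float
    ci_low: float
    ci_high: float
    model: str          # e.g. "two-way random, absolute agreement, average"
    n_subjects: int
    n_sessions: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.icc <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def _mean_squares(X: np.ndarray) -> Tuple[float, float, float, int, int]:
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssb = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((X - grand) ** 2).sum()
    sse = sst - ssb - ssc
    msr = ssb / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_two_way_random(
    scores, alpha: float = 0.05, form: str = "average_absolute"
) -> ICCResult:
    """Two-way random-effects ICC of a subjects x sessions score table.

    ``scores`` is an (n, k) array or DataFrame (sessions in columns).
    Rows with missing cells are listwise-deleted (logged).  ``form`` is
    one of ``single_absolute``, ``average_absolute`` (default headline),
    ``single_consistency``, ``average_consistency``.
    """
    res = icc_all_forms(scores, alpha=alpha)
    return res[form]


def icc_all_forms(scores, alpha: float = 0.05) -> Dict[str, ICCResult]:
    """All four two-way random ICC forms with F-based CIs."""
    X = scores.values if isinstance(scores, pd.DataFrame) else np.asarray(scores)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("scores must be subjects x sessions")
    complete = ~np.isnan(X).any(axis=1)
    if (~complete).sum():
        log.info("listwise-deleting %d incomplete subjects", int((~complete).sum()))
        X = X[complete]
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")

    msr, msc, mse, n, k = _mean_squares(X)

    icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc2k = (msr - mse) / (msr + (msc - mse) / n)
    icc31 = (msr - mse) / (msr + (k - 1) * mse)
    icc3k = (msr - mse) / msr

    # --- CIs (McGraw & Wong 1996) ---
    # consistency forms: from F = MSR/MSE
    f_obs = msr / mse
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fl = f_obs / stats.f.isf(alpha / 2, df1, df2)
    fu = f_obs * stats.f.isf(alpha / 2, df2, df1)
    ci31 = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    ci3k = (1 - 1 / fl, 1 - 1 / fu)

    # absolute-agreement single: Satterthwaite df for the denominator
    with np.errstate(divide="ignore", invalid="ignore"):
        a = k * icc21 / (n * (1 - icc21))
        b = 1 + k * icc21 * (n - 1) / (n * (1 - icc21))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.isf(alpha / 2, n - 1, v)
        f2 = stats.f.isf(alpha / 2, v, n - 1)
        lo21 = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi21 = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
        ci21 = (lo21, hi21)
        ci2k = (
            lo21 * k / (1 + lo21 * (k - 1)),
            hi21 * k / (1 + hi21 * (k - 1)),
        )

    def mk(est, ci, tag):
        est = float(est)
        lo, hi = float(ci[0]), float(ci[1])
        # degenerate tables (e.g. perfect agreement, MSE=0) make the
        # F-based bounds undefined; collapse the CI onto the estimate
        if not np.isfinite(lo):
            lo = est
        if not np.isfinite(hi):
            hi = est
        return ICCResult(est, min(lo, est), max(hi, est), tag, n, k)

    return {
        "single_absolute": mk(icc21, ci21, "two-way random, absolute, single"),
        "average_absolute": mk(icc2k, ci2k, "two-way random, absolute, average"),
        "single_consistency": mk(icc31, ci31, "two-way random, consistency, single"),
        "average_consistency": mk(icc3k, ci3k, "two-way random, consistency, average"),
    }


def session_score_table(score_lists, session_ids=None) -> pd.DataFrame:
    """Assemble per-session score vectors into a subjects x sessions table."""
    arr = np.column_stack([np.asarray(s, dtype=float) for s in score_lists])
    if session_ids is None:
        session_ids = [f"V{i + 2}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=session_ids)
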