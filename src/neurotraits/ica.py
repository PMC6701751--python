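"""Rule-based classification of ICA components as noise, plus the
band-pass and nuisance-regression operators applied to ROI time series.

A component is rejected as non-neuronal if any of three ratios exceeds
its threshold (strict inequalities, exactly as the rules are stated):

* edge rule: activated voxels on the one-voxel brain edge / all
  activated voxels > 0.45;
* white-matter/ventricle rule: activated voxels inside the WM+ventricle
  mask / all WM+ventricle voxels > 0.35;
* frequency rule: band power in 0.05-0.1 Hz / band power in
  0.008-0.05 Hz > 1.

The rule set is deliberately conservative: it only flags components
that are obviously artifactual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sp_signal

EDGE_THRESHOLD = 0.45
WM_VENT_THRESHOLD = 0.35
FREQ_THRESHOLD = 1.0
LOW_BAND = (0.008, 0.05)
HIGH_BAND = (0.05, 0.1)


def _active(spatial_map: np.ndarray, z_threshold: Optional[float]) -> np.ndarray:
    m = np.asarray(spatial_map)
    if m.dtype == bool or z_threshold is None:
        return m.astype(bool)
    return np.abs(m) > z_threshold


def edge_activation_ratio(
    spatial_map, edge_mask, z_threshold: Optional[float] = None
) -> float:
    """Fraction of a component's active voxels lying on the brain edge."""
    act = _active(spatial_map, z_threshold)
    edge = np.asarray(edge_mask, dtype=bool)
    n_act = int(act.sum())
    if n_act == 0:
        raise ValueError("component has no active voxels")
    return float((act & edge).sum() / n_act)


def wm_ventricle_ratio(
    spatial_map, wm_mask, vent_mask, z_threshold: Optional[float] = None
) -> float:
    """Active fraction of the white-matter + ventricle compartment."""
    act = _active(spatial_map, z_threshold)
    comp = np.asarray(wm_mask, dtype=bool) | np.asarray(vent_mask, dtype=bool)
    denom = int(comp.sum())
    if denom == 0:
        raise ValueError("empty white-matter/ventricle mask")
    return float((act & comp).sum() / denom)


def highlow_freq_ratio(
    timecourse,
    tr: float,
    low: Tuple[float, float] = LOW_BAND,
    high: Tuple[float, float] = HIGH_BAND,
) -> float:
    """High-band / low-band power ratio of a component time course.

    Band power is the discrete integral of the one-sided periodogram
    over (low, high] Hz (half-open bins so a bin at the shared 0.05 Hz
    boundary is counted once).
    """
    tc = np.asarray(timecourse, dtype=float)
    fs = 1.0 / tr
    if fs / 2 < high[1]:
        raise ValueError("sampling rate too low for the high band")
    min_len = int(np.ceil(2.0 / (low[0] * tr)))
    if tc.size < min_len:
        raise ValueError(
            f"time course too short to resolve {low[0]} Hz (need >= {min_len})"
        )
    f, pxx = sp_signal.periodogram(tc, fs=fs)
    lo_power = pxx[(f > low[0]) & (f <= low[1])].sum()
    hi_power = pxx[(f > high[0]) & (f <= high[1])].sum()
    if lo_power == 0:
        return np.inf
    return float(hi_power / lo_power)


@dataclass
class Classification:
    keep: bool
    reasons: List[str]
    edge_ratio: float
    wm_vent_ratio: float
    freq_ratio: float


def classify_component(fixture, z_threshold: Optional[float] = None) -> Classification:
    """Apply all three noise rules; reject if any fires (strictly above
    its threshold), listing every firing rule."""
    er = edge_activation_ratio(fixture.spatial_map, fixture.edge_mask, z_threshold)
    wr = wm_ventricle_ratio(
        fixture.spatial_map, fixture.wm_mask, fixture.vent_mask, z_threshold
    )
    fr = highlow_freq_ratio(fixture.timecourse, fixture.tr)
    reasons = []
    if er > EDGE_THRESHOLD:
        reasons.append(f"edge ratio {er:.3f} > {EDGE_THRESHOLD}")
    if wr > WM_VENT_THRESHOLD:
        reasons.append(f"wm/ventricle ratio {wr:.3f} > {WM_VENT_THRESHOLD}")
    if fr > FREQ_THRESHOLD:
        reasons.append(f"high/low frequency ratio {fr:.3f} > {FREQ_THRESHOLD}")
    return Classification(not reasons, reasons, er, wr, fr)


def butterworth_bandpass(
    timeseries, tr: float, band: Tuple[float, float] = (0.008, 0.1), order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of (multi-)channel time series.

    Applied forward-backward (filtfilt) so no phase shift is introduced;
    the DC component falls outside the pass band and is removed.
    """
    ts = np.asarray(timeseries, dtype=float)
    fs = 1.0 / tr
    nyq = fs / 2
    if not 0 < band[0] < band[1] < nyq:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq:.3f})")
    if ts.shape[0] <= 3 * (2 * order + 1):
        raise ValueError("series too short for the filter order")
    sos = sp_signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sp_signal.sosfiltfilt(sos, ts, axis=0)


def nuisance_regress(timeseries, regressors) -> np.ndarray:
    """Least-squares removal of nuisance regressors from each channel.

    ``regressors`` is a T x q matrix (e.g. six rigid-body motion
    parameters plus global, white-matter and ventricular signals, all
    band-pass filtered beforehand, as the pipeline's order of operations
    requires).  An intercept is included.  Residuals are returned.
    """
    Y = np.asarray(timeseries, dtype=float)
    R = np.asarray(regressors, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    if R.shape[0] != Y.shape[0]:
        raise ValueError("regressors and series have different lengths")
    X = np.column_stack([np.ones(R.shape[0]), R])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient regressor matrix")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta
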