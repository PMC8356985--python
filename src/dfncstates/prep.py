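"""Component time-course postprocessing: detrend, despike, low-pass filter.

The despike step is a tanh spike-compression scheme: with robust scale
``s = sqrt(pi/2) * median(|x|)`` (the half-normal absolute-moment estimator),
points beyond ``c1`` robust-SD units are compressed as

    y = sign(x) * s * (c1 + (c2 - c1) * tanh((|x|/s - c1) / (c2 - c1)))

so every output magnitude stays below ``c2 * s`` while sub-threshold points
pass through unchanged.  The low-pass stage is a zero-phase (forward-backward)
fifth-order Butterworth filter, which squares the magnitude response but
introduces no phase distortion into windowed correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class PrepConfig:
    despike_c1: float = 2.5
    despike_c2: float = 4.0
    filter_order: int = 5
    cutoff_hz: float = 0.15
    tr_seconds: float = 2.0

    def __post_init__(self):
        if not 0 < self.despike_c1 < self.despike_c2:
            raise ValueError("need 0 < c1 < c2")
        if not 0 < self.cutoff_hz < 0.5 / self.tr_seconds:
            raise ValueError("cutoff must lie in (0, Nyquist)")
        if self.filter_order < 1:
            raise ValueError("filter order must be >= 1")


def detrend(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (slope and intercept)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 samples to detrend")
    return sps.detrend(x, type="linear", axis=-1)


def despike(x: np.ndarray, c1: float = 2.5, c2: float = 4.0) -> np.ndarray:
    """Compress outliers with the tanh scheme; never increases any |x_t|."""
    if not 0 < c1 < c2:
        raise ValueError("need 0 < c1 < c2")
    x = np.asarray(x, dtype=float)
    s = np.sqrt(np.pi / 2.0) * np.median(np.abs(x))
    if s == 0.0:
        warnings.warn("despike: zero robust scale, returning input unchanged")
        return x.copy()
    a = np.abs(x) / s
    y = x.copy()
    mask = a > c1
    y[mask] = np.sign(x[mask]) * s * (c1 + (c2 - c1) * np.tanh((a[mask] - c1) / (c2 - c1)))
    return y


def lowpass(x: np.ndarray, cfg: PrepConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth low-pass at ``cfg.cutoff_hz``; DC gain 1.

    Edge handling: odd-reflection padding of length 3*(2*order + 1), clipped
    to the series length, which bounds edge transients on short scans.
    """
    cfg = cfg or PrepConfig()
    x = np.asarray(x, dtype=float)
    T = x.shape[-1]
    if T <= 6 * cfg.filter_order:
        raise ValueError(f"series too short to filter: T={T}")
    nyq = 0.5 / cfg.tr_seconds
    if cfg.cutoff_hz >= nyq:
        raise ValueError("cutoff at or above Nyquist")
    b, a = sps.butter(cfg.filter_order, cfg.cutoff_hz / nyq)
    padlen = min(3 * (2 * cfg.filter_order + 1), T - 1)
    return sps.filtfilt(b, a, x, axis=-1, padtype="odd", padlen=padlen)


def spectral_quality_ratio(x: np.ndarray, tr_seconds: float = 2.0) -> float:
    """Periodogram power in (0, 0.1] Hz over power in [0.15, 0.25] Hz.

    A component dominated by low-frequency signal (as expected of hemodynamic
    sources) scores high; a noise-dominated component scores near or below
    the flat-spectrum value of 1.  Returns +inf when the denominator band is
    empty of power.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for the spectral ratio")
    f, p = sps.periodogram(x, fs=1.0 / tr_seconds)
    num = p[(f > 0) & (f <= 0.1)].sum()
    den = p[(f >= 0.15) & (f <= 0.25)].sum()
    if den == 0.0:
        return np.inf
    return float(num / den)


def prep_series(x: np.ndarray, cfg: PrepConfig | None = None) -> np.ndarray:
    """Full postprocessing of one series: detrend -> despike -> low-pass."""
    cfg = cfg or PrepConfig()
    return lowpass(despike(detrend(x), cfg.despike_c1, cfg.despike_c2), cfg)


def prep_timecourses(X: np.ndarray, cfg: PrepConfig | None = None) -> np.ndarray:
    """Apply ``prep_series`` to every column of a T x N matrix."""
    cfg = cfg or PrepConfig()
    X = np.asarray(X, dtype=float)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = prep_series(X[:, j], cfg)
    return out


def prep_cohort(cohort, cfg: PrepConfig | None = None):
    """Postprocess every subject of a cohort, returning a new cohort object."""
    from .synthetic import CohortTimecourses

    cfg = cfg or replace(PrepConfig(), tr_seconds=cohort.tr_seconds)
    data = np.stack([prep_timecourses(cohort.data[i], cfg) for i in range(cohort.n_subjects)])
    return CohortTimecourses(
        list(cohort.subject_ids), data, cohort.manifest.copy(), cohort.partition, cohort.tr_seconds
    )
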