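"""Correlation, autocorrelation, lag and spectral feature extraction.

The central idea: the CVP and IJV-CSA pulses are poorly correlated in the
time domain because the vein's response lags the pressure wave, yet their
autocorrelation signals are nearly aligned because both pulses share the same
spectral content (Wiener-Khinchin).  The model's predictors are therefore the
autocorrelation r-values of the CSA pulse on a sparse lag grid (every 20
samples from 0 to 360) plus the mean CSA.

The autocorrelation uses the standard biased normalization: a single
full-series mean and the lag-0 sum of squares in the denominator,

    r_h = sum_t (y_t - ybar)(y_{t+h} - ybar) / sum_t (y_t - ybar)^2,

which is the convention of the classical sample ACF.  The lag grid is in
SAMPLES, not seconds, even though the sampling interval varies across
subjects (0.003-0.016 s): each subject's features live on its own grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_core import SignalValidationError, SubjectRecord, TimeSeriesSignal

__all__ = [
    "AutocorrFeatures",
    "LagResult",
    "SpectralSummary",
    "DegenerateSignalError",
    "NoPeriodicityError",
    "autocorrelation",
    "extract_features",
    "pearson_r",
    "cross_correlation_lag",
    "periodogram_topk",
    "freq_from_autocorr",
    "ensemble_mean_acf",
    "acf_similarity",
    "features_to_frame",
    "DEFAULT_LAG_STEP",
    "DEFAULT_MAX_LAG",
]

DEFAULT_LAG_STEP = 20
DEFAULT_MAX_LAG = 360


class DegenerateSignalError(ValueError):
    """Signal has zero variance; correlation statistics are undefined."""


class NoPeriodicityError(ValueError):
    """No positive-lag autocorrelogram peak; periodicity is undefined."""


@dataclass
class AutocorrFeatures:
    """Per-subject feature vector: ACF r-values on the lag grid + mean CSA."""

    subject_id: str
    lag_grid: np.ndarray
    r_values: np.ndarray
    csa_mean: float
    dt: Optional[float] = None

    def __post_init__(self) -> None:
        self.lag_grid = np.asarray(self.lag_grid, dtype=int)
        self.r_values = np.asarray(self.r_values, dtype=float)
        if self.lag_grid.shape != self.r_values.shape:
            raise SignalValidationError("lag_grid and r_values must align")
        if np.any(np.abs(self.r_values) > 1 + 1e-12):
            raise SignalValidationError("autocorrelation r-value outside [-1, 1]")

    def r_at(self, lag: int) -> float:
        idx = np.flatnonzero(self.lag_grid == lag)
        if idx.size == 0:
            raise SignalValidationError(f"lag {lag} not on the feature grid")
        return float(self.r_values[idx[0]])

    def as_dict(self) -> dict:
        d = {"subject_id": self.subject_id, "csa_mean": self.csa_mean}
        for lag, r in zip(self.lag_grid, self.r_values):
            d[f"lag{int(lag)}"] = float(r)
        return d


@dataclass(frozen=True)
class LagResult:
    """Signed lag (samples) maximizing the cross-correlation, plus timing."""

    incremental_lag: int
    dt: float
    peak_r: float

    @property
    def lag_time(self) -> float:
        return self.incremental_lag * self.dt


@dataclass(frozen=True)
class SpectralSummary:
    """Top-k dominant periodogram frequencies with matched amplitudes."""

    frequencies_hz: np.ndarray
    amplitudes: np.ndarray
    k: int = 5


def _demeaned(signal: TimeSeriesSignal) -> np.ndarray:
    x = signal.values
    d = x - np.mean(x)
    if not np.any(d):
        raise DegenerateSignalError("constant signal")
    return d


def autocorrelation(signal: TimeSeriesSignal, max_lag: int) -> np.ndarray:
    """Sample ACF at lags 0..max_lag with biased (lag-0) normalization."""
    n = len(signal)
    if not (0 <= max_lag < n):
        raise SignalValidationError(f"max_lag must be in [0, {n - 1}]")
    d = _demeaned(signal)
    # zero-padded FFT autocorrelation (Wiener-Khinchin); identical to the
    # direct lagged-product sum up to rounding
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(d, nfft)
    raw = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    return raw / raw[0]


def extract_features(
    record: SubjectRecord,
    lag_step: int = DEFAULT_LAG_STEP,
    max_lag: int = DEFAULT_MAX_LAG,
) -> AutocorrFeatures:
    """ACF r-values of the CSA pulse on the lag grid plus the mean CSA."""
    if len(record.csa) <= max_lag:
        raise SignalValidationError(
            f"CSA trace of {record.subject_id!r} shorter than max_lag+1 "
            f"({len(record.csa)} <= {max_lag})"
        )
    grid = np.arange(0, max_lag + 1, lag_step)
    acf = autocorrelation(record.csa, max_lag)
    return AutocorrFeatures(
        subject_id=record.subject_id,
        lag_grid=grid,
        r_values=acf[grid],
        csa_mean=float(np.mean(record.csa.values)),
        dt=record.csa.dt,
    )


def pearson_r(x: TimeSeriesSignal, y: TimeSeriesSignal) -> float:
    """Product-moment correlation between two equal-length traces."""
    if len(x) != len(y):
        raise SignalValidationError("pearson_r requires equal lengths")
    dx, dy = _demeaned(x), _demeaned(y)
    return float(np.dot(dx, dy) / np.sqrt(np.dot(dx, dx) * np.dot(dy, dy)))


def cross_correlation_lag(
    x: TimeSeriesSignal, y: TimeSeriesSignal, max_lag: Optional[int] = None
) -> LagResult:
    """Signed lag (samples) at which corr(x_{t+k}, y_t) is maximal.

    With x = CVP and y = CSA, a vein pulse that trails the pressure wave
    yields a negative lag, matching the sign convention of the classical
    cross-correlation function.  Default search window is a quarter of the
    trace length.
    """
    n = len(x)
    if len(y) != n:
        raise SignalValidationError("cross_correlation_lag requires equal lengths")
    if abs(x.dt - y.dt) > 1e-9:
        raise SignalValidationError("cross_correlation_lag requires equal dt")
    if max_lag is None:
        max_lag = n // 4
    if max_lag >= n:
        raise SignalValidationError("max_lag must be smaller than the trace length")
    dx, dy = _demeaned(x), _demeaned(y)
    denom = np.sqrt(np.dot(dx, dx) * np.dot(dy, dy))
    # np.correlate(dx, dy, 'full')[n-1+k] = sum_t dx_{t+k} dy_t
    cc = np.correlate(dx, dy, mode="full") / denom
    lags = np.arange(-(n - 1), n)
    window = (lags >= -max_lag) & (lags <= max_lag)
    cc, lags = cc[window], lags[window]
    best = int(np.argmax(cc))
    return LagResult(incremental_lag=int(lags[best]), dt=x.dt, peak_r=float(cc[best]))


def periodogram_topk(signal: TimeSeriesSignal, k: int = 5) -> SpectralSummary:
    """Top-k local maxima of the mean-removed amplitude spectrum, in Hz.

    Plain FFT periodogram without tapering; a peak is a local maximum over
    3 bins.  Amplitudes come back sorted non-increasing.
    """
    if len(signal) < 8:
        raise SignalValidationError("periodogram needs at least 8 samples")
    d = _demeaned(signal)
    amp = np.abs(np.fft.rfft(d))
    freqs = np.fft.rfftfreq(len(d), d=signal.dt)
    peaks, _ = sps.find_peaks(amp)  # strict 3-bin local maxima
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(amp[1:])) + 1])
    order = peaks[np.argsort(amp[peaks])[::-1]][:k]
    return SpectralSummary(
        frequencies_hz=freqs[order], amplitudes=amp[order], k=k
    )


def freq_from_autocorr(acf_values: Sequence[float], dt: float, prominence: float = 0.05) -> float:
    """Dominant frequency from autocorrelogram periodicity, f = 1/(D*dt).

    D is the mean spacing of the positive-lag autocorrelogram peaks (local
    maxima with the given prominence and positive r), counting lag 0 as the
    first peak.
    """
    acf = np.asarray(acf_values, dtype=float)
    peaks, _ = sps.find_peaks(acf, prominence=prominence, height=0.0)
    peaks = peaks[peaks > 0]
    if peaks.size == 0:
        raise NoPeriodicityError("no positive-lag autocorrelogram peak")
    spacing = np.diff(np.concatenate(([0], peaks)))
    D = float(np.mean(spacing))
    return 1.0 / (D * dt)


def ensemble_mean_acf(curves: Iterable) -> np.ndarray:
    """Point-wise mean of ACF curves across subjects (common lag grid)."""
    rows = []
    grid = None
    for c in curves:
        if isinstance(c, AutocorrFeatures):
            g, r = c.lag_grid, c.r_values
        else:
            r = np.asarray(c, dtype=float)
            g = np.arange(r.size)
        if grid is None:
            grid = g
        elif g.shape != grid.shape or np.any(g != grid):
            raise SignalValidationError("ensemble_mean_acf requires a common lag grid")
        rows.append(r)
    if not rows:
        raise SignalValidationError("ensemble_mean_acf needs at least one curve")
    return np.mean(np.vstack(rows), axis=0)


def acf_similarity(x_acf: Sequence[float], y_acf: Sequence[float]) -> float:
    """Pearson correlation between two full-resolution autocorrelation curves."""
    a = np.asarray(x_acf, dtype=float)
    b = np.asarray(y_acf, dtype=float)
    if a.shape != b.shape:
        raise SignalValidationError("acf curves must have equal length")
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.dot(da, da), np.dot(db, db)
    if na == 0 or nb == 0:
        raise DegenerateSignalError("constant acf curve")
    return float(np.dot(da, db) / np.sqrt(na * nb))


def features_to_frame(features: Sequence[AutocorrFeatures]) -> pd.DataFrame:
    """One row per subject: subject_id, csa_mean, lag0..lag360 columns."""
    return pd.DataFrame([f.as_dict() for f in features])
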