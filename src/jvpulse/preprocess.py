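"""Synchronization, non-cardiac frequency removal and length conforming.

The IJV-CSA pulse is contaminated by the thoracic pump: respiration modulates
the vein's cross-section in a band well below the cardiac fundamental
(~0.15-0.4 Hz versus ~1 Hz).  The default filter is a zero-phase Butterworth
band-pass, 0.5-10 Hz, order 4, applied forward-backward, which leaves the
cardiac band untouched (within 1 dB) while attenuating the respiratory band by
well over 20 dB.  The trace mean is preserved: the band-pass acts on the
demeaned fluctuation and the mean is restored afterwards, because the mean
CSA is itself a predictor in the pressure model and must survive filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import signal as sps

from .signal_core import (
    SignalValidationError,
    SubjectRecord,
    TimeSeriesSignal,
)

__all__ = [
    "FilterSpec",
    "SyncError",
    "remove_noncardiac",
    "detect_r_peaks",
    "synchronize",
    "conform_lengths",
    "resample",
]


class SyncError(RuntimeError):
    """Trace synchronization failed (e.g. no detectable R-peaks)."""


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification for non-cardiac frequency removal."""

    low_cutoff_hz: float = 0.5
    high_cutoff_hz: float = 10.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, dt: float) -> None:
        nyquist = 0.5 / dt
        if not (0 <= self.low_cutoff_hz < self.high_cutoff_hz):
            raise SignalValidationError("cutoffs must satisfy 0 <= low < high")
        if self.high_cutoff_hz >= nyquist and math.isfinite(self.high_cutoff_hz):
            raise SignalValidationError(
                f"high cutoff {self.high_cutoff_hz} Hz >= Nyquist {nyquist:g} Hz"
            )
        if self.low_cutoff_hz >= nyquist:
            raise SignalValidationError("low cutoff at or above Nyquist")


def remove_noncardiac(signal: TimeSeriesSignal, spec: FilterSpec = FilterSpec()) -> TimeSeriesSignal:
    """Suppress respiratory/thoracic-pump content, keeping the cardiac band.

    Returns a same-length signal.  Zero-phase (forward-backward) filtering is
    used by default so the filter introduces no lag between the CSA and CVP
    traces; edges are reflect-padded to suppress transients on short traces.
    """
    spec.validate(signal.dt)
    if len(signal) <= 3 * spec.order:
        raise SignalValidationError("signal too short for the requested filter order")
    fs = 1.0 / signal.dt
    if math.isinf(spec.high_cutoff_hz):
        sos = sps.butter(spec.order, spec.low_cutoff_hz, btype="highpass", fs=fs, output="sos")
    elif spec.low_cutoff_hz == 0:
        sos = sps.butter(spec.order, spec.high_cutoff_hz, btype="lowpass", fs=fs, output="sos")
    else:
        sos = sps.butter(
            spec.order,
            [spec.low_cutoff_hz, spec.high_cutoff_hz],
            btype="bandpass",
            fs=fs,
            output="sos",
        )
    mean = float(np.mean(signal.values))
    x = signal.values - mean
    if spec.zero_phase:
        # pad by ~3 periods of the slowest retained component so the
        # filter transient dies inside the padding, not the 10-15 s trace
        low = spec.low_cutoff_hz if spec.low_cutoff_hz > 0 else spec.high_cutoff_hz
        padlen = min(len(signal) - 1, int(round(3.0 / (low * signal.dt))))
        y = sps.sosfiltfilt(sos, x, padtype="odd", padlen=padlen)
    else:
        y = sps.sosfilt(sos, x)
    return signal.with_values(y + mean)


def detect_r_peaks(ecg: TimeSeriesSignal, refractory_s: float = 0.3) -> np.ndarray:
    """Indices of R-peaks: local maxima above mean + 2 SD with a refractory window."""
    x = ecg.values
    threshold = float(np.mean(x) + 2.0 * np.std(x))
    distance = max(1, int(round(refractory_s / ecg.dt)))
    peaks, _ = sps.find_peaks(x, height=threshold, distance=distance)
    return peaks


def synchronize(
    record: SubjectRecord,
    method: Literal["ecg_rpeak", "cross_correlation", "none"] = "ecg_rpeak",
) -> SubjectRecord:
    """Align the CVP trace with the CSA trace so their reference events coincide.

    ``ecg_rpeak`` aligns the first R-peak of the ECG co-recorded with each
    trace; ``cross_correlation`` aligns the traces directly at the lag
    maximizing their cross-correlation; ``none`` marks the record synchronized
    as-is.  The applied shift (in samples, positive = CVP-side channels moved
    earlier) is stored on the returned record.
    """
    if method == "none":
        return replace(record, synchronized=True, sync_shift_samples=0)

    if record.cvp is None:
        raise SyncError("record has no CVP trace to synchronize")
    if abs(record.csa.dt - record.cvp.dt) > 1e-9:
        raise SignalValidationError("synchronize requires equal dt (resample first)")

    if method == "ecg_rpeak":
        if record.ecg is None or record.cvp_ecg is None:
            raise SyncError("ecg_rpeak synchronization needs an ECG channel on both traces")
        p_csa = detect_r_peaks(record.ecg)
        p_cvp = detect_r_peaks(record.cvp_ecg)
        if len(p_csa) < 2 or len(p_cvp) < 2:
            raise SyncError("fewer than 2 R-peaks detected above adaptive threshold")
        shift = int(p_cvp[0] - p_csa[0])
    elif method == "cross_correlation":
        a = record.csa.values - np.mean(record.csa.values)
        b = record.cvp.values - np.mean(record.cvp.values)
        cc = np.correlate(b, a, mode="full")
        shift = int(np.argmax(cc) - (len(a) - 1))
    else:
        raise SignalValidationError(f"unknown synchronization method {method!r}")

    def _shift(sig):
        if sig is None:
            return None
        if shift > 0:
            return sig.with_values(sig.values[shift:])
        if shift < 0:
            return sig.with_values(sig.values[:shift])
        return sig

    rec = replace(
        record,
        cvp=_shift(record.cvp),
        cvp_ecg=_shift(record.cvp_ecg),
        synchronized=False,
        sync_shift_samples=shift,
    )
    return conform_lengths(rec)


def conform_lengths(record: SubjectRecord) -> SubjectRecord:
    """Truncate both traces to the shorter common length (index 0 aligned)."""
    if record.cvp is None:
        return replace(record, synchronized=True)
    if abs(record.csa.dt - record.cvp.dt) > 1e-9:
        raise SignalValidationError("conform_lengths requires equal dt (resample first)")
    n = min(len(record.csa), len(record.cvp))

    def _cut(sig):
        return None if sig is None else (sig if len(sig) == n else sig.with_values(sig.values[:n]))

    return replace(
        record,
        csa=_cut(record.csa),
        cvp=_cut(record.cvp),
        ecg=_cut(record.ecg),
        cvp_ecg=_cut(record.cvp_ecg),
        synchronized=True,
        sync_shift_samples=record.sync_shift_samples,
    )


def resample(signal: TimeSeriesSignal, new_dt: float) -> TimeSeriesSignal:
    """Linear-interpolation resampling onto a uniform grid of the same span.

    Linear interpolation is exact on affine signals and free of ringing; the
    traces here are short and heavily oversampled relative to the cardiac
    band, so spectral resampling buys nothing.
    """
    if not (new_dt > 0):
        raise SignalValidationError("new_dt must be positive")
    if new_dt > signal.duration:
        raise SignalValidationError("new_dt exceeds the trace duration")
    old_t = signal.time
    n_new = int(math.floor(signal.duration / new_dt)) + 1
    new_t = np.arange(n_new) * new_dt
    values = np.interp(new_t, old_t, signal.values)
    return TimeSeriesSignal(values, new_dt, label=signal.label, units=signal.units)
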