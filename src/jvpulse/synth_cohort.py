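"""Synthetic paired CVP / IJV-CSA / ECG waveform cohorts with ground truth.

The generator emulates the statistical structure the analysis relies on:

* a dominant cardiac oscillation just under or near 1 Hz in both traces;
* a secondary harmonic at twice the cardiac frequency, stronger in the CVP
  pulse than in the vein's cross-sectional area;
* respiratory-band modulation (default 0.25 Hz) additive on the CSA trace
  only, standing in for the thoracic pump;
* the CSA pulse trailing the CVP pulse by a lag of order 0.24 s, implemented
  as an exact index shift on a shared grid (both traces stay equal length);
* additive white noise on each trace in its own units.

Default pulse amplitudes and the distributions used for cohort draws follow
the clinical cohort's descriptive statistics: mean CVP 5.998 +/- 2.874 cmH2O,
mean CSA 0.984 +/- 0.497 cm^2, within-trace SDs near 1.21 cmH2O and 0.05 cm^2,
lag 0.241 +/- 0.175 s, sampling intervals 0.003-0.016 s, 10-15 s clips.

A cohort can optionally be wired to a known sparse linear ground-truth model:
each subject's mean CVP is then set to that linear function of its realized
CSA features (plus noise), which makes full-pipeline parameter recovery
testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import features as feat
from .signal_core import (
    SignalValidationError,
    SubjectRecord,
    TimeSeriesSignal,
    Units,
)

__all__ = ["WaveformSpec", "CohortSpec", "generate_subject", "generate_cohort", "write_cohort"]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class WaveformSpec:
    """Per-subject waveform parameters (one simulated recording)."""

    cardiac_hz: float = 1.0
    secondary_harmonic_ratio: float = 0.5     # CVP 2nd harmonic / fundamental
    csa_secondary_fraction: float = 0.3       # CSA keeps this fraction of it
    respiratory_hz: float = 0.25
    respiratory_amplitude: float = 0.4        # fraction of the CSA pulse amplitude
    lag_s: float = 0.24                       # CSA trails CVP by this much
    cvp_pulse_amp: float = 1.21 * _SQRT2      # cmH2O; trace SD ~= 1.21
    csa_pulse_amp: float = 0.05 * _SQRT2      # cm^2;  trace SD ~= 0.05
    noise_sd_cvp: float = 0.15                # cmH2O
    noise_sd_csa: float = 0.006               # cm^2
    dt: float = 0.008
    duration_s: float = 12.0
    cvp_mean: float = 5.998
    csa_mean: float = 0.984

    def validate(self) -> None:
        if self.dt <= 0 or self.duration_s <= 0:
            raise SignalValidationError("dt and duration_s must be positive")
        if self.cardiac_hz <= 0 or self.cardiac_hz >= 0.5 / self.dt:
            raise SignalValidationError("cardiac_hz must lie in (0, Nyquist)")
        for name in (
            "secondary_harmonic_ratio",
            "csa_secondary_fraction",
            "respiratory_amplitude",
            "cvp_pulse_amp",
            "csa_pulse_amp",
            "noise_sd_cvp",
            "noise_sd_csa",
        ):
            if getattr(self, name) < 0:
                raise SignalValidationError(f"{name} must be non-negative")
        if self.lag_s < 0:
            raise SignalValidationError("lag_s must be non-negative")


def generate_subject(spec: WaveformSpec, seed: int, subject_id: str = "synthetic") -> SubjectRecord:
    """Simulate one subject's paired CVP / CSA / ECG traces on a common grid.

    The CSA cardiac content is the CVP cardiac content delayed by
    ``round(lag_s / dt)`` samples (exact index shift), rescaled to the CSA
    pulse amplitude and with a weaker second harmonic; respiration and noise
    are then added.  The ECG is a narrow-spike train phase-locked to the CVP
    cardiac fundamental.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s / spec.dt)) + 1
    shift = int(round(spec.lag_s / spec.dt))

    phase = rng.uniform(0, 2 * np.pi)
    phase2 = rng.uniform(0, 2 * np.pi)
    phase_r = rng.uniform(0, 2 * np.pi)

    # shared cardiac components on an extended grid; CVP reads them `shift`
    # samples ahead of CSA, so the CSA pulse trails by exactly `shift` samples
    t_ext = np.arange(n + shift) * spec.dt
    fund = np.sin(2 * np.pi * spec.cardiac_hz * t_ext + phase)
    harm = np.sin(4 * np.pi * spec.cardiac_hz * t_ext + phase2)

    cvp_core = fund[shift:] + spec.secondary_harmonic_ratio * harm[shift:]
    csa_core = fund[:n] + spec.secondary_harmonic_ratio * spec.csa_secondary_fraction * harm[:n]

    t = np.arange(n) * spec.dt
    cvp = spec.cvp_mean + spec.cvp_pulse_amp * cvp_core
    if spec.noise_sd_cvp > 0:
        cvp = cvp + rng.normal(0, spec.noise_sd_cvp, n)

    csa = spec.csa_mean + spec.csa_pulse_amp * csa_core
    if spec.respiratory_amplitude > 0:
        csa = csa + (
            spec.respiratory_amplitude
            * spec.csa_pulse_amp
            * np.sin(2 * np.pi * spec.respiratory_hz * t + phase_r)
        )
    if spec.noise_sd_csa > 0:
        csa = csa + rng.normal(0, spec.noise_sd_csa, n)

    # R-spikes where the CVP cardiac phase crosses multiples of 2*pi
    cvp_phase = 2 * np.pi * spec.cardiac_hz * t_ext[shift:] + phase
    beat_times = (np.arange(np.ceil(cvp_phase[0] / (2 * np.pi)),
                            cvp_phase[-1] / (2 * np.pi) + 1) * 2 * np.pi - phase) / (
        2 * np.pi * spec.cardiac_hz
    ) - shift * spec.dt
    ecg = np.zeros(n)
    width = max(0.01, 2 * spec.dt)
    for bt in beat_times:
        ecg += np.exp(-0.5 * ((t - bt) / width) ** 2)

    return SubjectRecord(
        subject_id=subject_id,
        csa=TimeSeriesSignal(csa, spec.dt, label="csa", units=Units.cm2),
        cvp=TimeSeriesSignal(cvp, spec.dt, label="cvp", units=Units.cmH2O),
        ecg=TimeSeriesSignal(ecg, spec.dt, label="ecg", units=Units.au),
        synchronized=True,
        meta={"spec": spec, "lag_samples": shift, "seed": seed},
    )


@dataclass
class CohortSpec:
    """Distributional parameters for a cohort of simulated subjects.

    Each ``(mean, sd)`` pair is sampled per subject from a normal (ranges
    from a uniform); values are truncated to their physical bounds.  When
    ``ground_truth_model`` is given (predictor name -> coefficient, plus an
    ``"intercept"`` entry), each subject's mean CVP is set to that linear
    function of its realized CSA features plus ``ground_truth_noise_sd``.
    """

    n_subjects: int = 34
    seed: int = 0
    cardiac_hz: Tuple[float, float] = (1.0, 0.1)
    cvp_mean: Tuple[float, float] = (5.998, 2.874)
    csa_mean: Tuple[float, float] = (0.984, 0.497)
    cvp_pulse_amp: Tuple[float, float] = (1.21 * _SQRT2, 0.462 * _SQRT2)
    csa_pulse_amp: Tuple[float, float] = (0.05 * _SQRT2, 0.03 * _SQRT2)
    lag_s: Tuple[float, float] = (0.241, 0.175)
    dt_range: Tuple[float, float] = (0.003, 0.016)
    duration_range_s: Tuple[float, float] = (10.0, 15.0)
    secondary_ratio_range: Tuple[float, float] = (0.3, 0.7)
    respiratory_hz_range: Tuple[float, float] = (0.2, 0.3)
    respiratory_amp_range: Tuple[float, float] = (0.2, 0.5)
    noise_sd_cvp: float = 0.15
    noise_sd_csa: float = 0.006
    ground_truth_model: Optional[Dict[str, float]] = None
    ground_truth_noise_sd: float = 0.0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise SignalValidationError("cohort needs at least 2 subjects")
        for name in ("cardiac_hz", "cvp_mean", "csa_mean", "lag_s", "cvp_pulse_amp", "csa_pulse_amp"):
            if getattr(self, name)[1] < 0:
                raise SignalValidationError(f"{name} SD must be non-negative")
        if self.ground_truth_noise_sd < 0:
            raise SignalValidationError("ground_truth_noise_sd must be non-negative")


def _truncated_normal(rng, mean, sd, low, high=np.inf):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if low <= v <= high:
            return float(v)
    return float(min(max(mean, low), high))


def generate_cohort(spec: CohortSpec) -> Tuple[List[SubjectRecord], pd.DataFrame]:
    """Simulate a cohort; returns the records and a ground-truth table.

    Identical ``spec.seed`` reproduces the cohort bit-for-bit.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(spec.n_subjects + 1)[1:]]

    records: List[SubjectRecord] = []
    truth_rows = []
    for i in range(spec.n_subjects):
        wf = WaveformSpec(
            cardiac_hz=_truncated_normal(param_rng, *spec.cardiac_hz, 0.6, 1.8),
            secondary_harmonic_ratio=param_rng.uniform(*spec.secondary_ratio_range),
            respiratory_hz=param_rng.uniform(*spec.respiratory_hz_range),
            respiratory_amplitude=param_rng.uniform(*spec.respiratory_amp_range),
            lag_s=_truncated_normal(param_rng, *spec.lag_s, 0.0),
            cvp_pulse_amp=_truncated_normal(param_rng, *spec.cvp_pulse_amp, 0.3),
            csa_pulse_amp=_truncated_normal(param_rng, *spec.csa_pulse_amp, 0.01),
            noise_sd_cvp=spec.noise_sd_cvp,
            noise_sd_csa=spec.noise_sd_csa,
            dt=param_rng.uniform(*spec.dt_range),
            duration_s=param_rng.uniform(*spec.duration_range_s),
            cvp_mean=_truncated_normal(param_rng, *spec.cvp_mean, -5.0, 25.0),
            csa_mean=_truncated_normal(param_rng, *spec.csa_mean, 0.15),
        )
        subject_id = f"synth{i + 1:03d}"
        rec = generate_subject(wf, subject_seeds[i], subject_id=subject_id)

        if spec.ground_truth_model is not None:
            f = feat.extract_features(rec)
            row = f.as_dict()
            target = spec.ground_truth_model.get("intercept", 0.0)
            for name, coef in spec.ground_truth_model.items():
                if name == "intercept":
                    continue
                if name not in row:
                    raise SignalValidationError(f"ground-truth predictor {name!r} not a feature")
                target += coef * row[name]
            if spec.ground_truth_noise_sd > 0:
                target += param_rng.normal(0, spec.ground_truth_noise_sd)
            delta = target - float(np.mean(rec.cvp.values))
            rec = replace(rec, cvp=rec.cvp.with_values(rec.cvp.values + delta))
            wf = replace(wf, cvp_mean=wf.cvp_mean + delta)

        records.append(rec)
        truth_rows.append(
            {
                "subject_id": subject_id,
                "cvp_mean": float(np.mean(rec.cvp.values)),
                "csa_mean": wf.csa_mean,
                "lag_s": wf.lag_s,
                "lag_samples": rec.meta["lag_samples"],
                "cardiac_hz": wf.cardiac_hz,
                "dt": wf.dt,
                "duration_s": wf.duration_s,
                "secondary_harmonic_ratio": wf.secondary_harmonic_ratio,
                "respiratory_amplitude": wf.respiratory_amplitude,
                "seed": subject_seeds[i],
            }
        )
    return records, pd.DataFrame(truth_rows)


def write_cohort(records: List[SubjectRecord], truth: pd.DataFrame, outdir) -> None:
    """One signal file per subject plus a ground_truth.csv table."""
    from pathlib import Path

    from .signal_core import write_signal

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_signal(rec, outdir / f"{rec.subject_id}.csv")
    truth.to_csv(outdir / "ground_truth.csv", index=False)
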