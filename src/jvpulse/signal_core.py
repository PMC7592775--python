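"""Domain types, units and columnar file I/O shared by all pipeline stages.

The pipeline works on short (10-15 s) uniformly sampled physiological traces:
the internal-jugular-vein cross-sectional area (IJV-CSA, cm^2) pulse obtained
from B-mode ultrasound, the invasively measured central venous pressure
(CVP, cmH2O) and an ECG used only as a timing anchor.  Time is represented by
a sampling interval ``dt`` plus a 0-based index; absolute timestamps are not
retained because every downstream computation is lag/index based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Units",
    "PressureUnits",
    "TimeSeriesSignal",
    "SubjectRecord",
    "PressureValue",
    "MMHG_TO_CMH2O",
    "convert_pressure",
    "read_signal",
    "write_signal",
    "SignalValidationError",
    "SignalFormatError",
]

#: Fixed conversion constant, chosen to reproduce the clinical normal-range
#: bounds 2 mmHg -> 2.72 cmH2O and 8 mmHg -> 10.88 cmH2O at two decimals.
MMHG_TO_CMH2O = 1.35951


class SignalValidationError(ValueError):
    """A signal or record violates a structural invariant."""


class SignalFormatError(ValueError):
    """A columnar signal file cannot be parsed as requested."""


class Units(str, Enum):
    cm2 = "cm2"
    cmH2O = "cmH2O"
    au = "au"


class PressureUnits(str, Enum):
    mmHg = "mmHg"
    cmH2O = "cmH2O"


@dataclass(frozen=True)
class TimeSeriesSignal:
    """A uniformly sampled trace: values, sampling interval, label and units."""

    values: np.ndarray
    dt: float
    label: str = ""
    units: Units = Units.au

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not (self.dt > 0):
            raise SignalValidationError(f"dt must be positive, got {self.dt}")
        if values.ndim != 1 or values.size < 2:
            raise SignalValidationError("signal needs at least 2 samples")
        if not np.all(np.isfinite(values)):
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise SignalValidationError(f"non-finite value at index {bad}")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds, ``(n - 1) * dt``."""
        return (len(self) - 1) * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt

    def with_values(self, values: np.ndarray) -> "TimeSeriesSignal":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class SubjectRecord:
    """One subject's paired IJV-CSA / CVP / ECG traces plus metadata.

    ``ecg`` is the channel co-recorded with the CSA trace; ``cvp_ecg`` is the
    channel co-recorded with the CVP trace (pressure monitors record their
    own ECG) and exists only to drive R-peak synchronization.
    """

    subject_id: str
    csa: TimeSeriesSignal
    cvp: Optional[TimeSeriesSignal] = None
    ecg: Optional[TimeSeriesSignal] = None
    cvp_ecg: Optional[TimeSeriesSignal] = None
    synchronized: bool = False
    sync_shift_samples: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.synchronized and self.cvp is not None:
            if len(self.csa) != len(self.cvp):
                raise SignalValidationError(
                    "synchronized record requires equal-length csa and cvp"
                )
            if abs(self.csa.dt - self.cvp.dt) > 1e-9:
                raise SignalValidationError(
                    "synchronized record requires equal dt for csa and cvp"
                )


@dataclass(frozen=True)
class PressureValue:
    magnitude: float
    units: PressureUnits

    def __post_init__(self) -> None:
        if not isinstance(self.units, PressureUnits):
            object.__setattr__(self, "units", PressureUnits(self.units))


def convert_pressure(
    p: PressureValue, target_units: Union[PressureUnits, str]
) -> PressureValue:
    """Convert a pressure between mmHg and cmH2O (1 mmHg = 1.35951 cmH2O)."""
    target = PressureUnits(target_units)
    if p.units == target:
        return p
    if p.units == PressureUnits.mmHg and target == PressureUnits.cmH2O:
        return PressureValue(p.magnitude * MMHG_TO_CMH2O, target)
    if p.units == PressureUnits.cmH2O and target == PressureUnits.mmHg:
        return PressureValue(p.magnitude / MMHG_TO_CMH2O, target)
    raise SignalValidationError(f"unknown pressure conversion {p.units} -> {target}")


# ---------------------------------------------------------------------------
# Columnar file I/O
#
# Dialect: plain delimiter-separated text, one header row, delimiter
# auto-detected among comma / tab / semicolon.  Canonical column names are
# time_s, csa_cm2, cvp_cmh2o, ecg_au (any subset after time_s).

_CANONICAL_COLUMNS = {
    "csa": ("csa_cm2", Units.cm2),
    "cvp": ("cvp_cmh2o", Units.cmH2O),
    "ecg": ("ecg_au", Units.au),
}


def _sniff_delimiter(path: Path) -> str:
    header = path.read_text().splitlines()[0]
    counts = {d: header.count(d) for d in (",", "\t", ";")}
    return max(counts, key=counts.get)


def _uniform_dt(time: np.ndarray) -> float:
    """Sampling interval of a time column, rejecting non-uniform spacing.

    Deviations larger than 1% of the median step flag an irregular grid.
    """
    steps = np.diff(time)
    dt = float(np.median(steps))
    if dt <= 0:
        raise SignalValidationError("time column is not strictly increasing")
    if np.max(np.abs(steps - dt)) > 0.01 * dt:
        bad = int(np.argmax(np.abs(steps - dt))) + 1
        raise SignalValidationError(
            f"non-uniform time spacing at row {bad}: step deviates >1% from dt={dt:g}"
        )
    return dt


def read_signal(
    path: Union[str, Path],
    column_spec: Optional[Mapping[str, str]] = None,
    dt: Union[float, str] = "from-file",
    subject_id: Optional[str] = None,
) -> SubjectRecord:
    """Read a columnar signal file into a :class:`SubjectRecord`.

    Parameters
    ----------
    path:
        Delimiter-separated text file with one header row.
    column_spec:
        Mapping of roles (``csa``, ``cvp``, ``ecg``, ``time``) to column
        names in the file.  Defaults to the canonical names.
    dt:
        Sampling interval in seconds, or ``"from-file"`` to derive it from
        the time column (which must then be uniform to within 1%).
    """
    path = Path(path)
    if not path.exists():
        raise SignalFormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), float_precision="round_trip")

    spec = dict(column_spec) if column_spec else {}
    spec.setdefault("time", "time_s")
    for role, (canon, _) in _CANONICAL_COLUMNS.items():
        if role not in spec and canon in df.columns:
            spec[role] = canon
    if "csa" not in spec:
        raise SignalFormatError(f"{path}: no CSA column resolvable")
    missing = [c for c in spec.values() if c not in df.columns]
    if missing:
        raise SignalFormatError(f"{path}: missing column(s) {missing}")

    for col in spec.values():
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            row = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise SignalValidationError(f"{path}: non-finite entry in {col!r} row {row}")

    if dt == "from-file":
        dt_val = _uniform_dt(df[spec["time"]].to_numpy(dtype=float))
    else:
        dt_val = float(dt)

    signals = {}
    for role, (canon, units) in _CANONICAL_COLUMNS.items():
        if role in spec and spec[role] in df.columns:
            signals[role] = TimeSeriesSignal(
                df[spec[role]].to_numpy(dtype=float), dt_val, label=role, units=units
            )
    return SubjectRecord(
        subject_id=subject_id or path.stem,
        csa=signals["csa"],
        cvp=signals.get("cvp"),
        ecg=signals.get("ecg"),
    )


def write_signal(record: SubjectRecord, path: Union[str, Path], delimiter: str = ",") -> None:
    """Write a record as columnar text (header names carry the units).

    Serializes with 17 significant digits so a read-back round-trip is exact.
    """
    path = Path(path)
    cols = {"time_s": record.csa.time}
    cols["csa_cm2"] = record.csa.values
    for role, sig in (("cvp_cmh2o", record.cvp), ("ecg_au", record.ecg)):
        if sig is not None:
            if len(sig) != len(record.csa):
                raise SignalValidationError(
                    f"cannot serialize ragged record {record.subject_id!r}"
                )
            cols[role] = sig.values
    df = pd.DataFrame(cols)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
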