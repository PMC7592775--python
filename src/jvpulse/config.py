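"""Pipeline configuration: defaults, YAML round-trip, flat key access."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .published import NORMAL_RANGE_CMH2O

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs beyond the input data."""

    filter_low_hz: float = 0.5
    filter_high_hz: float = 10.0
    filter_order: int = 4
    apply_filter: bool = True
    sync_method: str = "none"
    resample_dt: Optional[float] = None      # None = keep each subject's grid
    lag_step: int = 20
    max_lag: int = 360
    selection_strategy: str = "exhaustive"
    cv_k: int = 10
    cv_seed: int = 0
    class_bounds_cmh2o: Tuple[float, float] = NORMAL_RANGE_CMH2O

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_bounds_cmh2o"] = list(self.class_bounds_cmh2o)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "class_bounds_cmh2o" in d:
            d["class_bounds_cmh2o"] = tuple(d["class_bounds_cmh2o"])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
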