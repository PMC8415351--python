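"""Pipeline configuration: one serializable object binding all stages.

The config round-trips losslessly through YAML; unknown keys are
rejected so a typo never silently falls back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .constants import PhysioConstants
from .fitting import FitConfig
from .phantom import PhantomConfig, TissueClass

__all__ = ["PipelineConfig", "load_config", "save_config"]

_CASES = ("dr", "ndr-enlarged", "ndr-equal", "single", "cohort")


@dataclass
class PipelineConfig:
    """Everything one reproducible simulate → fit → analyze → report run needs."""

    stages: list[str] = field(default_factory=lambda: ["simulate", "fit", "analyze", "report"])
    case: str = "dr"
    seed: int = 0
    output_dir: str = "qqoef_out"
    verbosity: str = "INFO"
    constants: dict[str, float] = field(default_factory=dict)
    fit: dict[str, Any] = field(default_factory=dict)
    phantom: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known_stages = {"simulate", "fit", "analyze", "report"}
        bad = set(self.stages) - known_stages
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.case not in _CASES:
            raise ValueError(f"unknown case {self.case!r}; choose from {_CASES}")

    # -- materialized sub-configs -------------------------------------
    def physio_constants(self) -> PhysioConstants:
        return PhysioConstants.from_dict({**PhysioConstants().to_dict(), **self.constants})

    def fit_config(self) -> FitConfig:
        d = {"seed": self.seed, **self.fit}
        known = set(FitConfig.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise KeyError(f"unknown fit keys: {sorted(bad)}")
        for key in ("y_bounds", "nu_bounds", "r2_bounds", "s0_bounds", "chi_nb_bounds"):
            if key in d and d[key] is not None:
                lo, hi = d[key]
                d[key] = (lo, np.inf if hi is None else hi)
        return FitConfig(**d)

    def phantom_config(self) -> PhantomConfig:
        d = {"seed": self.seed, **self.phantom}
        known = set(PhantomConfig.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise KeyError(f"unknown phantom keys: {sorted(bad)}")
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if "lesion_center_frac" in d:
            d["lesion_center_frac"] = tuple(d["lesion_center_frac"])
        if "lesion_axes_mm" in d:
            d["lesion_axes_mm"] = tuple(d["lesion_axes_mm"])
        if "tissue_table" in d:
            d["tissue_table"] = {k: TissueClass(**v) if isinstance(v, dict) else v
                                 for k, v in d["tissue_table"].items()}
        return PhantomConfig(**d)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise KeyError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return path
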