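"""Pipeline configuration: every tunable of the processing stages with its
default, serializable as YAML."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import yaml


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters and the global seed for one pipeline run."""

    seed: int = 0
    out_dir: str = "angioquant_out"
    # geometry overrides applied to the reference device
    geometry: Dict[str, Any] = dataclasses.field(default_factory=dict)
    # preprocessing
    median_window: int = 3
    background_k_sigma: float = 3.0
    # monolayer detection
    band_halfwidth_um: float = 10.0
    combine_weights: Tuple[float, float] = (0.7, 0.3)
    invert_transmitted: bool = True
    refit_monolayer_48hr: bool = False
    # metrics
    offset_um: float = 10.0
    ar_cap: float = 100.0
    # transport
    transport: Dict[str, Any] = dataclasses.field(default_factory=dict)
    # ensemble
    welch_ttest: bool = True

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["combine_weights"] = list(self.combine_weights)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "combine_weights" in d:
            d["combine_weights"] = tuple(d["combine_weights"])
        return cls(**d)
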