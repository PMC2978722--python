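"""Pipeline configuration: one object holding every stage's parameters.

Serializable to/from YAML so a run is reproducible from (data, config,
seed) alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .preprocess import EmaParams
from .ranking import CnrWindows

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    ema: EmaParams = field(default_factory=EmaParams)
    cnr_windows: CnrWindows = field(default_factory=CnrWindows)
    cnr_mode: str = "pooled_samples"
    rank_chromophore: str = "oxy"
    history_s: float = 1.0
    svm_c: float = 128.0
    #: cap on the channel-count sweep in the full pipeline
    max_channels: int = 16
    #: below this test accuracy, delays are reported as undefined in sweeps
    delay_accuracy_floor: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if self.max_channels < 1:
            raise ValueError("max_channels must be >= 1")
        if not 0 <= self.delay_accuracy_floor <= 1:
            raise ValueError("delay_accuracy_floor must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "ema" in d and isinstance(d["ema"], dict):
            d["ema"] = EmaParams(**d["ema"])
        if "cnr_windows" in d and isinstance(d["cnr_windows"], dict):
            w = {k: tuple(v) for k, v in d["cnr_windows"].items()}
            d["cnr_windows"] = CnrWindows(**w)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
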