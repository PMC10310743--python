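"""One validated configuration document driving the whole pipeline.

YAML round-trips losslessly; every pipeline output embeds the fully
resolved configuration plus tool version for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .drsa import DRSAConfig

__all__ = ["AnalysisConfig"]


@dataclass
class StimulusConfig:
    n_stimuli: int = 14
    n_markers: int = 13
    duration_s: float = 5.0
    fs: float = 100.0
    cutoff_hz: float = 2.0
    height: int = 64
    width: int = 60
    marker_sigma: float = 2.0


@dataclass
class ModelConfig:
    sigma: float = 5.0
    vertical_axis: int = 2
    names: list[str] = field(default_factory=lambda: [
        "pixelwise", "flow_magnitude", "flow_direction",
        "posture_vd", "posture_vi", "motion_vd", "motion_vi",
        "accel_vd", "gaze",
    ])


@dataclass
class NeuralConfig:
    # each implant: [model name, weight, lag_s]
    implants: list[list] = field(default_factory=lambda: [["posture_vd", 1.0, 0.0]])
    noise_weight: float = 0.0
    n_subjects: int = 1


@dataclass
class StatsConfig:
    sample_alpha: float = 0.01
    cluster_alpha: float = 0.05
    n_perm: int = 25_000


@dataclass
class AnalysisConfig:
    stimuli: StimulusConfig = field(default_factory=StimulusConfig)
    models: ModelConfig = field(default_factory=ModelConfig)
    kernel_ms: float = 30.0
    drsa: DRSAConfig = field(default_factory=DRSAConfig)
    estimator: str = "pcr"
    test_models: list[str] | None = None
    neural: NeuralConfig = field(default_factory=NeuralConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    tool_version: str = __version__

    def __post_init__(self) -> None:
        if self.estimator not in ("pcr", "correlation"):
            raise ValueError("estimator must be 'pcr' or 'correlation'")
        if self.kernel_ms < 0:
            raise ValueError("kernel_ms must be >= 0")
        if self.drsa.segment_s > self.stimuli.duration_s:
            raise ValueError("segment_s must not exceed stimulus duration")
        if self.drsa.lag_range_s >= self.drsa.segment_s:
            raise ValueError("lag_range_s must be smaller than segment_s")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        kwargs = {}
        for key, sub in (("stimuli", StimulusConfig), ("models", ModelConfig),
                         ("drsa", DRSAConfig), ("neural", NeuralConfig),
                         ("stats", StatsConfig)):
            if key in d:
                kwargs[key] = sub(**d.pop(key))
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
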