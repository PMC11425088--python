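"""Schema-validated YAML run configuration.

Pydantic models with ``extra="forbid"`` so typos in config keys fail fast,
before any computation starts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .commutation_control import ControllerConfig
from .errors import ParameterError
from .pose_io import ArenaSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ArenaConfig(_Strict):
    kind: Literal["circular", "linear", "open_field"] = "circular"
    size_m: float = Field(gt=0, default=0.345)
    px_per_m: float = Field(gt=0, default=1000.0)
    fps: float = Field(gt=0, le=1000, default=10.0)

    def to_runtime(self) -> ArenaSpec:
        return ArenaSpec(self.kind, self.size_m, self.px_per_m, self.fps)


class ControllerSection(_Strict):
    rotation_threshold_deg: float = Field(gt=0, le=360, default=90.0)
    conf_threshold: float = Field(ge=0, le=1, default=0.9)
    stride: int = Field(ge=1, default=5)
    n_segments: int = Field(ge=1, default=8)
    track_length_m: float = Field(gt=0, default=1.2)
    rotation_speed_dps: float = Field(gt=0, default=100.0)
    translation_speed_mps: float = Field(gt=0, default=0.2)
    compensation: Literal["accumulated", "threshold"] = "accumulated"
    hysteresis_m: float = Field(ge=0, default=0.0)

    def to_runtime(self) -> ControllerConfig:
        return ControllerConfig(**self.model_dump())


class PipelineSection(_Strict):
    outlier_sd: float = Field(gt=0, default=5.0)
    bin_fraction: float = Field(gt=0, le=1, default=0.8)
    bandpass_low_hz: float = Field(gt=0, default=0.1)
    bandpass_high_hz: float = Field(gt=0, default=5.0)
    filter_order: int = Field(ge=1, default=3)
    ripple_db: float = Field(gt=0, default=0.5)
    smooth_px: int = Field(ge=1, default=7)
    baseline: Literal["trial_mean", "rolling_percentile"] = "trial_mean"
    correction: Literal["ratiometric", "regression"] = "ratiometric"
    mask_vote: float = Field(gt=0, le=1, default=0.5)

    def to_runtime(self):
        from .calcium_pipeline import PreprocessingPipeline
        return PreprocessingPipeline(
            outlier_sd=self.outlier_sd, bin_fraction=self.bin_fraction,
            bandpass=(self.bandpass_low_hz, self.bandpass_high_hz),
            filter_order=self.filter_order, ripple_db=self.ripple_db,
            smooth_px=self.smooth_px, baseline=self.baseline,
            correction=self.correction, mask_vote=self.mask_vote)


class PethSection(_Strict):
    pre_s: float = Field(ge=0, default=2.0)
    post_s: float = Field(gt=0, default=10.0)
    n_boot: int = Field(ge=10, default=1000)
    alpha: float = Field(gt=0, lt=1, default=0.05)
    method: Literal["empirical", "sd"] = "empirical"

    @property
    def window_s(self) -> Tuple[float, float]:
        return (self.pre_s, self.post_s)


class RunConfig(_Strict):
    arena: ArenaConfig = ArenaConfig()
    controller: ControllerSection = ControllerSection()
    pipeline: PipelineSection = PipelineSection()
    peth: PethSection = PethSection()
    seed: int = 0
    out_dir: Optional[str] = None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ParameterError(f"invalid configuration {path}:\n{exc}") from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)
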