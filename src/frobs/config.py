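"""Run configuration: validated, hashable, loadable from YAML.

Every field has a documented default; unknown keys are rejected so a
typo in a config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .circuits import PRESETS, CircuitParams, ShuntSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CircuitConfig(_Strict):
    """Either a named preset or explicit element values."""

    preset: Optional[str] = None
    topology: Optional[Literal["uncoated", "coated"]] = None
    Rs: Optional[float] = None
    Cdl: Optional[float] = None
    RCT: Optional[float] = None
    Q: Optional[float] = None
    n: Optional[float] = None
    sigma_W: Optional[float] = None
    coated_form: Literal["parallel", "series"] = "parallel"

    def to_params(self) -> CircuitParams:
        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ValueError(f"unknown circuit preset {self.preset!r}")
            return PRESETS[self.preset]
        return CircuitParams(
            topology=self.topology,
            Rs=self.Rs,
            Cdl=self.Cdl,
            RCT=self.RCT,
            Q=self.Q,
            n=self.n,
            sigma_w=self.sigma_W,
        )


class ShuntConfig(_Strict):
    Cs: float = 3e-9  # total shunt capacitance, F

    def to_spec(self) -> ShuntSpec:
        return ShuntSpec(C_wires_connector=self.Cs, C_amplifier=0.0)


class BandConfig(_Strict):
    name: str
    f_low: float
    f_high: float


class DetectionConfig(_Strict):
    k: float = 3.0                 # envelope threshold in robust-RMS units
    min_duration_s: float = 0.006
    merge_gap_s: float = 0.010
    pad_s: float = 0.050


class SegmentationConfig(_Strict):
    smooth_sigma: float = 1.0      # 2-D Gaussian, in (time bin, freq bin) units
    extent_fraction: float = 0.5   # of the basin peak, for onset/offset
    f_step_hz: float = 5.0
    n_cycles: float = 6.0          # spectrogram wavelet width


class StatsConfig(_Strict):
    alternative: Literal["greater"] = "greater"  # coated > uncoated


class ScenarioConfig(_Strict):
    name: Literal["paper_like"] = "paper_like"
    duration_s: float = 60.0
    n_events: int = 20
    fs_hz: float = 2048.0


class RunConfig(_Strict):
    """Full pipeline configuration for one reproducible run."""

    out_dir: str = "run_out"
    seed: int = 0
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    circuit_a: CircuitConfig = Field(default_factory=lambda: CircuitConfig(preset="au"))
    circuit_b: CircuitConfig = Field(default_factory=lambda: CircuitConfig(preset="au_pedot"))
    shunt: ShuntConfig = Field(default_factory=ShuntConfig)
    bands: Optional[list[BandConfig]] = None  # None = canonical eight bands
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: Path | str | None = None, **overrides) -> RunConfig:
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    return RunConfig.model_validate(data)
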