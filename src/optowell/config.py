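"""Experiment configuration: schema-validated YAML/JSON files.

A config fully determines a run: the twin's parameters (seed, CVs, noise),
growth and circuit parameters, the per-well map of protocols and policies,
the measurement plan, and paths to calibration artifacts.  Validation is
aggregated: a bad file reports every violation at once.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .control import FeedbackPolicy, MeasurementPlan, StimProtocol
from .culture import ExpressionCircuit, GrowthParams, WellCulture
from .twin import (DEFAULT_ADC_MAX, DEFAULT_FLUOR_GAIN, DEFAULT_NOISE_SD,
                   DEFAULT_OD_PATHLENGTH_FACTOR, DEFAULT_OD_SCATTER_CV,
                   DEFAULT_UV_BLEEDTHROUGH, PWM_MAX, PlateTwin, ROLES)
from .wells import WELLS

_WELL_SET = set(WELLS)


class TwinSettings(BaseModel):
    seed: int = 0
    adc_max: int = Field(DEFAULT_ADC_MAX, ge=1)
    noise_sd: float = Field(DEFAULT_NOISE_SD, ge=0)
    gain_cv: dict[str, float] = Field(default_factory=dict)
    od_scatter_cv: float = Field(DEFAULT_OD_SCATTER_CV, ge=0)
    uv_bleedthrough: float = Field(DEFAULT_UV_BLEEDTHROUGH, ge=0)
    od_pathlength_factor: float = Field(DEFAULT_OD_PATHLENGTH_FACTOR, gt=0)
    fluor_gain: float = Field(DEFAULT_FLUOR_GAIN, gt=0)

    @field_validator("gain_cv")
    @classmethod
    def _roles_known(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown component roles: {sorted(unknown)}")
        if any(cv < 0 for cv in v.values()):
            raise ValueError("gain CVs must be >= 0")
        return v

    def build(self) -> PlateTwin:
        return PlateTwin(seed=self.seed, adc_max=self.adc_max,
                         noise_sd=self.noise_sd, gain_cv=self.gain_cv,
                         od_scatter_cv=self.od_scatter_cv,
                         uv_bleedthrough=self.uv_bleedthrough,
                         od_pathlength_factor=self.od_pathlength_factor,
                         fluor_gain=self.fluor_gain)


class GrowthSettings(BaseModel):
    rate: float = Field(0.5, gt=0)
    carrying_capacity: float = Field(1.0, gt=0)
    lag: float = Field(1.0, ge=0)
    shaking_multiplier: float = Field(2.0, ge=1)

    def build(self) -> GrowthParams:
        return GrowthParams(**self.model_dump())


class CircuitSettings(BaseModel):
    kind: Literal["none", "arabinose", "pDawn", "pDusk"] = "none"
    k_prod: float = Field(8.0, ge=0)
    half_max_light: float = Field(30.0, gt=0)
    hill_n: float = Field(2.0, ge=1)
    switch_delay: float = Field(0.5, ge=0)

    def build(self) -> ExpressionCircuit:
        return ExpressionCircuit(**self.model_dump())


class ProtocolSettings(BaseModel):
    intensity: int = Field(0, ge=0, le=PWM_MAX)
    t_on: float = Field(0.0, ge=0)
    t_off: float = Field(0.0, ge=0)
    active: bool = True

    def build(self) -> StimProtocol:
        return StimProtocol(**self.model_dump())


class PolicySettings(BaseModel):
    kind: Literal["constant", "stop_on_fluorescence", "start_on_od"] = \
        "constant"
    threshold: Optional[float] = None
    wells: list[str]

    @model_validator(mode="after")
    def _check(self) -> "PolicySettings":
        bad = [w for w in self.wells if w.upper() not in _WELL_SET]
        if bad:
            raise ValueError(f"unknown wells in policy: {bad}")
        if self.kind != "constant" and self.threshold is None:
            raise ValueError(f"{self.kind} policy requires a threshold")
        return self

    def build(self) -> FeedbackPolicy:
        return FeedbackPolicy(kind=self.kind, threshold=self.threshold,
                              wells=tuple(w.upper() for w in self.wells))


class PlanSettings(BaseModel):
    od_period_min: float = Field(20.0, gt=0)
    fluor_period_min: float = Field(20.0, gt=0)
    n_avg: int = Field(100, ge=1)
    duration_h: float = Field(18.0, gt=0)

    def build(self) -> MeasurementPlan:
        return MeasurementPlan(**self.model_dump())


class WellSettings(BaseModel):
    circuit: str = "default"
    protocol: str = "dark"
    initial_turbidity: float = Field(0.05, ge=0)
    inducer: bool = False


class ExperimentConfig(BaseModel):
    """Top-level, fully validated experiment description."""

    seed: int = 0
    twin: TwinSettings = Field(default_factory=TwinSettings)
    growth: GrowthSettings = Field(default_factory=GrowthSettings)
    circuits: dict[str, CircuitSettings] = Field(default_factory=dict)
    protocols: dict[str, ProtocolSettings] = Field(default_factory=dict)
    wells: dict[str, WellSettings] = Field(default_factory=dict)
    policies: list[PolicySettings] = Field(default_factory=list)
    plan: PlanSettings = Field(default_factory=PlanSettings)
    od_transform_csv: Optional[str] = None
    calibration_dir: Optional[str] = None

    @model_validator(mode="after")
    def _cross_checks(self) -> "ExperimentConfig":
        errors = []
        for w in self.wells:
            if w.upper() not in _WELL_SET:
                errors.append(f"unknown well {w!r} (expected A1..H12)")
        for w, ws in self.wells.items():
            if ws.circuit not in self.circuits and ws.circuit != "default":
                errors.append(f"well {w}: undefined circuit {ws.circuit!r}")
            if ws.protocol not in self.protocols and ws.protocol != "dark":
                errors.append(f"well {w}: undefined protocol {ws.protocol!r}")
        seen: dict[str, int] = {}
        for i, pol in enumerate(self.policies):
            for w in pol.wells:
                wu = w.upper()
                if wu in seen:
                    errors.append(
                        f"well {w} assigned to policies {seen[wu]} and {i}")
                seen[wu] = i
                if wu not in {x.upper() for x in self.wells}:
                    errors.append(f"policy {i}: well {w} has no assignment")
        if errors:
            raise ValueError("; ".join(errors))
        return self

    # ------------------------------------------------------------- builders
    def build_cultures(self) -> dict[str, WellCulture]:
        return {w.upper(): WellCulture(turbidity=ws.initial_turbidity)
                for w, ws in self.wells.items()}

    def build_circuits(self) -> dict[str, ExpressionCircuit]:
        default = CircuitSettings()
        out = {}
        for w, ws in self.wells.items():
            settings = self.circuits.get(ws.circuit, default)
            out[w.upper()] = settings.build()
        return out

    def build_protocols(self) -> dict[str, StimProtocol]:
        dark = ProtocolSettings()
        return {w.upper(): self.protocols.get(ws.protocol, dark).build()
                for w, ws in self.wells.items()}

    def inducer_wells(self) -> frozenset[str]:
        return frozenset(w.upper() for w, ws in self.wells.items()
                         if ws.inducer)

    def config_hash(self) -> str:
        """SHA-256 over the canonical JSON form; recorded in run outputs."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML or JSON experiment config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text))
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return ExperimentConfig.model_validate(data)
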