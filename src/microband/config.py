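"""Validated pipeline configuration.

All knobs of the end-to-end run live here: simulation design and
dynamics, band edges, sampling-rate targets, clustering settings,
outlier thresholds, cross-validation mode and forest size.  Unknown keys
are rejected, and every random choice traces back to the explicit seeds.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from microband.preprocess import BandSpec
from microband.synthetic import DynamicsSpec, StudyDesign


class EffectConfig(BaseModel):
    """A planted group difference in class-A dwell dynamics."""

    model_config = ConfigDict(extra="forbid")

    group: str = "MUD"
    conditions: list[str] | None = None   # None = every condition
    delta_duration_a_ms: float = 0.0


class SimulationConfig(BaseModel):
    """Synthetic-study design and dynamics parameters."""

    model_config = ConfigDict(extra="forbid")

    n_per_group: int = 20
    trials_per_condition: int = 15
    trial_s: float = 7.0
    gap_s: float = 7.0
    fs_hz: float = 500.0
    n_channels: int = 31
    resting_duration_s: float = 110.0
    mean_duration_ms: list[float] = Field(
        default_factory=lambda: [120.0, 100.0, 90.0, 80.0])
    duration_shape: float = 20.0
    carrier_freq_hz: float = 10.0
    snr: float = 5.0
    amplitude_uv: float = 10.0
    effect: EffectConfig = Field(default_factory=EffectConfig)

    def study_design(self) -> StudyDesign:
        return StudyDesign(
            n_per_group=self.n_per_group,
            trials_per_condition=self.trials_per_condition,
            trial_s=self.trial_s, gap_s=self.gap_s, fs_hz=self.fs_hz,
            n_channels=self.n_channels,
            resting_duration_s=self.resting_duration_s)

    def dynamics_specs(self) -> dict[tuple[str, str], DynamicsSpec]:
        design = self.study_design()
        base = DynamicsSpec(
            mean_duration_ms=np.asarray(self.mean_duration_ms, float),
            duration_shape=self.duration_shape,
            carrier_freq_hz=self.carrier_freq_hz, snr=self.snr,
            amplitude_uv=self.amplitude_uv)
        specs = {(g, c): base for g in design.groups
                 for c in design.conditions}
        eff = self.effect
        if eff.delta_duration_a_ms:
            conds = eff.conditions or list(design.conditions)
            for c in conds:
                mean = base.mean_duration_ms.copy()
                mean[0] += eff.delta_duration_a_ms
                specs[(eff.group, c)] = base.with_mean_durations(mean)
        return specs


class PipelineConfig(BaseModel):
    """Full configuration of one end-to-end run."""

    model_config = ConfigDict(extra="forbid")

    sim: SimulationConfig = Field(default_factory=SimulationConfig)
    bands: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "all": (4.0, 45.0), "theta": (4.0, 7.0), "alpha": (8.0, 12.0),
            "beta": (13.0, 28.0), "gamma": (29.0, 45.0)})
    target_fs: float = 250.0
    transition_hz: float = 2.0
    k: int = 4
    n_restarts: int = 20
    peak_cap_per_subject: int = 1000
    max_duration_ms: float = 250.0
    cv_mode: str = "trial"
    n_trees: int = 500
    importance_cell: tuple[str, str] = ("alpha", "resting")
    ancova_cell: tuple[str, str] = ("alpha", "resting")
    seed: int = 0
    write_edf: bool = False

    @field_validator("cv_mode")
    @classmethod
    def _cv_mode_known(cls, v: str) -> str:
        if v not in ("trial", "subject"):
            raise ValueError("cv_mode must be 'trial' or 'subject'")
        return v

    @field_validator("bands")
    @classmethod
    def _bands_valid(cls, v):
        if "all" not in v:
            raise ValueError("an 'all' band must be configured")
        for name, (lo, hi) in v.items():
            BandSpec(name, lo, hi)  # range validation
        return v

    def band_specs(self) -> dict[str, BandSpec]:
        return {name: BandSpec(name, lo, hi)
                for name, (lo, hi) in self.bands.items()}

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(self.model_dump_json())))

    def config_hash(self) -> str:
        payload = json.dumps(json.loads(self.model_dump_json()),
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
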