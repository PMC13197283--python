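"""Run configuration: YAML-backed, schema-validated, round-trippable.

A :class:`RunConfig` collects everything needed to reproduce a run: the
disease-stage preset and its overridable physiological parameters, the
network scale, all random seeds, solver tolerance and output options.
Every default traces to the reference parameter tables or to a documented
modelling convention; :meth:`RunConfig.provenance` distinguishes defaults
from user overrides.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .cirrhosis import DEFAULT_EARLY_SEG23_MEAN_FRACTION, stage_parameters

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    stage: Literal["healthy", "early", "advanced"] = "healthy"
    lobule_count: int = Field(20_000, ge=1, le=5_000_000)
    network_seed: int = 0
    sampling_seed: int = 1
    optimizer_seed: int = 2
    solver_tolerance: float = Field(1e-10, gt=0)

    collateral_fraction: float = Field(0.01, gt=0)
    sinusoid_family: Optional[Literal["lognormal", "gaussian", "degenerate"]] = None
    early_seg23_mean_fraction: float = Field(
        DEFAULT_EARLY_SEG23_MEAN_FRACTION, gt=0, le=1
    )
    pv_base_radius_mm: Optional[float] = Field(None, gt=0)
    hematocrit: float = Field(0.45, gt=0, lt=1)

    output_dir: str = "results"
    report_units: Literal["clinical", "si"] = "clinical"

    def to_model(self):
        """Build the :class:`~hepaflow.model.LiverModel` this config describes."""
        from dataclasses import replace

        from .model import LiverModel
        from .rheology import ViscosityModel

        stage = stage_parameters(
            self.stage,
            family=self.sinusoid_family,
            early_seg23_mean_fraction=self.early_seg23_mean_fraction,
            collateral_fraction=self.collateral_fraction,
        )
        if self.pv_base_radius_mm is not None:
            stage = replace(stage, pv_base_radius_mm=self.pv_base_radius_mm)
        return LiverModel(
            stage=stage,
            lobule_count=self.lobule_count,
            network_seed=self.network_seed,
            sampling_seed=self.sampling_seed,
            viscosity=ViscosityModel(hematocrit=self.hematocrit),
            solver_tolerance=self.solver_tolerance,
        )

    def provenance(self) -> dict:
        """Per-field origin: ``"override"`` if user-set, else ``"default"``."""
        return {
            name: ("override" if name in self.model_fields_set else "default")
            for name in type(self).model_fields
        }


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        keys = sorted({str(e["loc"][0]) for e in exc.errors() if e["loc"]})
        raise ConfigError(
            f"invalid configuration keys/values: {keys}\n{exc}"
        ) from exc


def save_config(config: RunConfig, path):
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
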