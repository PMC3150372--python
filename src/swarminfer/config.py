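"""Run configuration: a validated YAML mirror of model spec, parameters,
grid and run settings.

Configs are strict: unknown keys are rejected and missing required keys are
reported with their full key path (both courtesy of pydantic).  A parsed
config serializes back to an equivalent document, so a run can be
reconstructed bit-identically from its config snapshot plus seeds.
"""

from __future__ import annotations

import hashlib
import math
from importlib import resources
from pathlib import Path
from typing import Dict, List, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .bayes import ParameterGrid, make_grid
from .model import ModelParams, ModelSpec

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "reference_config",
    "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpecBlock(_Strict):
    neighbourhood_scheme: Literal["geometric", "topological"] = "geometric"
    include_alignment: bool = True
    include_attraction: bool = True
    infer_update_rate: bool = False


class ParamsBlock(_Strict):
    attraction_weight: float = 0.0
    alignment_weight: float = 0.0
    interaction_radius: Optional[float] = None
    neighbour_count: Optional[int] = None
    blind_angle: float = 0.0
    noise_sd: float = 0.0
    speed: float = 1.0
    update_prob: float = 1.0
    arena_size: float = 1.0


class AxisBlock(_Strict):
    lower: float
    upper: float
    points: Optional[int] = None
    values: Optional[List[float]] = None

    @model_validator(mode="after")
    def _points_or_values(self):
        if (self.points is None) == (self.values is None):
            raise ValueError("axis needs exactly one of 'points' or 'values'")
        return self


class GridBlock(_Strict):
    axes: Dict[str, AxisBlock]


class BurnInBlock(_Strict):
    threshold: float = 0.8
    window: int = 20
    max_steps: int = 4000


class RunBlock(_Strict):
    n_particles: int = 25
    n_steps: int = 10
    n_seeds: int = 5
    seed: int = 0
    burn_in: BurnInBlock = Field(default_factory=BurnInBlock)


class RunConfig(_Strict):
    schema_version: int = 1
    model: SpecBlock = Field(default_factory=SpecBlock)
    params: Optional[ParamsBlock] = None
    grid: Optional[GridBlock] = None
    run: RunBlock = Field(default_factory=RunBlock)

    # -- converters to domain objects ------------------------------------

    def model_spec(self) -> ModelSpec:
        axes = ()
        if self.grid is not None:
            axes = tuple(
                (name, ax.lower, ax.upper) for name, ax in self.grid.axes.items()
            )
        return ModelSpec(
            neighbourhood_scheme=self.model.neighbourhood_scheme,
            include_alignment=self.model.include_alignment,
            include_attraction=self.model.include_attraction,
            infer_update_rate=self.model.infer_update_rate,
            parameter_axes=axes,
        )

    def model_params(self) -> ModelParams:
        if self.params is None:
            raise ValueError("config has no 'params' block")
        return ModelParams(**self.params.model_dump())

    def parameter_grid(self) -> ParameterGrid:
        if self.grid is None:
            raise ValueError("config has no 'grid' block")
        resolution = {
            name: (ax.points if ax.points is not None else ax.values)
            for name, ax in self.grid.axes.items()
        }
        return make_grid(self.model_spec(), resolution)


def load_config(source: Union[str, Path]) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    text = Path(source).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a YAML mapping")
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path: Optional[Union[str, Path]] = None) -> str:
    """Serialize a config to YAML (round-trips losslessly through load)."""
    text = yaml.safe_dump(
        config.model_dump(exclude_none=True), sort_keys=False
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(config: RunConfig) -> str:
    """Short stable digest of a config, for log lines and reports."""
    canonical = yaml.safe_dump(config.model_dump(exclude_none=True), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def reference_config() -> RunConfig:
    """The bundled reference parameter set (reliably produces a rotating mill)."""
    with resources.files("swarminfer.data").joinpath("reference.yaml").open() as fh:
        return RunConfig.model_validate(yaml.safe_load(fh))
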