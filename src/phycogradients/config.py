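"""Declarative run configuration: validation, defaults, (de)serialization.

A run is described by a nested mapping (YAML or JSON on disk) covering
the plate geometry, transport parameters, organisms and simulation
settings.  Unknown keys are rejected so silent typos cannot change an
experiment; units follow the package conventions (days, µM, mm, µl,
m² s⁻¹, cells ml⁻¹, fmol cell⁻¹ d⁻¹).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .phycosphere import D_DOC_DEFAULT, D_NITRATE_DEFAULT
from . import plate as _plate
from . import community as _community

__all__ = [
    "WallConfig", "ReservoirConfig", "AlgaConfig", "TaxonConfig",
    "RunConfig", "load_config", "save_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class WallConfig(_Strict):
    thickness_mm: float = Field(0.9, gt=0)
    area_mm2: float = Field(15.0, gt=0)
    d_eff_doc: float = Field(_plate.D_EFF_DOC_DEFAULT, gt=0)
    d_eff_nitrate: float = Field(_plate.D_EFF_NITRATE_DEFAULT, gt=0)

    @model_validator(mode="after")
    def _physical_bounds(self) -> "WallConfig":
        if self.d_eff_doc > D_DOC_DEFAULT:
            raise ValueError(
                f"d_eff_doc={self.d_eff_doc} exceeds the free-solution "
                f"diffusivity {D_DOC_DEFAULT} m^2/s")
        if self.d_eff_nitrate > D_NITRATE_DEFAULT:
            raise ValueError(
                f"d_eff_nitrate={self.d_eff_nitrate} exceeds the free-solution "
                f"diffusivity {D_NITRATE_DEFAULT} m^2/s")
        return self

    def build(self) -> _plate.WallParams:
        return _plate.WallParams(**self.model_dump())


class ReservoirConfig(_Strict):
    doc: float = Field(0.0, ge=0)
    nitrate: float = Field(882.0, ge=0)  # f/2-Si nominal
    volume_ml: float | None = Field(None, gt=0)

    def build(self) -> _plate.Reservoir:
        return _plate.Reservoir(**self.model_dump())


class AlgaConfig(_Strict):
    initial_density: float = Field(1e6, ge=0)
    mu_max: float = Field(0.5, gt=0)
    monod_km: float = Field(1.0, gt=0)
    quota_n: float = Field(70.0, gt=0)
    exudation_q: float = Field(60.0, ge=0)

    def build(self) -> _plate.AlgalPopulation:
        return _plate.AlgalPopulation(**self.model_dump())


class TaxonConfig(_Strict):
    name: str
    strategy: _community.Strategy
    mu_max_doc: float = Field(ge=0)
    km_doc: float = Field(gt=0)
    mu_max_n: float = Field(0.0, ge=0)
    km_n: float = Field(20.0, gt=0)
    yield_doc: float = Field(1e8, gt=0)
    yield_n: float = Field(1e9, gt=0)
    mortality: float = Field(0.1, ge=0)
    initial_density: float = Field(1e5, ge=0)

    def build(self) -> _community.TaxonParams:
        return _community.TaxonParams(**self.model_dump())


class RunConfig(_Strict):
    """Everything needed to reproduce one plate run."""

    preset: str = "community_layers"
    days: float = Field(7.0, gt=0)
    dt_out: float = Field(0.1, gt=0)
    wall: WallConfig = WallConfig()
    reservoir: ReservoirConfig = ReservoirConfig()
    alga: AlgaConfig | None = AlgaConfig()
    taxa: tuple[TaxonConfig, ...] = ()
    n_replicates: int = Field(3, ge=1)
    geometric_sd: float = Field(1.3, ge=1.0)
    volume_ul: float | None = Field(None, gt=0)

    def build_layout(self) -> _plate.PlateLayout:
        return _plate.build_layout(
            self.preset, wall=self.wall.build(),
            reservoir=self.reservoir.build(), volume_ul=self.volume_ul)


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a run configuration (YAML/JSON file or mapping).

    An empty file or ``None`` yields the documented defaults; schema
    violations raise with the offending key in the message.
    """
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
    else:
        raw = data or {}
    if not isinstance(raw, dict):
        raise TypeError("configuration root must be a mapping")
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"),
                                         sort_keys=False))
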