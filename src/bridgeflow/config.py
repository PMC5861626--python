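"""Run configuration: one JSON document with generator/geometry/solver/analysis blocks.

Every default the pipeline assumes where the source study is silent (sinus
caliber, vessel lengths, inlet profile, resolution rule, plateau exclusion
sizes) lives here, so a single config file pins a whole run.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, model_validator

from .lbm import BoundaryConditions, FluidProperties, SolverConfig
from .synthetic import GeneratorConfig, GroupSpec

__all__ = [
    "GeneratorSettings",
    "GeometrySettings",
    "FluidSettings",
    "BoundarySettings",
    "SolverSettings",
    "AnalysisSettings",
    "RunConfig",
]


class GroupSettings(BaseModel):
    group: Literal["anterior", "posterior"]
    n: int
    diameter_mean: float
    diameter_sd: float
    diameter_bounds: tuple[float, float]
    angle_mean: float
    angle_sd: float
    angle_bounds: tuple[float, float]

    def to_spec(self) -> GroupSpec:
        return GroupSpec(
            self.group, self.n, self.diameter_mean, self.diameter_sd,
            tuple(self.diameter_bounds), self.angle_mean, self.angle_sd,
            tuple(self.angle_bounds),
        )


def _default_groups() -> list[GroupSettings]:
    return [
        GroupSettings(group="anterior", n=62, diameter_mean=2.0, diameter_sd=0.9,
                      diameter_bounds=(0.6, 5.2), angle_mean=93.0, angle_sd=34.0,
                      angle_bounds=(40.0, 170.0)),
        GroupSettings(group="posterior", n=75, diameter_mean=3.0, diameter_sd=1.1,
                      diameter_bounds=(0.8, 5.8), angle_mean=43.0, angle_sd=25.0,
                      angle_bounds=(10.0, 90.0)),
    ]


class GeneratorSettings(BaseModel):
    seed: int = 0
    correlation: float = 0.0
    on_infeasible: Literal["closest", "error"] = "closest"
    groups: list[GroupSettings] = Field(default_factory=_default_groups)

    def to_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            specs=tuple(g.to_spec() for g in self.groups),
            seed=self.seed,
            correlation=self.correlation,
            on_infeasible=self.on_infeasible,
        )


class GeometrySettings(BaseModel):
    """Junction dimensions (mm). The sinus caliber and the vessel lengths are
    modelling assumptions, not measured quantities — surfaced here on purpose."""

    d_ss: float = 8.0
    l_up: float = 30.0
    l_down: float = 60.0
    l_bv: float = 20.0
    spacing: float | None = None  # explicit grid spacing (mm); None -> rule below
    spacing_divisor: float = 10.0  # spacing = d_bv / divisor ...
    spacing_cap: float = 0.25  # ... capped at this (mm)
    # Angle convention: entry angle measured between the BV inflow direction
    # and the upstream sinus direction; alpha < 90 discharges against the
    # sinus stream (posterior-vein configuration).
    angle_convention: str = "upstream"

    @model_validator(mode="after")
    def _check(self):
        if min(self.d_ss, self.l_up, self.l_down, self.l_bv) <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.spacing_divisor < 8.0:
            raise ValueError("spacing_divisor must be >= 8 (grid-resolution floor)")
        return self

    def spacing_for(self, d_bv: float) -> float:
        if self.spacing is not None:
            return self.spacing
        return min(d_bv / self.spacing_divisor, self.spacing_cap)

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.l_up, self.l_down, self.l_bv)


class FluidSettings(BaseModel):
    density: float = 1050.0
    viscosity: float = 4.24e-3

    def to_properties(self) -> FluidProperties:
        return FluidProperties(self.density, self.viscosity)


class BoundarySettings(BaseModel):
    u_ss_inlet: float = 0.15
    u_bv_inlet: float = 0.10
    outlet_gauge_pressure: float = 0.0
    ambient_pressure: float = 1333.0
    inlet_profile: Literal["uniform", "parabolic"] = "uniform"

    def to_conditions(self) -> BoundaryConditions:
        return BoundaryConditions(
            self.u_ss_inlet, self.u_bv_inlet, self.outlet_gauge_pressure,
            self.ambient_pressure, self.inlet_profile,
        )


class SolverSettings(BaseModel):
    scheme: Literal["lbm_bgk"] = "lbm_bgk"
    tolerance: float = 1e-6
    max_iterations: int = 200_000
    u_lattice: float = 0.05
    relaxation_time: float | None = None
    check_every: int = 1000
    ramp_steps: int = 2000
    avg_steps: int = 20000
    seed: int = 0

    def to_config(self) -> SolverConfig:
        return SolverConfig(
            scheme=self.scheme, tolerance=self.tolerance,
            max_iterations=self.max_iterations, u_lattice=self.u_lattice,
            relaxation_time=self.relaxation_time, check_every=self.check_every,
            ramp_steps=self.ramp_steps, avg_steps=self.avg_steps, seed=self.seed,
        )


class AnalysisSettings(BaseModel):
    inlet_exclusion_widths: float = 5.0  # plateau: widths from the wall's inlet
    entrance_exclusion_spans: float = 3.0  # plateau: mouth spans from the entrance
    diameter_floor: float = 1.2  # mm, excluded from angle-group tables
    angle_cutpoints: tuple[float, float] = (65.0, 105.0)


class RunConfig(BaseModel):
    generator: GeneratorSettings = Field(default_factory=GeneratorSettings)
    geometry: GeometrySettings = Field(default_factory=GeometrySettings)
    fluid: FluidSettings = Field(default_factory=FluidSettings)
    boundary: BoundarySettings = Field(default_factory=BoundarySettings)
    solver: SolverSettings = Field(default_factory=SolverSettings)
    analysis: AnalysisSettings = Field(default_factory=AnalysisSettings)

    @classmethod
    def desk_scale(cls, **overrides) -> "RunConfig":
        """Scaled-down profile for single-workstation sweeps.

        Shorter vessels, the coarsest admissible grid (8 cells across the
        vein) and tighter plateau exclusions sized so SSD/BVU plateaus exist
        across the whole cohort diameter/angle range.
        """
        cfg = cls(
            geometry=GeometrySettings(l_up=14.0, l_down=28.0, l_bv=16.0,
                                      spacing_divisor=8.0, spacing_cap=0.25),
            solver=SolverSettings(max_iterations=70_000),
            analysis=AnalysisSettings(inlet_exclusion_widths=2.0,
                                      entrance_exclusion_spans=1.0),
        )
        return cfg.model_copy(update=overrides) if overrides else cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")
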