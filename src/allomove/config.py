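"""Pipeline configuration: a single validated YAML document.

Unknown keys are rejected so a typo cannot silently fall back to a
default.  Every stochastic stage draws from the single top-level seed.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "load_config"]

_STAGES = ("simulate", "score", "prep", "fit", "decode", "report")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    n_individuals: int = Field(10, ge=1)
    steps_per_individual: int = Field(720, ge=2)
    missing_dive_prob: float = Field(0.25, ge=0.0, le=1.0)
    csi_source: str = "cohort"  # "cohort" | "health"
    n_health_records: int = Field(200, ge=1)
    write_telemetry: bool = False  # also emit locations/depth/raster for `prep`


class HealthSection(_Section):
    quantile_method: str = "linear"
    fixed_thresholds: dict[str, float] | None = None


class TrackSection(_Section):
    max_gap_hours: float = Field(3.0, gt=0)
    frame: str = "planar"


class DiveSection(_Section):
    threshold_m: float = Field(10.0, gt=0)
    bottom_fraction: float = Field(0.8, gt=0, lt=1)
    zoc_window_s: float = Field(7200.0, gt=0)
    zoc_quantile: float = Field(0.05, ge=0, le=1)


class HmmSection(_Section):
    n_states: int = Field(3, ge=1)
    covariate_structure: str = "full"  # none|transitions_only|emissions_only|full
    initial: str = "estimated"
    n_restarts: int = Field(25, ge=1)
    perturbation_sd: float = Field(0.25, gt=0)
    ftol: float = Field(1e-8, gt=0)
    compute_hessian: bool = True
    aic_table: bool = False
    aic_n_states: list[int] = [2, 3, 4]
    curve_grid_max: float = Field(0.75, gt=0)
    curve_grid_points: int = Field(31, ge=2)


class PathsSection(_Section):
    health_csv: str = "health.csv"
    scores_csv: str = "scores.csv"
    streams_csv: str = "streams.csv"
    locations_csv: str = "locations.csv"
    raw_fixes_csv: str = "raw_fixes.csv"
    depth_csv: str = "depth.csv"
    shore_raster: str = "shore.asc"
    prepped_streams_csv: str = "streams_prepped.csv"
    fit_json: str = "fit.json"
    aic_csv: str = "aic_table.csv"
    decoded_csv: str = "decoded.csv"
    budgets_csv: str = "budgets.csv"
    curves_csv: str = "stationary_curves.csv"
    report_md: str = "report.md"


class PipelineConfig(_Section):
    seed: int
    run_dir: str
    stages: list[str] = ["simulate", "score", "fit", "decode", "report"]
    simulate: SimulateSection = SimulateSection()
    health: HealthSection = HealthSection()
    track: TrackSection = TrackSection()
    dive: DiveSection = DiveSection()
    hmm: HmmSection = HmmSection()
    paths: PathsSection = PathsSection()

    def model_post_init(self, _ctx) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}; valid: {list(_STAGES)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def resolve(self, name: str) -> Path:
        return Path(self.run_dir) / getattr(self.paths, name)


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_yaml(path)
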