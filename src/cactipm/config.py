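"""Pipeline configuration: one structured (YAML) file drives a full run."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import SimulationParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; exactly one input source.

    Either ``census_path`` (a census CSV) or ``simulation`` (ground-truth
    parameters for the synthetic generator) must be supplied, never both.
    """

    census_path: str | None = None
    simulation: SimulationParams | None = None
    grid_lower: float = 0.0
    grid_upper: float = 70.0
    grid_n: int = 200
    elongation_growth: str = "G_r"  # growth density applied on elongation
    retracted_survival: bool = True  # keep the s(z°) factor in K_ur
    selection: str = "stepwise"  # 'stepwise' | 'direct'
    random_candidates: tuple[str, ...] = ("individual", "year", "plot")
    force_no_contraction: bool = False
    max_retracted_years: int = 5
    apply_censoring: bool = True
    delta: float = 1e-4  # vital-rate perturbation step
    tol: float = 1e-10  # eigensolver relative tolerance
    max_iter: int = 100_000
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        if (self.census_path is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of census_path or simulation parameters must be supplied"
            )
        if self.selection not in ("stepwise", "direct"):
            raise ValueError("selection must be 'stepwise' or 'direct'")
        if self.elongation_growth not in ("G_r", "G_u"):
            raise ValueError("elongation_growth must be 'G_r' or 'G_u'")
        if self.census_path is not None and not Path(self.census_path).exists():
            raise FileNotFoundError(f"census file not found: {self.census_path}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["random_candidates"] = list(self.random_candidates)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationParams.from_dict(d["simulation"])
        if "random_candidates" in d:
            d["random_candidates"] = tuple(d["random_candidates"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
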