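"""Run configuration: one YAML file driving simulate and analyze.

Sections: ``acquisition`` (gate geometry/timing), ``analysis`` (every
pipeline threshold), ``simulation`` (scene parameters), ``io`` (paths and
formats) and a top-level ``seed``.  Unknown keys are rejected so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import AcquisitionConfig
from .pipeline import AnalysisParams

__all__ = ["SimulationParams", "IOParams", "RunConfig"]


@dataclass
class SimulationParams:
    """Scene-level knobs for the synthetic-data generator."""

    scene: str = "uniform"  # "uniform" (one lifetime) or "fret"
    n_molecules: int = 50
    lifetime: float = 2.5  # ns; tau_DA for the fret scene
    lifetime_donor: float = 3.4  # ns; tau_D, fret scene only
    brightness: float = 500.0  # signal photons / first-gate frame
    sbr: float = 5.0  # box-level signal-to-background ratio
    bleach_scale_pairs: float = 100.0
    warm_pixel_fraction: float = 0.0
    warm_pixel_rate: float = 0.0
    psf_sigma: float = 1.0

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class IOParams:
    stack_format: str = "png"
    results_name: str = "molecules.tsv"

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "IOParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown io keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    io: IOParams = field(default_factory=IOParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "acquisition": self.acquisition.to_dict(),
            "analysis": self.analysis.to_dict(),
            "simulation": self.simulation.to_dict(),
            "io": self.io.to_dict(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"acquisition", "analysis", "simulation", "io", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(
            acquisition=AcquisitionConfig.from_dict(d.get("acquisition", {})),
            analysis=AnalysisParams.from_dict(d.get("analysis", {})),
            simulation=SimulationParams.from_dict(d.get("simulation", {})),
            io=IOParams.from_dict(d.get("io", {})),
            seed=int(d.get("seed", 0)),
        )

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def digest(self) -> str:
        """Short stable hash of the full configuration, for output headers."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
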