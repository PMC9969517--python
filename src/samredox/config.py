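"""YAML run configuration with strict schema validation.

An empty file (or missing sections) means all defaults; unknown keys are
rejected per-field so typos surface immediately. The constants section
round-trips losslessly to the physical-constants record.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .constants import Constants, K_B_EV

__all__ = ["RunConfig", "run_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConstantsConfig(_Strict):
    e_she: float = 4.281  # V, absolute SHE potential
    g_electron_gas: float = -0.867  # kcal/mol, Fermi-Dirac electron
    t_marcus: float = 300.0  # K, sampling-ensemble temperature
    t_thermo: float = 298.15  # K, standard thermochemistry
    k_b: float = K_B_EV  # eV/K
    faraday: float = 1.0  # eV-per-electron <-> V

    def to_constants(self) -> Constants:
        return Constants(**self.model_dump())

    @classmethod
    def from_constants(cls, c: Constants) -> "ConstantsConfig":
        return cls(**c.to_dict())


class BuilderConfig(_Strict):
    coverage: float = 0.70
    seed: int = 0
    cation_site: Literal["none", "central"] = "none"

    @field_validator("coverage")
    @classmethod
    def _coverage_range(cls, v: float) -> float:
        if not 0.0 < v <= 1.0:
            raise ValueError("coverage must lie in (0, 1]")
        return v


class MarcusConfig(_Strict):
    temperature: float = 300.0
    alpha: float = 0.05
    sigma_ratio_low: float = 0.8
    sigma_ratio_high: float = 1.25
    lambda_rel_tol: float = 0.2
    normality_test: Literal["omnibus", "shapiro"] = "omnibus"


class RegionsConfig(_Strict):
    n_ligands: int = 2
    n_au: int = 4
    n_waters: int = 0
    embedding: Literal["mm_point_charges", "continuum", "mm_plus_continuum"] = (
        "mm_plus_continuum"
    )


class BackendConfig(_Strict):
    kind: Literal["mock", "table"] = "mock"
    gap_table: Optional[str] = None
    i0_ev: float = 6.0
    qm_scaling: float = 1.1
    continuum_shift_ev: float = -0.25


class IOConfig(_Strict):
    window_fraction: float = 0.70
    n_snapshots: int = 200
    restraint_k: float = 50.0  # kcal/(mol A^2)


class RunConfig(_Strict):
    constants: ConstantsConfig = Field(default_factory=ConstantsConfig)
    builder: BuilderConfig = Field(default_factory=BuilderConfig)
    marcus: MarcusConfig = Field(default_factory=MarcusConfig)
    regions: RegionsConfig = Field(default_factory=RegionsConfig)
    backend: BackendConfig = Field(default_factory=BackendConfig)
    io: IOConfig = Field(default_factory=IOConfig)

    def thresholds(self):
        from .marcus import DiagnosticThresholds

        return DiagnosticThresholds(
            alpha=self.marcus.alpha,
            sigma_ratio_bounds=(
                self.marcus.sigma_ratio_low,
                self.marcus.sigma_ratio_high,
            ),
            lambda_rel_tol=self.marcus.lambda_rel_tol,
            normality_test=self.marcus.normality_test,
        )


def run_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load and validate a YAML configuration (None or empty -> defaults)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration root must be a mapping")
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
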