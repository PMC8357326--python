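"""Declarative run configuration (TOML) with schema-validated defaults.

Every field has a default; unknown keys are hard errors so that a typo in a
clinic-deployed config file cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field, fields

from .acquisition import AcquisitionConfig
from .calibration import CalibrationConfig
from .simulate import BendingEvent, BendingSchedule, InstrumentModel, default_model
from .spectra import WavelengthGrid, default_grid

__all__ = ["InstrumentConfig", "FlatfieldConfig", "RunConfig", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class InstrumentConfig:
    """Simulator parameters; see :func:`fiberspec.simulate.default_model`."""

    grid_start_nm: float = 400.0
    grid_stop_nm: float = 800.0
    grid_step_nm: float = 0.25
    speckle_contrast: float = 0.02
    read_noise_sd: float = 5.0
    bias_level: float = 120.0
    bias_drift_rate: float = 0.05
    external_level: float = 10.0
    background_excess: float = 1.03
    hgar_shift_nm: float = 0.0       # injected mis-registration (fault injection)
    accumulation_s: float = 0.5

    def grid(self) -> WavelengthGrid:
        return default_grid(self.grid_start_nm, self.grid_stop_nm, self.grid_step_nm)

    def model(self, seed: int) -> InstrumentModel:
        return default_model(
            self.grid(),
            seed=seed,
            speckle_contrast=self.speckle_contrast,
            read_noise_sd=self.read_noise_sd,
            bias_level=self.bias_level,
            bias_drift_rate=self.bias_drift_rate,
            external_level=self.external_level,
        )


@dataclass
class FlatfieldConfig:
    jump_threshold: float = 0.005
    n_sets: int = 20
    mode: str = "sqrt"
    # bending events as [time_s, fiber, factor] triples
    bending: list = field(default_factory=list)

    def schedule(self) -> BendingSchedule:
        return BendingSchedule(
            [BendingEvent(float(t), int(f), float(x)) for t, f, x in self.bending]
        )


@dataclass
class RunConfig:
    seed: int = 0
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    flatfield: FlatfieldConfig = field(default_factory=FlatfieldConfig)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{where}]: {', '.join(sorted(unknown))}; "
            f"allowed: {', '.join(sorted(allowed))}"
        )
    return cls(**data)


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a TOML run configuration; missing sections take defaults."""
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    if overrides:
        data.update(overrides)
    sections = {"instrument", "calibration", "acquisition", "flatfield"}
    unknown = set(data) - sections - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    return RunConfig(
        seed=int(data.get("seed", 0)),
        instrument=_build(InstrumentConfig, data.get("instrument", {}), "instrument"),
        calibration=_build(CalibrationConfig, data.get("calibration", {}), "calibration"),
        acquisition=_build(AcquisitionConfig, data.get("acquisition", {}), "acquisition"),
        flatfield=_build(FlatfieldConfig, data.get("flatfield", {}), "flatfield"),
    )
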