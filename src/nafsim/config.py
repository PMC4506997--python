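"""Run configuration: a single validated, serializable description of a study.

The configuration is flat YAML with one section per pipeline stage.  Unknown
keys are rejected so that a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .phantom import PhantomConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Section):
    domain_size_um: tuple[float, ...] = (8000.0, 8000.0)
    voxel_size_um: float = 5.0
    n_micro: int = 150
    n_macro: int = 6
    micro_radius_um: tuple[float, float] = (6.0, 24.0)
    macro_radius_um: tuple[float, float] = (150.0, 1200.0)
    mineral_density_range: tuple[float, float] = (0.85, 1.0)
    max_attempts: int = 1000

    def to_phantom_config(self) -> PhantomConfig:
        return PhantomConfig(**self.model_dump())


class AdsorptionSection(_Section):
    k_on: float = 4.5e9  # M^-1 min^-1
    k_off: float = 0.0027  # min^-1
    ligand_conc: float = 1.0e-11  # M
    site_density: float = 1.0e12
    incubation_time_min: float = 60.0
    penetration_depth_um: float = 20.0
    sectioned_first: bool = False
    saturable: bool = False


class ImagingSection(_Section):
    hu_bg: float = 0.0
    hu_soft: float = 40.0
    hu_calc: float = 1300.0
    pairs: tuple[tuple[str, str], ...] = (
        ("clinical_pet", "clinical_ct"),
        ("micro_pet", "micro_ct"),
        ("autoradiography", "histology"),
    )


class QuantificationSection(_Section):
    blur_sigma_px: float = 20.0
    hu_threshold: float = 1000.0
    pet_threshold: Literal["otsu", "li"] = "otsu"


class KineticsSection(_Section):
    association_times_min: tuple[float, ...] = (0.0, 5.0, 15.0, 30.0, 60.0)
    wash_times_min: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0)
    calibration_decades: tuple[int, int] = (-12, -7)
    calibration_slope: float = 0.92
    calibration_intercept: float = 13.0
    patlak_ki: float = 0.003  # ml cm^-3 min^-1, plaque-like influx
    patlak_v: float = 0.3
    patlak_t_start_min: float = 10.0
    noise_sigma: float = 0.05
    n_replicates: int = 200


class RunConfig(_Section):
    """Full pipeline configuration with a single master seed."""

    seed: int = 1
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    adsorption: AdsorptionSection = Field(default_factory=AdsorptionSection)
    imaging: ImagingSection = Field(default_factory=ImagingSection)
    quantification: QuantificationSection = Field(default_factory=QuantificationSection)
    kinetics: KineticsSection = Field(default_factory=KineticsSection)


def load_config(path: Union[str, Path]) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path: Union[str, Path]) -> Path:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    )
    return Path(path)
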