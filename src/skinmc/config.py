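"""Run configuration: strict YAML/JSON schema with unit-annotated defaults.

A minimal config needs only ``variant``; every other section fills in the
named study defaults.  Unknown keys are rejected (strict schema) and every
resolved config can be echoed back out so a run directory documents
exactly what was executed.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .coefficients import CoefficientTable
from .model import SkinModel, SourceSpec, VARIANTS, build_default_skin
from .spectrum import EmissionSpectrum, default_study_spectrum, read_spectrum


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    variant: str = "wavelength_study"
    cell_um: float = 5.0
    lateral_extent_mm: float | None = None
    # source
    wavelength_nm: float | None = None  # monochromatic if set
    spectrum_path: str | None = None  # else default IPL spectrum
    beam_width_mm: float = 30.0
    radiant_exposure_j_cm2: float = 10.0
    photons: int = 1_000_000
    # analysis
    criteria: tuple[float, ...] = (0.01,)
    band_fraction: float | None = 0.25
    # thermal
    pulses_ms: tuple[tuple[float, float], ...] = ((10.0, 20.0),)
    total_energy_j: float = 10.0
    t_end_s: float | None = None
    dt_ms: float = 0.1
    # bookkeeping
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant: unknown value {self.variant!r}; expected one of {VARIANTS}")
        if self.beam_width_mm <= 0:
            raise ConfigError("beam_width_mm: must be > 0 (millimetres)")
        if self.radiant_exposure_j_cm2 <= 0:
            raise ConfigError("radiant_exposure_j_cm2: must be > 0 (J/cm^2)")
        if int(self.photons) < 1:
            raise ConfigError("photons: must be >= 1")
        for f in self.criteria:
            if not 0.0 < f < 1.0:
                raise ConfigError("criteria: fractions must be strictly between 0 and 1")
        if self.dt_ms <= 0:
            raise ConfigError("dt_ms: must be > 0 (milliseconds)")
        if not 0 <= int(self.seed) < 2**31:
            raise ConfigError("seed: must be in [0, 2^31)")

    # ------------------------------------------------------------ builders
    def build_model(self) -> SkinModel:
        lat = None if self.lateral_extent_mm is None else self.lateral_extent_mm * 1000.0
        return build_default_skin(self.variant, cell_um=self.cell_um,
                                  lateral_extent_um=lat)

    def build_table(self) -> CoefficientTable:
        return CoefficientTable()

    def build_spectrum(self) -> EmissionSpectrum:
        if self.wavelength_nm is not None:
            return EmissionSpectrum.monochromatic(self.wavelength_nm)
        if self.spectrum_path is not None:
            return read_spectrum(self.spectrum_path)
        return default_study_spectrum(self.variant)

    def build_source(self) -> SourceSpec:
        return SourceSpec(spectrum=self.build_spectrum(), beam_width_mm=self.beam_width_mm,
                          radiant_exposure_j_cm2=self.radiant_exposure_j_cm2,
                          photon_count=int(self.photons), seed=int(self.seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["criteria"] = list(self.criteria)
        d["pulses_ms"] = [list(p) for p in self.pulses_ms]
        return d


_UNITS = {
    "cell_um": "micrometres", "lateral_extent_mm": "millimetres",
    "wavelength_nm": "nanometres", "beam_width_mm": "millimetres",
    "radiant_exposure_j_cm2": "J/cm^2", "photons": "count",
    "criteria": "fractions of maximum deposition", "band_fraction": "fraction of beam width",
    "pulses_ms": "list of [on_ms, off_ms]", "total_energy_j": "joules",
    "t_end_s": "seconds", "dt_ms": "milliseconds", "seed": "integer",
    "variant": "wavelength_study | beamwidth_study", "spectrum_path": "path",
    "out_dir": "path", "band_fraction_note": "",
}


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    allowed = set(RunConfig.__dataclass_fields__)
    for key in data:
        if key not in allowed:
            hint = ", ".join(f"{k} ({_UNITS.get(k, '')})" for k in sorted(allowed))
            raise ConfigError(f"unknown config key {key!r}; allowed keys: {hint}")
    kwargs = dict(data)
    if "criteria" in kwargs:
        kwargs["criteria"] = tuple(kwargs["criteria"])
    if "pulses_ms" in kwargs:
        kwargs["pulses_ms"] = tuple(tuple(p) for p in kwargs["pulses_ms"])
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    return config_from_dict(data)


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
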