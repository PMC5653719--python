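"""Layered skin geometry, scoring grid and source description.

The tissue is a stack of horizontal layers with the free surface at z = 0
and z increasing downward.  Photons are scored on a uniform 2-D Cartesian
grid over (y, z); the lateral coordinate y is centred on the beam axis and
the third dimension x is translation-invariant (infinite-slot beam) and
never scored.  Cells are half-open boxes [i*d, (i+1)*d) with 0-based
indices; a layer interface at depth d belongs to the deeper layer.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrum import EmissionSpectrum
from .units import UM_PER_MM


@dataclass(frozen=True)
class LayerSpec:
    """One homogeneous tissue layer.

    Thermal constants default to the epidermal values; optical absorption
    and scattering are supplied separately by a coefficient table because
    they are wavelength dependent.
    """

    name: str
    thickness_um: float
    melanin_fraction: float = 0.0
    refractive_index: float = 1.4
    anisotropy_g: float = 0.789
    thermal_conductivity_k: float = 0.5  # W m^-1 K^-1
    density_rho: float = 1200.0  # kg m^-3
    specific_heat_c: float = 3600.0  # J kg^-1 K^-1

    def __post_init__(self) -> None:
        if not self.thickness_um > 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0 um")
        if not 0.0 <= self.melanin_fraction <= 1.0:
            raise ValueError(f"layer {self.name!r}: melanin_fraction must be in [0, 1]")
        if self.refractive_index < 1.0:
            raise ValueError(f"layer {self.name!r}: refractive_index must be >= 1")
        if not -1.0 < self.anisotropy_g < 1.0:
            raise ValueError(f"layer {self.name!r}: anisotropy g must be in (-1, 1)")
        a = self.thermal_diffusivity
        if not (np.isfinite(a) and a > 0):
            raise ValueError(f"layer {self.name!r}: thermal diffusivity must be finite and positive")

    @property
    def thermal_diffusivity(self) -> float:
        """alpha = k / (rho * c) in m^2 s^-1."""
        return self.thermal_conductivity_k / (self.density_rho * self.specific_heat_c)


@dataclass(frozen=True)
class GridSpec:
    """Uniform Cartesian scoring grid over (y, z).

    y spans [-lateral_extent/2, +lateral_extent/2), z spans [0, depth).
    Extents must be positive integer multiples of the cell size.
    """

    cell_um: float = 5.0
    lateral_extent_um: float = 50_000.0
    depth_extent_um: float = 8_000.0

    def __post_init__(self) -> None:
        if not self.cell_um > 0:
            raise ValueError("cell_um must be > 0")
        for name, ext in (("lateral_extent_um", self.lateral_extent_um),
                          ("depth_extent_um", self.depth_extent_um)):
            n = ext / self.cell_um
            if ext <= 0 or abs(n - round(n)) > 1e-9 or round(n) < 1:
                raise ValueError(f"{name} must be a positive integer multiple of cell_um")

    @property
    def n_y(self) -> int:
        return int(round(self.lateral_extent_um / self.cell_um))

    @property
    def n_z(self) -> int:
        return int(round(self.depth_extent_um / self.cell_um))

    @property
    def y_min_um(self) -> float:
        return -self.lateral_extent_um / 2.0

    @property
    def y_centers_um(self) -> np.ndarray:
        return self.y_min_um + (np.arange(self.n_y) + 0.5) * self.cell_um

    @property
    def z_centers_um(self) -> np.ndarray:
        return (np.arange(self.n_z) + 0.5) * self.cell_um


@dataclass(frozen=True)
class SkinModel:
    """Ordered layer stack (surface downward) plus the scoring grid."""

    layers: tuple[LayerSpec, ...]
    grid: GridSpec
    ambient_refractive_index: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("at least one layer required")
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.total_thickness_um < self.grid.depth_extent_um - 1e-9:
            raise ValueError("grid depth_extent_um extends below the bottom layer")
        if self.ambient_refractive_index < 1.0:
            raise ValueError("ambient refractive index must be >= 1")

    @property
    def total_thickness_um(self) -> float:
        return float(sum(l.thickness_um for l in self.layers))

    @property
    def layer_bottoms_um(self) -> np.ndarray:
        """Cumulative depth of each layer's lower interface."""
        return np.cumsum([l.thickness_um for l in self.layers])

    def layer_index(self, z_um: float) -> int:
        """Index of the layer containing depth z; interfaces belong to the deeper layer."""
        if not 0.0 <= z_um < self.grid.depth_extent_um:
            raise ValueError(f"z = {z_um} um outside grid [0, {self.grid.depth_extent_um})")
        idx = int(np.searchsorted(self.layer_bottoms_um, z_um, side="right"))
        return min(idx, len(self.layers) - 1)

    def layer_at(self, z_um: float) -> LayerSpec:
        return self.layers[self.layer_index(z_um)]


@dataclass(frozen=True)
class SourceSpec:
    """Beam geometry, spectral content and photon budget.

    The beam is uniform over [-beam_width/2, +beam_width/2) in y, normally
    incident, translation-invariant in x.  ``spectrum`` may be broadband or
    monochromatic (a single-sample spectrum).
    """

    spectrum: EmissionSpectrum
    beam_width_mm: float
    radiant_exposure_j_cm2: float = 10.0
    photon_count: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.beam_width_mm > 0:
            raise ValueError("beam_width_mm must be > 0")
        if not self.radiant_exposure_j_cm2 > 0:
            raise ValueError("radiant_exposure_j_cm2 must be > 0")
        if int(self.photon_count) < 1:
            raise ValueError("photon_count must be >= 1")
        if not 0 <= int(self.seed) < 2**31:
            raise ValueError("seed must be in [0, 2^31)")

    @property
    def beam_width_um(self) -> float:
        return self.beam_width_mm * UM_PER_MM

    @classmethod
    def monochromatic(cls, wavelength_nm: float, **kwargs) -> "SourceSpec":
        return cls(spectrum=EmissionSpectrum.monochromatic(wavelength_nm), **kwargs)


# Table of per-layer physical constants for the tissue types carried by the
# model: thermal conductivity k [W m^-1 K^-1], density rho [kg m^-3],
# specific heat c [J kg^-1 K^-1], refractive index n, anisotropy g.  The
# hair row is carried as data only; no hair geometry is modelled.
TISSUE_CONSTANTS = {
    "epidermis": dict(k=0.5, rho=1200.0, c=3600.0, n=1.34, g=0.789),
    "dermis": dict(k=0.53, rho=1200.0, c=3800.0, n=1.37, g=0.789),
    "hair": dict(k=0.24, rho=1210.0, c=3500.0, n=1.7, g=0.789),
}

#: Default study set-ups, by name.
VARIANTS = ("wavelength_study", "beamwidth_study")


def build_default_skin(variant: str, *, cell_um: float = 5.0,
                       lateral_extent_um: float | None = None) -> SkinModel:
    """Build one of the two default study models.

    ``wavelength_study``: 80 um epidermis at 5 % melanin over a melanin-free
    dermis (7920 um, giving an 8 mm scoring depth), 50 mm lateral extent for
    the default 30 mm beam.

    ``beamwidth_study``: 80 um epidermis at 4.3 % melanin (skin type 2) over
    a 5560 um dermis, 60 mm lateral extent to accommodate 40 mm beams.
    """
    epi_c = TISSUE_CONSTANTS["epidermis"]
    der_c = TISSUE_CONSTANTS["dermis"]
    if variant == "wavelength_study":
        mel, dermis_um, lat = 0.05, 7920.0, 50_000.0
    elif variant == "beamwidth_study":
        mel, dermis_um, lat = 0.043, 5560.0, 60_000.0
    else:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if lateral_extent_um is not None:
        lat = lateral_extent_um
    epidermis = LayerSpec(
        name="epidermis", thickness_um=80.0, melanin_fraction=mel,
        refractive_index=epi_c["n"], anisotropy_g=epi_c["g"],
        thermal_conductivity_k=epi_c["k"], density_rho=epi_c["rho"],
        specific_heat_c=epi_c["c"])
    dermis = LayerSpec(
        name="dermis", thickness_um=dermis_um, melanin_fraction=0.0,
        refractive_index=der_c["n"], anisotropy_g=der_c["g"],
        thermal_conductivity_k=der_c["k"], density_rho=der_c["rho"],
        specific_heat_c=der_c["c"])
    grid = GridSpec(cell_um=cell_um, lateral_extent_um=lat,
                    depth_extent_um=80.0 + dermis_um)
    return SkinModel(layers=(epidermis, dermis), grid=grid)
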