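"""Deterministic test scenarios built from parameters and a seed only.

Each fixture returns the ready-to-run inputs (model, coefficient table,
source, or pre-built maps) for a scenario with a known analytic structure
or a named study configuration, so every stage of the pipeline is
testable without external data.
"""
from __future__ import annotations

import numpy as np

from .analysis import FluenceMap, SweepResult
from .coefficients import CoefficientTable, ConstantCoefficientTable
from .model import GridSpec, LayerSpec, SkinModel, SourceSpec, build_default_skin
from .spectrum import default_study_spectrum

import pandas as pd


def _slab_model(depth_um: float = 5000.0, lateral_um: float = 10000.0,
                cell_um: float = 10.0, n: float = 1.0, g: float = 0.0) -> SkinModel:
    layer = LayerSpec(name="slab", thickness_um=depth_um, refractive_index=n,
                      anisotropy_g=g)
    grid = GridSpec(cell_um=cell_um, lateral_extent_um=lateral_um,
                    depth_extent_um=depth_um)
    return SkinModel(layers=(layer,), grid=grid)


def beer_lambert(params: dict | None = None, seed: int = 0) -> dict:
    """Pure-absorber slab (mu_s = 0, index-matched): depth law exp(-mu_a z)."""
    p = dict(mua_mm=1.0, depth_um=10000.0, cell_um=10.0, photons=100_000)
    p.update(params or {})
    model = _slab_model(depth_um=p["depth_um"], cell_um=p["cell_um"])
    table = ConstantCoefficientTable(mua_default=p["mua_mm"], mus_default=0.0)
    source = SourceSpec.monochromatic(600.0, beam_width_mm=1.0,
                                      photon_count=p["photons"], seed=seed)
    return {"model": model, "table": table, "source": source, "mua_mm": p["mua_mm"]}


def isotropic(params: dict | None = None, seed: int = 0) -> dict:
    """Index-matched isotropic scatterer (g = 0) for symmetry checks."""
    p = dict(mua_mm=0.5, mus_mm=5.0, photons=50_000)
    p.update(params or {})
    model = _slab_model(g=0.0)
    table = ConstantCoefficientTable(mua_default=p["mua_mm"], mus_default=p["mus_mm"])
    source = SourceSpec.monochromatic(600.0, beam_width_mm=0.5,
                                      photon_count=p["photons"], seed=seed)
    return {"model": model, "table": table, "source": source}


def exp_decay_map(params: dict | None = None, seed: int = 0) -> dict:
    """Analytic map exp(-z/delta), uniform in y; 1% depth = delta*ln(100)."""
    p = dict(delta_mm=0.5, depth_um=5000.0, cell_um=5.0, n_y=11)
    p.update(params or {})
    n_z = int(round(p["depth_um"] / p["cell_um"]))
    z = (np.arange(n_z) + 0.5) * p["cell_um"] / 1000.0  # mm at cell centres
    col = np.exp(-z / p["delta_mm"])
    values = np.repeat(col[:, None], p["n_y"], axis=1)
    values /= values.max()
    fmap = FluenceMap(values=values, cell_um=p["cell_um"],
                      y_min_um=-p["n_y"] * p["cell_um"] / 2.0,
                      mode="per_max_deposition", beam_width_mm=1.0,
                      radiant_exposure_j_cm2=10.0, photons=1)
    return {"map": fmap, "delta_mm": p["delta_mm"],
            "expected_depth_um": p["delta_mm"] * 1000.0 * np.log(100.0)}


def toy_sweep(params: dict | None = None, seed: int = 0) -> dict:
    """Constructed beam-width sweep with a plateau from 10 mm onward."""
    p = dict(widths_mm=(1.0, 5.0, 10.0, 20.0, 40.0),
             depths_mm=(2.0, 4.0, 5.0, 5.05, 5.02))
    p.update(params or {})
    table = pd.DataFrame({"beam_width_mm": p["widths_mm"],
                          "depth_um_0.01": [d * 1000.0 for d in p["depths_mm"]]})
    return {"sweep": SweepResult(axis="beam_width", table=table, criteria=(0.01,))}


def wavelength_study_setup(params: dict | None = None, seed: int = 0) -> dict:
    """Default 5 % melanin / 80 um epidermis wavelength-study configuration."""
    model = build_default_skin("wavelength_study")
    table = CoefficientTable()
    source = SourceSpec.monochromatic(750.0, beam_width_mm=30.0,
                                      photon_count=int((params or {}).get("photons", 1_000_000)),
                                      seed=seed)
    return {"model": model, "table": table, "source": source}


def beamwidth_study_setup(params: dict | None = None, seed: int = 0) -> dict:
    """Skin-type-2 (4.3 % melanin, 5560 um dermis) beam-width configuration."""
    model = build_default_skin("beamwidth_study")
    table = CoefficientTable()
    source = SourceSpec(spectrum=default_study_spectrum("beamwidth_study"), beam_width_mm=30.0,
                        photon_count=int((params or {}).get("photons", 1_000_000)),
                        seed=seed)
    return {"model": model, "table": table, "source": source}


FIXTURES = {
    "beer_lambert": beer_lambert,
    "isotropic": isotropic,
    "exp_decay_map": exp_decay_map,
    "toy_sweep": toy_sweep,
    "wavelength_study_setup": wavelength_study_setup,
    "beamwidth_study_setup": beamwidth_study_setup,
}


def make_fixture(name: str, params: dict | None = None, seed: int = 0) -> dict:
    """Build a named deterministic scenario from its parameters and seed."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return builder(params, seed)
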