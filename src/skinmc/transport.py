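"""Monte Carlo photon random walk through the layered skin model.

Photons launch at the surface with unit weight, travel exponential free
paths, deposit the fraction mu_a/(mu_a + mu_s) of their weight at every
interaction site, deflect by Henyey-Greenstein sampling, undergo
Fresnel/Snell boundary physics at layer interfaces, and terminate when
their weight falls below one hundredth of the launch weight (the residual
is tallied, not deposited).  The hot loop lives in :mod:`skinmc._kernel`;
this module provides the validated public surface plus a readable
single-photon tracer for diagnostics.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .coefficients import CoefficientTable
from .model import SkinModel, SourceSpec
from .units import UM_PER_MM

#: Termination threshold as a fraction of the launch weight.
WEIGHT_THRESHOLD_FRACTION = 0.01
#: Hard cap on interaction + boundary events per photon.
MAX_EVENTS = 100_000


# ---------------------------------------------------------------- samplers

def sample_free_path(mua_mm: float, mus_mm: float, R: float) -> float:
    """Free path -ln(R)/(mu_a + mu_s) in um, for R in (0, 1]."""
    mut = mua_mm + mus_mm
    if mut <= 0:
        raise ValueError("degenerate medium: mu_a + mu_s must be > 0")
    if not 0.0 < R <= 1.0:
        raise ValueError("R must be in (0, 1]")
    return -math.log(R) / mut * UM_PER_MM


def sample_scatter_cos(g: float, R: float) -> float:
    """Henyey-Greenstein deflection cosine by inverse CDF (isotropic at g=0)."""
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must be in (-1, 1)")
    return float(_kernel.hg_cos(g, R))


def sample_azimuth(R: float) -> float:
    """Azimuthal angle phi = 2*pi*R, uniform on [0, 2*pi)."""
    return 2.0 * math.pi * R


def rotate_direction(direction, cos_theta: float, phi: float) -> np.ndarray:
    """Rotate a unit direction vector by (cos_theta, phi)."""
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    return np.array(_kernel.rotate(d[0], d[1], d[2], cos_theta, phi))


def fresnel_reflectance(n1: float, n2: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance; 1.0 beyond the critical angle."""
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    if not 0.0 <= cos_i <= 1.0:
        raise ValueError("cos_i must be in [0, 1]")
    r, _, _ = _kernel.fresnel(n1, n2, cos_i)
    return float(r)


def deposit_weight(W: float, mua_mm: float, mus_mm: float) -> tuple[float, float]:
    """(delta_W, W') with delta_W = W * mu_a / (mu_a + mu_s)."""
    mut = mua_mm + mus_mm
    if mut <= 0:
        raise ValueError("degenerate medium: mu_a + mu_s must be > 0")
    if W <= 0:
        raise ValueError("weight must be > 0")
    dw = W * mua_mm / mut
    return dw, W - dw


def check_termination(W: float, W0: float = 1.0,
                      threshold_fraction: float = WEIGHT_THRESHOLD_FRACTION) -> bool:
    """True iff the photon terminates: W < W0 * threshold (strict)."""
    return W < W0 * threshold_fraction


# ------------------------------------------------------------------ result

@dataclass
class TransportResult:
    """Deposited-weight grid plus escape/residual tallies for one run.

    ``absorbed`` is indexed [z, y] in deposited photon weight per cell;
    escape tallies are split by face.  Energy bookkeeping:
    absorbed_total + escaped_weight + residual_weight = photons_launched.
    """

    absorbed: np.ndarray
    escaped_top: float
    escaped_side: float
    escaped_bottom: float
    residual_weight: float
    photons_launched: int
    seed: int
    cell_um: float
    y_min_um: float
    beam_width_mm: float
    radiant_exposure_j_cm2: float
    capped_photons: int = 0

    @property
    def escaped_weight(self) -> float:
        return self.escaped_top + self.escaped_side + self.escaped_bottom

    @property
    def absorbed_total(self) -> float:
        return float(self.absorbed.sum())

    @property
    def bookkeeping_error(self) -> float:
        """Relative energy-conservation defect of the run."""
        total = self.absorbed_total + self.escaped_weight + self.residual_weight
        return abs(total - self.photons_launched) / self.photons_launched


# ------------------------------------------------------------------- runs

def run_simulation(model: SkinModel, table: CoefficientTable, source: SourceSpec,
                   *, roulette: bool = False, roulette_p: float = 0.1,
                   max_events: int = MAX_EVENTS) -> TransportResult:
    """Launch ``source.photon_count`` photons and score the absorbed grid.

    Bit-identical for identical inputs and seed (single seeded RNG
    stream).  Raises before tracing if the beam does not fit the grid.
    """
    grid = model.grid
    if source.beam_width_um > grid.lateral_extent_um + 1e-9:
        raise ValueError(
            f"beam width {source.beam_width_mm} mm exceeds grid lateral extent "
            f"{grid.lateral_extent_um / UM_PER_MM} mm")
    mua, mus = table.optical_arrays(model, source.spectrum)
    if np.any(mua < 0) or np.any(mus < 0):
        raise ValueError("negative optical coefficients")
    if np.any(mua + mus <= 0):
        raise ValueError("degenerate medium: mu_a + mu_s must be > 0 everywhere")
    layer_bot = np.ascontiguousarray(model.layer_bottoms_um, dtype=float)
    layer_n = np.array([l.refractive_index for l in model.layers], dtype=float)
    layer_g = np.array([l.anisotropy_g for l in model.layers], dtype=float)
    absorbed, esc_top, esc_side, esc_bottom, residual, n_capped = _kernel.run_kernel(
        int(source.seed), int(source.photon_count), float(grid.cell_um),
        grid.n_y, grid.n_z, float(grid.y_min_um), layer_bot, layer_n, layer_g,
        mua, mus, float(model.ambient_refractive_index),
        source.spectrum.cdf(), source.beam_width_um / 2.0,
        WEIGHT_THRESHOLD_FRACTION, roulette, roulette_p, max_events)
    if n_capped:
        warnings.warn(f"{n_capped} photons hit the {max_events}-event cap; "
                      "their weight was tallied as residual")
    return TransportResult(
        absorbed=absorbed, escaped_top=esc_top, escaped_side=esc_side,
        escaped_bottom=esc_bottom, residual_weight=residual,
        photons_launched=int(source.photon_count), seed=int(source.seed),
        cell_um=grid.cell_um, y_min_um=grid.y_min_um,
        beam_width_mm=source.beam_width_mm,
        radiant_exposure_j_cm2=source.radiant_exposure_j_cm2,
        capped_photons=int(n_capped))


def trace_photon(model: SkinModel, table: CoefficientTable, source: SourceSpec,
                 rng: np.random.Generator):
    """Trace a single photon; returns (events, fate).

    ``events`` is a list of (y_um, z_um, delta_W) deposition sites; ``fate``
    is a dict with the terminal disposition.  This is a readable reference
    walk sharing the compiled physics primitives; bulk runs should use
    :func:`run_simulation`.
    """
    grid = model.grid
    spectrum = source.spectrum
    s = int(np.searchsorted(spectrum.cdf(), rng.random()))
    s = min(s, spectrum.wavelengths_nm.size - 1)
    lam = float(spectrum.wavelengths_nm[s])
    mua_l = np.array([float(np.asarray(table.mua(l, lam))) for l in model.layers])
    mus_l = np.array([float(np.asarray(table.mus(l, lam))) for l in model.layers])
    layer_bot = model.layer_bottoms_um
    layer_n = [l.refractive_index for l in model.layers]
    z_max = grid.depth_extent_um
    y_max = grid.y_min_um + grid.lateral_extent_um

    half = source.beam_width_um / 2.0
    y, z = -half + 2.0 * half * rng.random(), 0.0
    ux, uy, uz = 0.0, 0.0, 1.0
    layer = 0
    rsp = fresnel_reflectance(model.ambient_refractive_index, layer_n[0], 1.0)
    w = 1.0 - rsp
    events: list[tuple[float, float, float]] = []
    fate = {"wavelength_nm": lam, "specular": rsp, "escaped": 0.0, "residual": 0.0,
            "deposited": 0.0, "outcome": "capped"}
    for _ in range(MAX_EVENTS):
        step = sample_free_path(mua_l[layer], mus_l[layer], 1.0 - rng.random())
        if uz > 0.0:
            zb = min(layer_bot[layer], z_max)
            d = (zb - z) / uz
        elif uz < 0.0:
            zb = layer_bot[layer - 1] if layer > 0 else 0.0
            d = (zb - z) / uz
        else:
            zb, d = z, math.inf
        if step < d:
            y += uy * step
            z += uz * step
            if y < grid.y_min_um or y >= y_max:
                fate["escaped"], fate["outcome"] = w, "escaped_side"
                break
            dw, w = deposit_weight(w, mua_l[layer], mus_l[layer])
            events.append((y, z, dw))
            fate["deposited"] += dw
            if check_termination(w):
                fate["residual"], fate["outcome"] = w, "terminated"
                break
            ct = sample_scatter_cos(model.layers[layer].anisotropy_g, rng.random())
            phi = sample_azimuth(rng.random())
            ux, uy, uz = _kernel.rotate(ux, uy, uz, ct, phi)
        else:
            y += uy * d
            z = zb
            if y < grid.y_min_um or y >= y_max:
                fate["escaped"], fate["outcome"] = w, "escaped_side"
                break
            if uz < 0.0 and layer == 0:
                refl, _, _ = _kernel.fresnel(layer_n[0], model.ambient_refractive_index, -uz)
                if rng.random() < refl:
                    uz = -uz
                else:
                    fate["escaped"], fate["outcome"] = w, "escaped_top"
                    break
            elif uz > 0.0 and zb >= z_max:
                fate["escaped"], fate["outcome"] = w, "escaped_bottom"
                break
            else:
                other = layer + 1 if uz > 0.0 else layer - 1
                refl, cos_t, ratio = _kernel.fresnel(layer_n[layer], layer_n[other], abs(uz))
                if rng.random() < refl:
                    uz = -uz
                else:
                    ux, uy = ux * ratio, uy * ratio
                    uz = cos_t if uz > 0.0 else -cos_t
                    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux, uy, uz = ux / norm, uy / norm, uz / norm
                    layer = other
    else:
        fate["residual"] = w
    return events, fate
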