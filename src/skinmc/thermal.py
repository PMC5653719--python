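"""Transient 2-D heat diffusion driven by the Monte Carlo energy source.

Solves rho*c dT/dt = d/dy(k dT/dy) + d/dz(k dT/dz) + H on the scoring
grid with the alternating-direction-implicit (Peaceman-Rachford) scheme:
each step is an implicit tridiagonal solve in y followed by one in z,
unconditionally stable for the homogeneous problem.  Material properties
vary with depth only (layered medium); interface conductivities use the
harmonic mean, which keeps the discretization conservative, so with
insulated boundaries and no source the total heat content sum(rho*c*T) is
preserved to solver round-off.

The volumetric source H comes from the absorbed-energy matrix of a
transport run: energy per cell divided by cell volume and by the pulse
on-time, toggled by the pulse train.  The 2-D problem is interpreted per
unit slab thickness of 1 cm in x.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .analysis import FluenceMap
from .model import SkinModel
from .units import M_PER_UM, UM_PER_CM

#: Slab thickness in x used to convert the 2-D grid to volumes, in um.
SLAB_THICKNESS_UM = UM_PER_CM


@dataclass(frozen=True)
class ThermalProps:
    """Per-row (depth-wise) thermal constants on the scoring grid."""

    k: np.ndarray  # W m^-1 K^-1, shape (n_z,)
    rho_c: np.ndarray  # J m^-3 K^-1, shape (n_z,)
    cell_m: float

    def __post_init__(self) -> None:
        if np.any(self.k <= 0) or np.any(self.rho_c <= 0):
            raise ValueError("thermal constants must be positive")

    @classmethod
    def from_model(cls, model: SkinModel) -> "ThermalProps":
        z = model.grid.z_centers_um
        layers = [model.layer_at(zz) for zz in z]
        k = np.array([l.thermal_conductivity_k for l in layers])
        rho_c = np.array([l.density_rho * l.specific_heat_c for l in layers])
        return cls(k=k, rho_c=rho_c, cell_m=model.grid.cell_um * M_PER_UM)

    @classmethod
    def uniform(cls, k: float, rho: float, c: float, n_z: int, cell_m: float) -> "ThermalProps":
        return cls(k=np.full(n_z, float(k)), rho_c=np.full(n_z, float(rho * c)),
                   cell_m=cell_m)


@dataclass(frozen=True)
class PulseTrain:
    """IPL-style pulse sequence; total energy split equally across on-phases."""

    pulses: tuple[tuple[float, float], ...]  # (on_ms, off_ms) pairs
    total_energy_j: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pulses", tuple((float(a), float(b)) for a, b in self.pulses))
        if not self.pulses:
            raise ValueError("at least one pulse required")
        for on, off in self.pulses:
            if on <= 0 or off < 0:
                raise ValueError("pulse on-durations must be > 0 and off-durations >= 0")

    @property
    def duration_s(self) -> float:
        return sum(on + off for on, off in self.pulses) * 1e-3

    def power_fraction(self, t_s: float) -> float:
        """Fraction of the total energy delivered per second at time t.

        Equals 1/(n_pulses * on_duration) during the k-th on-phase and 0
        during off-phases and after the train ends; integrates to 1 over
        the train.
        """
        t_ms = t_s * 1e3
        share = 1.0 / len(self.pulses)
        for on, off in self.pulses:
            if t_ms < on:
                return share / (on * 1e-3)
            t_ms -= on + off
            if t_ms < 0:
                return 0.0
        return 0.0


@dataclass
class ThermalField:
    temperature: np.ndarray  # degC, shape (n_z, n_y)
    time_s: float
    source: np.ndarray  # J m^-3 for the full train energy; scaled at use


def build_heat_source(fluence: FluenceMap, pulse: PulseTrain) -> np.ndarray:
    """Volumetric energy density [J m^-3] deposited by the whole train.

    ``fluence`` must be normalized per_incident, so its values are
    deposition per unit incident weight per illuminated cell column; the
    pulse train's ``total_energy_j`` is the incident energy of the whole
    train, giving ``total_energy_j * cell / beam_width`` joules incident
    per column.  Multiplying the returned matrix by
    ``pulse.power_fraction(t)`` [1/s] yields the instantaneous H in
    W m^-3, zero during off-phases.
    """
    if fluence.mode != "per_incident":
        raise ValueError("fluence map must be normalized per_incident")
    e_cell_j = pulse.total_energy_j * fluence.cell_um / (fluence.beam_width_mm * 1000.0)
    cell_volume_m3 = (fluence.cell_um * M_PER_UM) ** 2 * (SLAB_THICKNESS_UM * M_PER_UM)
    return fluence.values * e_cell_j / cell_volume_m3


def _solve_tridiag(rhs: np.ndarray, r_minus: np.ndarray, r_plus: np.ndarray) -> np.ndarray:
    """Solve (I - flux-form diffusion) x = rhs along axis 0.

    Row i couples as -r_minus[i] x[i-1] + (1 + r_minus[i] + r_plus[i]) x[i]
    - r_plus[i] x[i+1]; boundary faces carry r = 0 (insulated) unless the
    caller folded a Dirichlet ghost value into rhs and r.
    """
    n = rhs.shape[0]
    ab = np.zeros((3, n))
    ab[0, 1:] = -r_plus[:-1]
    ab[1, :] = 1.0 + r_minus + r_plus
    ab[2, :-1] = -r_minus[1:]
    return solve_banded((1, 1), ab, rhs)


def _face_coeffs(k_row: np.ndarray) -> np.ndarray:
    """Harmonic-mean conductivities at the n+1 faces; zero at the ends."""
    n = k_row.shape[0]
    faces = np.zeros(n + 1)
    faces[1:-1] = 2.0 * k_row[:-1] * k_row[1:] / (k_row[:-1] + k_row[1:])
    return faces


def adi_step(field: ThermalField, props: ThermalProps, dt_s: float,
             source_scale: float = 0.0, bottom_fixed: float | None = None,
             ) -> ThermalField:
    """Advance one Peaceman-Rachford ADI step of length dt.

    ``source_scale`` multiplies ``field.source`` (pass the pulse-train
    power fraction in 1/s; 0 during off-phases).  ``bottom_fixed``
    switches the bottom face from insulated to a fixed temperature.
    """
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    T = field.temperature
    n_z, n_y = T.shape
    h2 = props.cell_m ** 2
    dt2 = dt_s / 2.0

    rz_face = dt2 * _face_coeffs(props.k) / h2  # (n_z + 1,)
    rz_minus = rz_face[:-1] / props.rho_c
    rz_plus = rz_face[1:] / props.rho_c
    rb = 0.0
    if bottom_fixed is not None:
        # Dirichlet ghost at the bottom face, half a cell away.
        rb = 2.0 * dt2 * props.k[-1] / (h2 * props.rho_c[-1])
    ry = dt2 * props.k / (props.rho_c * h2)  # (n_z,), k uniform within a row
    q = dt2 * source_scale * field.source / props.rho_c[:, None]

    def apply_z(U: np.ndarray) -> np.ndarray:
        out = np.zeros_like(U)
        out[1:] += rz_minus[1:, None] * (U[:-1] - U[1:])
        out[:-1] += rz_plus[:-1, None] * (U[1:] - U[:-1])
        if bottom_fixed is not None:
            out[-1] += rb * (bottom_fixed - U[-1])
        return out

    def apply_y(U: np.ndarray) -> np.ndarray:
        out = np.zeros_like(U)
        out[:, 1:] += ry[:, None] * (U[:, :-1] - U[:, 1:])
        out[:, :-1] += ry[:, None] * (U[:, 1:] - U[:, :-1])
        return out

    # half step 1: implicit in y, explicit in z
    rhs = T + apply_z(T) + q
    T_star = np.empty_like(T)
    rm = np.empty(n_y)
    rp = np.empty(n_y)
    for iz in range(n_z):
        rm[:] = ry[iz]
        rp[:] = ry[iz]
        rm[0] = 0.0
        rp[-1] = 0.0
        T_star[iz] = _solve_tridiag(rhs[iz], rm, rp)

    # half step 2: implicit in z, explicit in y
    rhs2 = T_star + apply_y(T_star) + q
    rmz = rz_minus.copy()
    rpz = rz_plus.copy()
    if bottom_fixed is not None:
        rpz = rpz.copy()
        rpz[-1] = rb
        rhs2[-1] += rb * bottom_fixed
    T_new = _solve_tridiag(rhs2, rmz, rpz)
    if not np.all(np.isfinite(T_new)):
        raise ArithmeticError("ADI solve produced non-finite temperatures")
    return ThermalField(temperature=T_new, time_s=field.time_s + dt_s,
                        source=field.source)


@dataclass
class HeatingResult:
    fields: list[ThermalField]
    peak_trace: np.ndarray  # (n_steps, 2): time_s, max temperature


def run_heating(fluence: FluenceMap, props: ThermalProps, pulse: PulseTrain,
                T0: float = 37.0, t_end_s: float | None = None,
                dt_s: float = 1e-4, bottom_fixed: float | None = None,
                sample_every: int = 50) -> HeatingResult:
    """Time-step the ADI solver with the source toggled by the pulse train.

    Returns sampled fields plus the peak-temperature trace.  The default
    initial condition is a uniform 37 degC body temperature.
    """
    for on, off in pulse.pulses:
        if dt_s > on * 1e-3 or (off > 0 and dt_s > off * 1e-3):
            raise ValueError("dt must not exceed any pulse on/off phase")
    if t_end_s is None:
        t_end_s = pulse.duration_s * 2.0
    H_unit = build_heat_source(fluence, pulse)
    n_steps = int(round(t_end_s / dt_s))
    if n_steps < 1:
        raise ValueError("t_end shorter than one step")
    field = ThermalField(temperature=np.full_like(H_unit, float(T0)),
                         time_s=0.0, source=H_unit)
    fields = [field]
    trace = np.empty((n_steps, 2))
    for i in range(n_steps):
        scale = pulse.power_fraction(field.time_s + dt_s / 2.0)
        field = adi_step(field, props, dt_s, source_scale=scale,
                         bottom_fixed=bottom_fixed)
        trace[i, 0] = field.time_s
        trace[i, 1] = field.temperature.max()
        if (i + 1) % sample_every == 0 or i == n_steps - 1:
            fields.append(field)
    return HeatingResult(fields=fields, peak_trace=trace)
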