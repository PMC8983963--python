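"""Two-zone (near-field/far-field) well-mixed box model with constant source.

A room of volume ``V`` is ventilated with clean supply air ``Q`` (m3/min).
A small near-field zone of volume ``V_N`` encloses the worker and the
source (generation ``G`` mg/min) and exchanges air with the remaining
far field (``V_F = V - V_N``) at the inter-zone flow ``beta`` (m3/min),
set by random air speed ``s`` across the free-slip boundary area ``A_FS``:
``beta = s * A_FS / 2``.  Mass balances:

    V_N dC_N/dt = G + beta (C_F - C_N)
    V_F dC_F/dt = beta (C_N - C_F) - Q C_F

Assumptions: each zone instantaneously well mixed, supply and initial air
clean unless stated, exhaust the only removal (no surface losses or
reactions).  At steady state C_F = G/Q and C_N = G/Q + G/beta,
independent of the zone volumes.

The linear system is solved exactly through its two (real, negative)
eigenvalues; the same decomposition yields closed-form running time
integrals of both concentrations, which the scenario engine uses for exact
time-weighted averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import MOLAR_MASS_G_MOL, MOLAR_VOLUME_L_MOL
from .errors import InvalidParameterError

__all__ = [
    "TwoZoneSystem",
    "NearFieldGeometry",
    "ZoneConcentrations",
    "interzone_flow",
    "steady_state",
    "transient_solution",
    "transient_concentrations",
    "integrated_concentrations",
    "mass_to_ppb",
    "ppb_to_mass",
    "generation_rate",
    "emitted_mass",
    "twa",
]


@dataclass(frozen=True)
class TwoZoneSystem:
    """Room geometry, ventilation, inter-zone flow and source strength."""

    room_volume: float        # m3 (total, near field included)
    nf_volume: float          # m3
    supply_air: float         # m3/min
    interzone_flow: float     # m3/min (beta)
    generation: float         # mg/min
    analyte: str = "diacetyl"

    def __post_init__(self) -> None:
        if not (self.room_volume > self.nf_volume > 0):
            raise InvalidParameterError("require room_volume > nf_volume > 0")
        if self.supply_air <= 0 or self.interzone_flow <= 0:
            raise InvalidParameterError("supply air and inter-zone flow must be > 0")
        if self.generation < 0:
            raise InvalidParameterError("generation rate must be >= 0")

    @property
    def far_volume(self) -> float:
        return self.room_volume - self.nf_volume

    @property
    def molar_mass(self) -> float:
        try:
            return MOLAR_MASS_G_MOL[self.analyte]
        except KeyError:
            raise InvalidParameterError(f"unknown analyte {self.analyte!r}") from None

    def with_generation(self, g: float) -> "TwoZoneSystem":
        return replace(self, generation=g)


@dataclass(frozen=True)
class NearFieldGeometry:
    """Hemispherical near-field zone around the worker/source.

    The free-slip area is the curved boundary 2*pi*r^2 through which air
    exchanges; the default radius of 0.75 m gives A_FS ~ 3.53 m2 and a
    near-field volume of ~0.884 m3.
    """

    radius: float = 0.75            # m
    random_air_speed: float = 6.0   # m/min
    shape: str = "hemisphere"

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.random_air_speed <= 0:
            raise InvalidParameterError("radius and air speed must be > 0")
        if self.shape != "hemisphere":
            raise InvalidParameterError("only hemispherical near fields are supported")

    @property
    def free_slip_area(self) -> float:
        return 2.0 * math.pi * self.radius**2

    @property
    def volume(self) -> float:
        return (2.0 / 3.0) * math.pi * self.radius**3

    @property
    def beta(self) -> float:
        return interzone_flow(self.random_air_speed, self.free_slip_area)


@dataclass(frozen=True)
class ZoneConcentrations:
    """Near- and far-field concentrations (mg/m3) at one time (min)."""

    time: float
    c_nf: float
    c_ff: float


def interzone_flow(random_air_speed: float, free_slip_area: float) -> float:
    """beta = s * A_FS / 2 (half the boundary area carries air inward)."""
    if random_air_speed <= 0 or free_slip_area <= 0:
        raise InvalidParameterError("air speed and area must be > 0")
    return 0.5 * random_air_speed * free_slip_area


def steady_state(system: TwoZoneSystem) -> ZoneConcentrations:
    """t -> infinity limit: C_F = G/Q, C_N = G/Q + G/beta (volume-free)."""
    g, q, b = system.generation, system.supply_air, system.interzone_flow
    return ZoneConcentrations(time=math.inf, c_nf=g / q + g / b, c_ff=g / q)


def _solution_terms(system: TwoZoneSystem, c_n0: float, c_f0: float):
    """Decompose the affine ODE solution.

    Returns ``(x_ss, mode)`` where for distinct eigenvalues
    ``mode = ("distinct", lam (2,), W (2,2))`` with
    ``x(t) = x_ss + W @ exp(lam t)`` (columns of W are coefficient-scaled
    eigenvectors), and for a (measure-zero) repeated eigenvalue
    ``mode = ("repeated", lam, a (2,), b (2,))`` with
    ``x(t) = x_ss + exp(lam t) (a + b t)``.
    """
    vn, vf = system.nf_volume, system.far_volume
    b, q, g = system.interzone_flow, system.supply_air, system.generation
    A = np.array([[-b / vn, b / vn], [b / vf, -(b + q) / vf]])
    x_ss = np.array([g / q + g / b, g / q])
    x0 = np.array([c_n0, c_f0], dtype=float)
    dev = x0 - x_ss
    lam, V = np.linalg.eig(A)
    lam = lam.real
    V = V.real
    if abs(lam[0] - lam[1]) > 1e-9 * max(abs(lam).max(), 1e-30):
        coeff = np.linalg.solve(V, dev)
        W = V * coeff  # scale columns
        return x_ss, ("distinct", lam, W)
    # Repeated eigenvalue: exp(At) = exp(lam t) (I + t (A - lam I)).
    lam0 = float(lam.mean())
    b_vec = (A - lam0 * np.eye(2)) @ dev
    return x_ss, ("repeated", lam0, dev, b_vec)


def transient_concentrations(
    system: TwoZoneSystem,
    times,
    c_n0: float = 0.0,
    c_f0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact concentrations (mg/m3) at an array of times (min).

    Vectorized over ``times``; returns ``(c_nf, c_ff)`` arrays.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise InvalidParameterError("time must be >= 0")
    x_ss, mode = _solution_terms(system, c_n0, c_f0)
    if mode[0] == "distinct":
        _, lam, W = mode
        ex = np.exp(np.outer(t, lam))          # (nt, 2)
        x = x_ss[None, :] + ex @ W.T
    else:
        _, lam0, a_vec, b_vec = mode
        ex = np.exp(lam0 * t)[:, None]
        x = x_ss[None, :] + ex * (a_vec[None, :] + np.outer(t, b_vec))
    # Guard tiny negative round-off near zero concentrations.
    x = np.where((x < 0) & (x > -1e-12), 0.0, x)
    return x[:, 0], x[:, 1]


def integrated_concentrations(
    system: TwoZoneSystem,
    times,
    c_n0: float = 0.0,
    c_f0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact running integrals ``int_0^t C dt`` (mg min/m3) for both zones.

    Same eigen-decomposition as :func:`transient_concentrations`; the
    integral of each exponential mode is closed-form, so time-weighted
    averages computed from these are exact rather than quadrature-limited.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise InvalidParameterError("time must be >= 0")
    x_ss, mode = _solution_terms(system, c_n0, c_f0)
    if mode[0] == "distinct":
        _, lam, W = mode
        em1 = np.expm1(np.outer(t, lam)) / lam[None, :]   # (e^{lam t}-1)/lam
        x = x_ss[None, :] * t[:, None] + em1 @ W.T
    else:
        _, lam0, a_vec, b_vec = mode
        el = np.exp(lam0 * t)
        i0 = (np.expm1(lam0 * t) / lam0)[:, None]                   # int e^{lt}
        i1 = ((t * el - np.expm1(lam0 * t) / lam0) / lam0)[:, None]  # int t e^{lt}
        x = x_ss[None, :] * t[:, None] + i0 * a_vec[None, :] + i1 * b_vec[None, :]
    return x[:, 0], x[:, 1]


def transient_solution(
    system: TwoZoneSystem,
    initial: ZoneConcentrations | None,
    t: float,
) -> ZoneConcentrations:
    """Exact solution at a single time ``t`` (min) from an initial state."""
    c_n0 = initial.c_nf if initial is not None else 0.0
    c_f0 = initial.c_ff if initial is not None else 0.0
    cn, cf = transient_concentrations(system, [t], c_n0, c_f0)
    return ZoneConcentrations(time=float(t), c_nf=float(cn[0]), c_ff=float(cf[0]))


def mass_to_ppb(c_mg_m3, molar_mass_g_mol: float,
                molar_volume_l_mol: float = MOLAR_VOLUME_L_MOL):
    """mg/m3 -> ppb at 25 degC, 1 atm: ppb = C * 1000 * Vm / M."""
    if molar_mass_g_mol <= 0:
        raise InvalidParameterError("molar mass must be > 0")
    return c_mg_m3 * 1000.0 * molar_volume_l_mol / molar_mass_g_mol


def ppb_to_mass(c_ppb, molar_mass_g_mol: float,
                molar_volume_l_mol: float = MOLAR_VOLUME_L_MOL):
    """Inverse of :func:`mass_to_ppb`."""
    if molar_mass_g_mol <= 0:
        raise InvalidParameterError("molar mass must be > 0")
    return c_ppb * molar_mass_g_mol / (1000.0 * molar_volume_l_mol)


def generation_rate(ser_mg_kg_hr: float, coffee_mass_kg: float) -> float:
    """G (mg/min) from a specific emission rate and the coffee mass handled."""
    if ser_mg_kg_hr < 0 or coffee_mass_kg < 0:
        raise InvalidParameterError("SER and mass must be >= 0")
    return ser_mg_kg_hr * coffee_mass_kg / 60.0


def emitted_mass(g_mg_min: float, duration_min: float) -> float:
    """Mass emitted (mg) by a constant source over a task duration."""
    if g_mg_min < 0 or duration_min < 0:
        raise InvalidParameterError("generation and duration must be >= 0")
    return g_mg_min * duration_min


def twa(segments) -> float:
    """Time-weighted average of (concentration, duration) segments."""
    segs = list(segments)
    if not segs:
        raise InvalidParameterError("TWA of an empty segment list is undefined")
    total = sum(d for _, d in segs)
    if total <= 0:
        raise InvalidParameterError("total duration must be > 0")
    return sum(c * d for c, d in segs) / total
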