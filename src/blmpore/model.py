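"""Closed-form pore biophysics for bilayer lipid membrane (BLM) recordings.

A conductive pore across a planar lipid bilayer is modelled as an
equivalent cylinder of radius ``r`` spanning the membrane thickness ``h``
and filled with electrolyte of the bulk specific conductivity ``g``.  Its
conductance is then ``G = pi * g * r**2 / h``, which inverts to

    r = sqrt(G * h / (pi * g))

With the defaults used throughout this package (``h`` = 5 nm, ``g`` =
1.04 S/m for 0.1 M KCl at room temperature) a 110 pS level corresponds to
a 0.41 nm pore and a 942 pS level to a 1.20 nm pore.

Metastable pore states are linked to their mean dwell times through a
Kramers-type attempt-rate relation

    tau_i = 1 / (nu * V_i) * exp((E_max - E_i) / kT)

where ``nu`` is the attempt rate density of lipid thermal fluctuations
(literature estimates span 5e32 to 2e42 s^-1 m^-3), ``V_i ~ 2*pi*r_i**2*h``
is the membrane volume whose fluctuations can drive a transition out of
state ``i``, ``E_i`` is the state energy and ``E_max`` the barrier
separating the metastable states.  Energies are carried in units of kT at
the measurement temperature; ratios of dwell times therefore give energy
differences directly and an absolute dwell time gives the barrier height
up to the (large) uncertainty in ``nu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MembraneContext",
    "PoreState",
    "KineticsContext",
    "DEFAULT_MEMBRANE",
    "NU_LITERATURE_RANGE",
    "pore_radius",
    "pore_conductance",
    "fluctuation_volume",
    "radius_uncertainty",
    "energy_difference",
    "barrier_height",
    "barrier_interval",
    "dwell_from_energy",
    "volume_to_concentration",
    "kT_to_joules",
]

_PS = 1e-12  # pS -> S
_NM = 1e-9   # nm -> m

#: Literature span of the lipid attempt rate density, s^-1 m^-3.
NU_LITERATURE_RANGE: tuple[float, float] = (5e32, 2e42)

_K_BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class MembraneContext:
    """Physical constants of the membrane/recording configuration.

    Parameters
    ----------
    thickness_nm
        Hydrophobic thickness ``h`` of the bilayer, nm.
    conductivity_S_per_m
        Specific conductivity ``g`` of the bathing electrolyte, S/m
        (1.04 S/m for 0.1 M KCl at ~21 degC).
    holding_voltage_mV
        Constant transmembrane voltage applied during recording, mV.
    temperature_K
        Bath temperature; defines the kT energy unit.
    """

    thickness_nm: float = 5.0
    conductivity_S_per_m: float = 1.04
    holding_voltage_mV: float = 25.0
    temperature_K: float = 294.15

    def __post_init__(self) -> None:
        for name in (
            "thickness_nm",
            "conductivity_S_per_m",
            "holding_voltage_mV",
            "temperature_K",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"MembraneContext.{name} must be strictly positive")


DEFAULT_MEMBRANE = MembraneContext()


@dataclass(frozen=True)
class KineticsContext:
    """Attempt-rate density and barrier used for dwell-time energetics."""

    attempt_rate_density_nu: float = NU_LITERATURE_RANGE[0]
    barrier_energy_Emax_kT: float = 18.0

    def __post_init__(self) -> None:
        if not self.attempt_rate_density_nu > 0:
            raise ValueError("attempt_rate_density_nu must be strictly positive")


def pore_radius(g_pore_pS, ctx: MembraneContext = DEFAULT_MEMBRANE):
    """Equivalent cylindrical pore radius (nm) from pore conductance (pS).

    ``r = sqrt(G*h / (pi*g))``; strictly increasing in G.  Accepts scalars
    or arrays.  The conductance should be the pore's own contribution,
    i.e. level conductance minus the intact-membrane baseline.
    """
    g_pore = np.asarray(g_pore_pS, dtype=float)
    if np.any(g_pore < 0):
        raise ValueError("pore conductance must be non-negative")
    r_m = np.sqrt(
        g_pore * _PS * (ctx.thickness_nm * _NM) / (math.pi * ctx.conductivity_S_per_m)
    )
    r_nm = r_m / _NM
    return float(r_nm) if np.isscalar(g_pore_pS) else r_nm


def pore_conductance(r_nm, ctx: MembraneContext = DEFAULT_MEMBRANE):
    """Pore conductance (pS) of an equivalent cylinder of radius ``r_nm`` nm.

    Exact algebraic inverse of :func:`pore_radius`.
    """
    r = np.asarray(r_nm, dtype=float)
    if np.any(r < 0):
        raise ValueError("pore radius must be non-negative")
    g_S = math.pi * ctx.conductivity_S_per_m * (r * _NM) ** 2 / (ctx.thickness_nm * _NM)
    g_pS = g_S / _PS
    return float(g_pS) if np.isscalar(r_nm) else g_pS


def fluctuation_volume(r_nm, ctx: MembraneContext = DEFAULT_MEMBRANE):
    """Membrane volume (m^3) immediately connected with a pore of radius r.

    ``V = 2*pi*r**2*h`` — the lipid volume whose thermal fluctuations can
    drive the pore between metastable states.
    """
    r = np.asarray(r_nm, dtype=float)
    if np.any(r < 0):
        raise ValueError("pore radius must be non-negative")
    v = 2.0 * math.pi * (r * _NM) ** 2 * (ctx.thickness_nm * _NM)
    return float(v) if np.isscalar(r_nm) else v


def radius_uncertainty(
    g_pore_pS: float, sd_pS: float, ctx: MembraneContext = DEFAULT_MEMBRANE
) -> float:
    """First-order propagated radius uncertainty, nm.

    Since ``r ~ sqrt(G)``, ``delta_r = (r/2) * (delta_G / G)``.
    """
    if g_pore_pS <= 0:
        raise ValueError("pore conductance must be strictly positive")
    if sd_pS < 0:
        raise ValueError("conductance SD must be non-negative")
    return pore_radius(g_pore_pS, ctx) * 0.5 * sd_pS / g_pore_pS


@dataclass(frozen=True)
class PoreState:
    """A metastable pore state: geometry plus relative energy.

    ``energy_kT`` is relative to an arbitrary reference state (only energy
    differences are observable).  ``radius_nm`` and ``conductance_pS`` are
    kept mutually consistent under the cylinder model; construct with
    :meth:`from_radius` or :meth:`from_conductance`.
    """

    state_id: str
    radius_nm: float
    conductance_pS: float
    energy_kT: float = 0.0
    fluctuation_volume_m3: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.radius_nm < 0:
            raise ValueError("radius must be non-negative")

    @classmethod
    def from_radius(
        cls,
        state_id: str,
        radius_nm: float,
        energy_kT: float = 0.0,
        ctx: MembraneContext = DEFAULT_MEMBRANE,
    ) -> "PoreState":
        return cls(
            state_id=state_id,
            radius_nm=radius_nm,
            conductance_pS=pore_conductance(radius_nm, ctx),
            energy_kT=energy_kT,
            fluctuation_volume_m3=fluctuation_volume(radius_nm, ctx),
        )

    @classmethod
    def from_conductance(
        cls,
        state_id: str,
        conductance_pS: float,
        energy_kT: float = 0.0,
        ctx: MembraneContext = DEFAULT_MEMBRANE,
    ) -> "PoreState":
        r = pore_radius(conductance_pS, ctx)
        return cls(
            state_id=state_id,
            radius_nm=r,
            conductance_pS=float(conductance_pS),
            energy_kT=energy_kT,
            fluctuation_volume_m3=fluctuation_volume(r, ctx),
        )

    @classmethod
    def closed(cls, state_id: str = "closed", energy_kT: float = 0.0) -> "PoreState":
        return cls(state_id=state_id, radius_nm=0.0, conductance_pS=0.0,
                   energy_kT=energy_kT, fluctuation_volume_m3=0.0)


def energy_difference(tau_a_s, r_a_nm, tau_b_s, r_b_nm):
    """Energy of state b minus state a (kT) from dwell times and radii.

    ``E_b - E_a = ln(tau_a * r_a**2 / (tau_b * r_b**2))`` — the state with
    the longer volume-weighted dwell time is lower in energy.  Antisymmetric
    under swapping the two states.
    """
    for v, name in ((tau_a_s, "tau_a"), (r_a_nm, "r_a"), (tau_b_s, "tau_b"), (r_b_nm, "r_b")):
        if not np.all(np.asarray(v) > 0):
            raise ValueError(f"{name} must be strictly positive")
    return float(np.log((tau_a_s * r_a_nm**2) / (tau_b_s * r_b_nm**2)))


def barrier_height(tau_s, nu, volume_m3):
    """Barrier above a metastable state, ``E_max - E_i = ln(tau*nu*V)`` in kT.

    ``nu`` is the attempt rate density (s^-1 m^-3) and ``V`` the
    fluctuation volume of the state (m^3).
    """
    arg = tau_s * nu * volume_m3
    if not np.all(np.asarray(arg) > 0):
        raise ValueError("tau * nu * V must be strictly positive")
    return float(np.log(arg)) if np.isscalar(arg) else np.log(arg)


def barrier_interval(
    tau_s: float,
    volume_m3: float,
    nu_range: tuple[float, float] = NU_LITERATURE_RANGE,
) -> tuple[float, float]:
    """Barrier height (kT) evaluated at both ends of the attempt-rate range.

    The attempt rate density is known only to about ten orders of
    magnitude, so a single dwell time yields a barrier interval rather than
    a point estimate.
    """
    lo, hi = sorted(nu_range)
    return barrier_height(tau_s, lo, volume_m3), barrier_height(tau_s, hi, volume_m3)


def dwell_from_energy(barrier_kT, nu, volume_m3):
    """Mean dwell time (s) below a barrier: ``tau = exp(barrier)/(nu*V)``.

    Exact inverse of :func:`barrier_height`.
    """
    if not (np.all(np.asarray(nu) > 0) and np.all(np.asarray(volume_m3) > 0)):
        raise ValueError("nu and V must be strictly positive")
    return np.exp(barrier_kT) / (nu * volume_m3)


def volume_to_concentration(
    added_volume_uL,
    stock_mg_per_mL: float = 1.0,
    chamber_volume_mL: float = 2.5,
):
    """Nanoparticle concentration (ug/mL) after adding suspension to a chamber.

    Follows the convention that the added volume's own contribution to the
    chamber volume is ignored: ``c = v_added * c_stock / V_chamber``
    (100 uL of a 1 mg/mL stock into 2.5 mL gives 40 ug/mL).
    """
    v = np.asarray(added_volume_uL, dtype=float)
    if np.any(v < 0) or stock_mg_per_mL < 0:
        raise ValueError("volumes and concentrations must be non-negative")
    if chamber_volume_mL <= 0:
        raise ValueError("chamber volume must be strictly positive")
    c = v * stock_mg_per_mL / chamber_volume_mL
    return float(c) if np.isscalar(added_volume_uL) else c


def kT_to_joules(energy_kT: float, ctx: MembraneContext = DEFAULT_MEMBRANE) -> float:
    """Presentation utility: convert an energy in kT units to joules."""
    return energy_kT * _K_BOLTZMANN * ctx.temperature_K
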