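"""AUC transport observables from the hydrodynamic radius.

Converts between R_h, the translational diffusion coefficient D
(Stokes–Einstein), the sedimentation coefficient s (Svedberg relation), the
frictional ratio f/f0 and the apparent partial specific volume v̄′.  User
units are Å, μm²/s, svedbergs, kDa and ml/g; everything is converted to SI
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as c
from .exceptions import BuoyancyError, InvalidParameterError
from .hydrodynamics import HydroEnvironment

__all__ = [
    "MolecularSpec", "TransportResult",
    "diffusion_from_rh", "rh_from_diffusion", "svedberg_s", "apparent_psv",
    "frictional_ratio", "standard_conditions", "transport_from_rh",
]


@dataclass(frozen=True)
class MolecularSpec:
    """Analyte identity: molar mass in kDa and partial specific volume in ml/g."""

    molar_mass_M: float
    psv_vbar: float = 0.482
    label: str = ""

    def __post_init__(self):
        if self.molar_mass_M <= 0:
            raise InvalidParameterError("molar mass must be positive")
        if not 0 < self.psv_vbar < 1.5:
            raise InvalidParameterError("v̄ outside plausible range (0, 1.5) ml/g")

    @property
    def mass_kg_per_mol(self) -> float:
        return self.molar_mass_M  # kDa == kg/mol


@dataclass(frozen=True)
class TransportResult:
    """Predicted observables for one species under given conditions."""

    Rh: float           # Å
    D: float            # μm²/s
    s: float            # svedbergs
    f_over_f0: float
    vbar_apparent: float  # ml/g
    conditions: HydroEnvironment


def diffusion_from_rh(Rh: float, env: HydroEnvironment) -> float:
    """D = k_BT/(6πη·R_h) in μm²/s (R_h in Å)."""
    if Rh <= 0:
        raise InvalidParameterError("Rh must be positive")
    d_si = c.BOLTZMANN * env.temperature_T / (
        6.0 * np.pi * env.viscosity_eta * Rh * c.ANGSTROM)
    return c.m2s_to_um2s(d_si)


def rh_from_diffusion(D: float, env: HydroEnvironment) -> float:
    """Inverse Stokes–Einstein: R_h in Å from D in μm²/s."""
    if D <= 0:
        raise InvalidParameterError("D must be positive")
    return c.BOLTZMANN * env.temperature_T / (
        6.0 * np.pi * env.viscosity_eta * D * c.UM2_PER_S) / c.ANGSTROM


def svedberg_s(D: float, spec: MolecularSpec, env: HydroEnvironment) -> float:
    """Sedimentation coefficient s = M(1 − v̄ρ)·D/(R·T) in svedbergs.

    ``D`` in μm²/s; raises if the particle is neutrally buoyant or floats.
    """
    buoyancy = 1.0 - spec.psv_vbar * env.solvent_density_rho
    if buoyancy <= 0:
        raise BuoyancyError(
            f"v̄·ρ = {spec.psv_vbar * env.solvent_density_rho:.3f} >= 1: "
            "particle does not sediment")
    s_si = (spec.mass_kg_per_mol * buoyancy * D * c.UM2_PER_S
            / (c.GAS_CONSTANT * env.temperature_T))
    return s_si / c.SVEDBERG


def apparent_psv(s: float, D: float, spec: MolecularSpec,
                 env: HydroEnvironment) -> float:
    """Apparent partial specific volume v̄′ = (1/ρ)(1 − s·R·T/(M·D)) in ml/g.

    Exact algebraic inverse of :func:`svedberg_s`; warns (via ValueError-free
    return of a negative value is avoided) when the implied buoyancy is
    non-physical.
    """
    if min(s, D, env.solvent_density_rho) <= 0:
        raise InvalidParameterError("s, D and ρ must be positive")
    ratio = (s * c.SVEDBERG * c.GAS_CONSTANT * env.temperature_T
             / (spec.mass_kg_per_mol * D * c.UM2_PER_S))
    if ratio >= 1.0:
        import warnings
        warnings.warn("s/D pair implies non-positive buoyancy: apparent PSV "
                      "is non-physical", stacklevel=2)
    return (1.0 - ratio) / env.solvent_density_rho


def frictional_ratio(Rh: float, spec: MolecularSpec) -> float:
    """f/f0 = R_h/R0 with R0 the radius of the sphere of the analyte's
    PSV-defined volume, R0 = (3·M·v̄/(4π·N_A))^(1/3)."""
    if Rh <= 0:
        raise InvalidParameterError("Rh must be positive")
    # M v̄: (kg/mol)·(ml/g) = (1e3 g/mol)·(1e-6 m³/kg·...) — work in SI:
    vol_per_mol = spec.mass_kg_per_mol * spec.psv_vbar * 1e-3  # m³/mol
    r0 = (3.0 * vol_per_mol / (4.0 * np.pi * c.AVOGADRO)) ** (1.0 / 3.0)
    return Rh * c.ANGSTROM / r0


def standard_conditions(s_TB: float, D_TB: float, env_TB: HydroEnvironment,
                        vbar: float) -> tuple[float, float]:
    """Correct buffer-condition (s, D) to water at 20 ℃.

    s_20,w = s_T,B · (1 − v̄ρ)_20,w/(1 − v̄ρ)_T,B · η_T,B/η_20,w and
    D_20,w = D_T,B · (T_20/T) · η_T,B/η_20,w, with η_20,w = 1.0016 cP and
    ρ_20,w = 0.99823 g/ml built in.  Identity when the buffer already is
    water at 20 ℃.
    """
    eta_ratio = env_TB.viscosity_eta / (c.ETA_WATER_20C_CP * c.CENTIPOISE)
    buoy_20w = 1.0 - vbar * c.RHO_WATER_20C
    buoy_tb = 1.0 - vbar * env_TB.solvent_density_rho
    if buoy_tb <= 0:
        raise BuoyancyError("non-positive buoyancy in buffer conditions")
    s20 = s_TB * (buoy_20w / buoy_tb) * eta_ratio
    d20 = D_TB * (293.15 / env_TB.temperature_T) * eta_ratio
    return s20, d20


def transport_from_rh(Rh: float, spec: MolecularSpec,
                      env: HydroEnvironment) -> TransportResult:
    """Full observable set for a species of known R_h."""
    D = diffusion_from_rh(Rh, env)
    s = svedberg_s(D, spec, env)
    return TransportResult(
        Rh=Rh, D=D, s=s,
        f_over_f0=frictional_ratio(Rh, spec),
        vbar_apparent=apparent_psv(s, D, spec, env),
        conditions=env,
    )
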