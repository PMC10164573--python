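"""Order-of-magnitude electrostatic and energy-scale estimates.

These diagnostics justify treating a few-hundred-bp minicircle as a stiff
elastic beam: the Debye screening length in the AUC buffer is a few Å (far
below inter-segment distances), the electrostatic increment to the
persistence length is ~1 Å, and the bending/twisting energies stored in the
loop exceed k_BT by an order of magnitude or more.  They are reporting-only
quantities — nothing here feeds back into the shape minimiser.

Note on one published figure: evaluating R_D = 1/(κ0·√Cs) at Cs = 0.23 M
gives 6.3 Å, while a value of 1.45 Å is sometimes quoted for the same
conditions; 1.45 Å numerically matches the *electrostatic persistence
length* R_D²/(4·l_B) rather than R_D itself.  The formulas here are
implemented as written above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

__all__ = ["ElectrostaticParams", "debye_length", "persistence_length",
           "loop_energy_scales", "long_range_electrostatic_energy"]


@dataclass(frozen=True)
class ElectrostaticParams:
    """Ionic-solution parameters; lengths in Å, concentration in mol/l."""

    ionic_strength_Cs: float = 0.23
    kappa0: float = 0.329            # 1/(Å sqrt(mol/l))
    bjerrum_length_lB: float = 7.1   # Å, water at ~20 C
    charge_q: float = 1.0            # per site, in elementary charges
    n_charges_N: int = 672           # two per bp for a 336-bp loop
    intrinsic_P_in: float = 500.0    # Å

    def __post_init__(self):
        if self.ionic_strength_Cs <= 0:
            raise InvalidParameterError("ionic strength must be positive")
        if min(self.kappa0, self.bjerrum_length_lB, self.intrinsic_P_in) <= 0:
            raise InvalidParameterError("lengths must be positive")


def debye_length(params: ElectrostaticParams) -> float:
    """Debye screening length R_D = 1/(κ0·√Cs) in Å."""
    return 1.0 / (params.kappa0 * np.sqrt(params.ionic_strength_Cs))


def persistence_length(params: ElectrostaticParams) -> tuple[float, float]:
    """(P_el, P_total) in Å.

    The electrostatic part follows Odijk–Skolnick–Fixman,
    P_el = R_D²/(4·l_B), and adds to the intrinsic backbone rigidity.
    """
    rd = debye_length(params)
    p_el = rd**2 / (4.0 * params.bjerrum_length_lB)
    return p_el, params.intrinsic_P_in + p_el


def loop_energy_scales(dLk: float, loop_length: float,
                       persistence: float) -> tuple[float, float]:
    """(E_bend, E_twist) of a circular loop in k_BT.

    E_bend = 4π²·P/L and E_twist = 6π²·ΔLk²·P/L.  ``loop_length`` and
    ``persistence`` must share a unit (both bp or both Å): only their ratio
    enters, so e.g. P = 150 bp with L = 336 bp and P = 500 Å with
    L = 1142.4 Å are both valid conventions.
    """
    if loop_length <= 0 or persistence <= 0:
        raise InvalidParameterError("P and L must be positive")
    ratio = persistence / loop_length
    e_bend = 4.0 * np.pi**2 * ratio
    e_twist = 6.0 * np.pi**2 * dLk**2 * ratio
    return e_bend, e_twist


def long_range_electrostatic_energy(params: ElectrostaticParams,
                                    L: float) -> float:
    """Screened loop-scale electrostatic energy in k_BT.

    E_lr ≈ (q²·N·l_B / 2L)·exp(−L/(2π·R_D)) — the interaction of N charges q
    at a typical separation of the loop radius L/2π, exponentially screened.
    (The Bjerrum length converts the Coulomb prefactor q²N/(2εL) to k_BT
    units.)  Negligible for minicircles in a physiological-strength buffer.
    """
    if L <= 0:
        raise InvalidParameterError("L must be positive")
    rd = debye_length(params)
    prefactor = (params.charge_q**2 * params.n_charges_N
                 * params.bjerrum_length_lB) / (2.0 * L)
    return prefactor * np.exp(-L / (2.0 * np.pi * rd))
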