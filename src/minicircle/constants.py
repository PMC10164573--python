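"""Physical constants and unit conversions.

User-facing units throughout the package are Å, μm²/s, svedbergs (1 S =
1e-13 s), kDa, ml/g, cP and kelvin; all internal transport computations are
done in SI and converted at the boundary by the helpers below.
"""

# CODATA 2018 exact values
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
GAS_CONSTANT = BOLTZMANN * AVOGADRO  # J/(mol K)

# Water at 20 C (CRC Handbook); used by the standard-condition corrections.
ETA_WATER_20C_CP = 1.0016  # cP
RHO_WATER_20C = 0.99823  # g/ml

# Default experimental buffer (50 mM Tris-Cl, 150 mM NaCl, 10 mM CaCl2, 20 C)
BUFFER_ETA_CP = 1.02667
BUFFER_RHO = 1.00682  # g/ml
BUFFER_T = 293.15  # K

# B-DNA geometry defaults
RISE_PER_BP = 3.4  # Å per base pair (axial rise)
HELICAL_REPEAT = 10.42  # bp per turn in 10 mM CaCl2
PERSISTENCE_LENGTH = 500.0  # Å (~150 bp) for dsDNA near 0.1 M monovalent salt

ANGSTROM = 1e-10  # m
CENTIPOISE = 1e-3  # Pa s
SVEDBERG = 1e-13  # s
UM2_PER_S = 1e-12  # m^2/s


def cp_to_pas(eta_cp: float) -> float:
    return eta_cp * CENTIPOISE


def angstrom_to_m(x: float) -> float:
    return x * ANGSTROM


def m2s_to_um2s(d: float) -> float:
    return d / UM2_PER_S


def bp_to_angstrom(n_bp: float, rise: float = RISE_PER_BP) -> float:
    return n_bp * rise
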