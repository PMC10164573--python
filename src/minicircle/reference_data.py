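"""Published benchmark data for 336 bp and 672 bp DNA minicircles.

Sedimentation-velocity (AUC) measurements and model predictions for
minicircle topoisomers in 50 mM Tris-Cl pH 8.0, 150 mM NaCl, 10 mM CaCl2 at
20 ℃, together with the per-sample apparent partial specific volumes derived
from them and the gel-quantified topoisomer mixtures of the supercoiled
preparations.  These serve as calibration inputs and regression anchors for
the hydroelastic pipeline; they are printed-table values, reported at the
precision of the source.
"""

from __future__ import annotations

# molar masses from sequence, g/mol (kDa * 1000)
MOLAR_MASS_KDA = {336: 207.576, 672: 415.152}

# buffer conditions used for every measurement below
BUFFER = {"eta_cp": 1.02667, "rho": 1.00682, "T": 293.15}

# study-average apparent PSV (ml/g)
PSV_AVERAGE = 0.482

# per-sample apparent PSV in the buffer (ml/g)
PSV_TABLE = {
    ("336", "linear"): 0.479,
    ("336", "relaxed"): 0.470,
    ("336", "nicked"): 0.469,
    ("336", "supercoiled"): 0.488,
    ("336", "hypernegative"): 0.479,
    ("672", "nicked"): 0.495,
    ("672", "supercoiled"): 0.494,
}

# (D predicted, D measured, s predicted, s measured); D in μm²/s, s in S.
# dominant |ΔLk| of the species the prediction was made for (None = linear)
TRANSPORT_TABLE = [
    {"sample": "336 linear", "length_bp": 336, "kind": "linear",
     "dlk_dominant": None,
     "D_pred": 14.7, "D_meas": 14.5, "s_pred": 6.4, "s_meas": 6.40},
    {"sample": "336 relaxed", "length_bp": 336, "kind": "relaxed",
     "dlk_dominant": 0,
     "D_pred": 17.2, "D_meas": 16.2, "s_pred": 7.5, "s_meas": 7.26},
    {"sample": "336 nicked", "length_bp": 336, "kind": "nicked",
     "dlk_dominant": 0,
     "D_pred": 17.2, "D_meas": 16.1, "s_pred": 7.5, "s_meas": 7.25},
    {"sample": "336 supercoiled", "length_bp": 336, "kind": "supercoiled",
     "dlk_dominant": -3,
     "D_pred": 20.5, "D_meas": 19.0, "s_pred": 9.0, "s_meas": 8.28},
    {"sample": "336 hypernegatively supercoiled", "length_bp": 336,
     "kind": "hypernegative", "dlk_dominant": -6,
     "D_pred": 21.9, "D_meas": 20.1, "s_pred": 9.6, "s_meas": 8.89},
    {"sample": "672 nicked", "length_bp": 672, "kind": "nicked",
     "dlk_dominant": 0,
     "D_pred": 9.9, "D_meas": 10.3, "s_pred": 8.7, "s_meas": 8.77},
    {"sample": "672 supercoiled", "length_bp": 672, "kind": "supercoiled",
     "dlk_dominant": -4,
     "D_pred": 12.4, "D_meas": 12.5, "s_pred": 10.9, "s_meas": 10.72},
]

# map rows of TRANSPORT_TABLE to rows of PSV_TABLE
PSV_KEY_FOR_SAMPLE = {
    "336 linear": ("336", "linear"),
    "336 relaxed": ("336", "relaxed"),
    "336 nicked": ("336", "nicked"),
    "336 supercoiled": ("336", "supercoiled"),
    "336 hypernegatively supercoiled": ("336", "hypernegative"),
    "672 nicked": ("672", "nicked"),
    "672 supercoiled": ("672", "supercoiled"),
}

# gel-quantified topoisomer fractions of the mixed samples
TOPOISOMER_MIXTURES = {
    ("336", "supercoiled"): {-3: 0.48, -2: 0.41, -1: 0.07},
    ("336", "hypernegative"): {-6: 0.61, -5: 0.33},
    ("672", "supercoiled"): {-4: 0.63, -5: 0.24, -6: 0.06},
}

# fitted hydrodynamic thickness (Å) used for all bead-model predictions;
# obtained by fitting a common d_h to the measured R_h of nicked/relaxed
# loops of both lengths (logarithmic sensitivity: treat as approximate)
DH_FITTED = 29.4

# hydrodynamic aspect ratios the predictions are quoted at (d_h/L)
DH_OVER_L = {336: 2.6e-2, 672: 1.3e-2}

# elastic (steric) aspect ratios (d_s/L) with d_s = 20 Å
DS_OVER_L = {336: 0.018, 672: 0.0090, 718: 0.0082}

HELICAL_REPEAT = 10.42  # bp/turn in 10 mM CaCl2
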