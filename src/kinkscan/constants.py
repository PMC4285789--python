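"""Packaged physical and biochemical constants.

These are data, not computed quantities: standard backbone internal
coordinates, van der Waals radii, the experimentally derived
interface-to-octanol transfer free-energy scale used as the hydrophobicity
measure, and Gly-X-Gly reference maxima for relative solvent accessibility.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# common modified residues with an unambiguous parent amino acid
NONSTANDARD_PARENT = {
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K", "M3L": "K",
    "KCX": "K", "CME": "C", "FME": "M",
}

# Standard backbone internal coordinates (Engh-Huber-style values), Å / deg.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

# Ideal alpha-helix parametrization used by the helical-seed criteria.
IDEAL_RISE = 1.5          # Å per residue
IDEAL_TWIST = 100.0       # degrees per residue
IDEAL_CA_RADIUS = 2.3     # Å

# Ideal phi/psi for the alpha-helical region (starting point for the
# rise/twist solver in the synthetic generator).
ALPHA_PHI = -57.8
ALPHA_PSI = -47.0

# Rectangular alpha-region bounds for the helical-seed dihedral test, deg.
ALPHA_REGION_PHI = (-140.0, -30.0)
ALPHA_REGION_PSI = (-90.0, 45.0)

# Kabsch-Sander hydrogen-bond energy: E = Q * (1/rON + 1/rCH - 1/rOH - 1/rCN)
KS_Q = 0.084 * 332.0      # kcal/mol * Å
KS_HBOND_CUTOFF = -0.5    # kcal/mol
KS_MIN_ENERGY = -9.9      # clamp for near-contact numerical blowups

# Sidechain-to-backbone hydrogen-bond geometric rule.
SC_HBOND_MAX_DIST = 3.5   # Å, donor heavy atom to acceptor
SC_HBOND_MIN_ANGLE = 90.0  # deg at the donor heavy atom

# Sidechain donor heavy atoms per residue, with their covalent antecedent
# (used for the donor-angle test when present).
SIDECHAIN_DONORS = {
    "S": [("OG", "CB")],
    "T": [("OG1", "CB")],
    "Y": [("OH", "CZ")],
    "N": [("ND2", "CG")],
    "Q": [("NE2", "CD")],
    "K": [("NZ", "CE")],
    "R": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "W": [("NE1", "CD1")],
    "H": [("ND1", "CG"), ("NE2", "CD2")],
    "C": [("SG", "CB")],
}

# van der Waals radii (Å) by element for Shrake-Rupley surface areas.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
VDW_DEFAULT = 1.70
SASA_PROBE_RADIUS = 1.4
SASA_N_SPHERE_POINTS = 256
SASA_ACCESSIBLE_THRESHOLD = 0.07  # fraction above which a residue is "accessible"

# Maximum accessible surface areas (Å^2) of residue X in an extended
# Gly-X-Gly tripeptide; denominators for relative accessibility.
MAX_SASA_GLY_X_GLY = {
    "A": 113.0, "R": 241.0, "N": 158.0, "D": 151.0, "C": 140.0,
    "Q": 189.0, "E": 183.0, "G": 85.0, "H": 194.0, "I": 182.0,
    "L": 180.0, "K": 211.0, "M": 204.0, "F": 218.0, "P": 143.0,
    "S": 122.0, "T": 146.0, "W": 259.0, "Y": 229.0, "V": 160.0,
}

# Experimentally derived interface-to-octanol transfer free energies
# (kcal/mol); positive = prefers the interface (hydrophilic), negative =
# prefers octanol (hydrophobic).
INTERFACE_OCTANOL_DG = {
    "A": 0.33, "R": 1.00, "N": 0.43, "D": 2.41, "C": -0.22,
    "Q": 0.19, "E": 1.61, "G": 1.14, "H": 0.06, "I": -0.81,
    "L": -0.69, "K": 1.81, "M": -0.44, "F": -0.58, "P": -0.31,
    "S": 0.33, "T": 0.11, "W": -0.24, "Y": -0.13, "V": -0.53,
}

# Kink-relative offsets that sit on the inside (concave face) of a kink in
# the standard helical-wheel numbering; the complement within one turn on
# each side is the outside.
INSIDE_OFFSETS = (-4, -3, 0, 3, 4)
OUTSIDE_OFFSETS = (-5, -2, 2, 5)

# Motif expressions commonly screened around kinks (literal one-letter
# codes, `x` = any residue, square brackets = alternatives; the final entry
# is the positional special case: Gly at kink offset 0 or +1).
DEFAULT_MOTIFS = [
    "[AVILMFYW]xxxP", "xxxxP", "[ST]P", "[DR]P", "xP", "xxxP",
    "[AVILMFYW]xP", "GxP", "xxP", "P[ST]", "Px", "P",
    "[VALT]LWx[AG]YP", "GHPxVY[FI]", "[ST][ST]", "[ST]xx[ST]",
    "[ST]xxx[ST]", "GxxGxxxG", "GxxxGxxG", "[FYW]xxxSxxx[FYW]",
    "LSAxF", "WLF[ST]", "[FYW]xxx[FYW]", "[FYW]xxx[FYW]xx[FYW]",
    "[FYW]xxx[FYW]xxx[FYW]", "[FYW]xx[FYW]xxx[FYW]",
    "[RHDEK]xxx[RHDEK]", "[ASG]xxx[ASG]", "[STNQ]xxx[STNQ]",
    "G_0 or G_+1",
]
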