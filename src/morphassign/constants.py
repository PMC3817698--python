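"""Shared chemical and geometric constants.

Ideal backbone geometry follows Engh & Huber-style values commonly used in
restraint libraries.  Side-chain "size" is measured in electrons of the
side-chain heavy atoms, which is the quantity a density probe actually sees.
"""

from __future__ import annotations

import numpy as np

# --- residue naming -------------------------------------------------------

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA1_TO_3["X"] = "UNK"
STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_SEQ_CHARS = set(STANDARD_AA1) | {"X"}

# --- ideal backbone geometry (Å, degrees) ---------------------------------

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329   # peptide bond
BOND_C_O = 1.231
BOND_CA_CB = 1.530

ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4

# derived 1-3 distances across the peptide link (law of cosines)


def _d13(b1: float, b2: float, angle_deg: float) -> float:
    a = np.deg2rad(angle_deg)
    return float(np.sqrt(b1 * b1 + b2 * b2 - 2.0 * b1 * b2 * np.cos(a)))


DIST_CA_N_NEXT = _d13(BOND_CA_C, BOND_C_N, ANGLE_CA_C_N)    # CA(i)-N(i+1)
DIST_C_CA_NEXT = _d13(BOND_C_N, BOND_N_CA, ANGLE_C_N_CA)    # C(i)-CA(i+1)
DIST_O_N_NEXT = 2.250                                        # O(i)-N(i+1), trans planar
DIST_CA_CA_TRANS = 3.80                                      # CA(i)-CA(i+1), omega=180

# maximum CA-CA separation within a continuous chain; beyond this the chain
# is treated as broken (trans peptide ~3.8 Å plus tolerance)
CHAIN_BREAK_CUTOFF = 4.5

# --- side-chain electron counts (heavy atoms beyond CA) --------------------
# C=6, N=7, O=8, S=16 electrons; counts from standard residue compositions.

SIDECHAIN_ELECTRONS = {
    "G": 0,            # no side chain
    "A": 6,            # CB
    "S": 6 + 8,        # CB OG
    "C": 6 + 16,       # CB SG
    "T": 2 * 6 + 8,    # CB OG1 CG2
    "V": 3 * 6,        # CB CG1 CG2
    "P": 3 * 6,        # CB CG CD
    "I": 4 * 6,        # CB CG1 CG2 CD1
    "L": 4 * 6,        # CB CG CD1 CD2
    "N": 2 * 6 + 7 + 8,        # CB CG OD1 ND2
    "D": 2 * 6 + 2 * 8,        # CB CG OD1 OD2
    "M": 3 * 6 + 16,           # CB CG SD CE
    "Q": 3 * 6 + 7 + 8,        # CB CG CD OE1 NE2
    "E": 3 * 6 + 2 * 8,        # CB CG CD OE1 OE2
    "K": 4 * 6 + 7,            # CB CG CD CE NZ
    "H": 4 * 6 + 2 * 7,        # CB CG ND1 CD2 CE1 NE2
    "R": 4 * 6 + 3 * 7,        # CB CG CD NE CZ NH1 NH2
    "F": 7 * 6,                # CB CG CD1 CD2 CE1 CE2 CZ
    "Y": 7 * 6 + 8,            # phenyl + OH
    "W": 9 * 6 + 7,            # indole
    "X": 4 * 6,                # unknown: leucine-like
}

_vals = np.array([SIDECHAIN_ELECTRONS[a] for a in STANDARD_AA1], dtype=float)
SIDECHAIN_ELECTRONS_MEAN = float(_vals.mean())
SIDECHAIN_ELECTRONS_SD = float(_vals.std())

# electrons of the side chain beyond CB (used for the reduced side-chain
# pseudo-atom of the synthetic generator)
SIDECHAIN_ELECTRONS_BEYOND_CB = {
    a: max(0, e - 6) if a != "G" else 0 for a, e in SIDECHAIN_ELECTRONS.items()
}

# approximate amino-acid composition of globular proteins, used by the
# synthetic sequence generator
AA_COMPOSITION = {
    "A": 0.083, "R": 0.055, "N": 0.041, "D": 0.054, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.096, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.054, "W": 0.011, "Y": 0.029, "V": 0.069,
}
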