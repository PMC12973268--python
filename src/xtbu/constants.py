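"""Physical constants, unit conversions, and per-element reference data.

All energies are Hartree and all lengths Bohr internally; the XYZ interface
is Angstrom.  The kcal/mol conversion constant is fixed here so spin gaps are
reproducible to the digit.
"""

from __future__ import annotations

# CODATA 2018
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903
EV_PER_HARTREE = 27.211386245988
HARTREE_PER_EV = 1.0 / EV_PER_HARTREE
KB_HARTREE = 3.166811563e-6  # Boltzmann constant, Hartree / K
HARTREE_TO_KCAL = 627.5095  # fixed convention for spin gaps

# element symbol -> atomic number (subset relevant to the shipped parameterization
# plus common light elements for input validation)
SYMBOL_TO_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Sc": 21, "Ti": 22,
    "V": 23, "Cr": 24, "Mn": 25, "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29,
    "Zn": 30,
}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

ANGULAR_MOMENTUM = {"s": 0, "p": 1, "d": 2}
L_LABEL = {0: "s", 1: "p", 2: "d"}


def normalize_symbol(sym: str) -> str:
    """Case-normalize an element symbol ('fe' -> 'Fe')."""
    s = sym.strip().capitalize()
    if s not in SYMBOL_TO_Z:
        raise ValueError(f"unknown element symbol: {sym!r}")
    return s
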