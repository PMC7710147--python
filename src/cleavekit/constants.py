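"""Bundled physical constants and residue tables.

Masses are monoisotopic, fixed to 6-decimal standard values so tests are
bit-exact. The table is versioned: bump ``MASS_TABLE_VERSION`` whenever a
value changes.
"""

from __future__ import annotations

MASS_TABLE_VERSION = "2023.1"

#: Monoisotopic residue masses in Da (residue = amino acid minus water).
RESIDUE_MASS: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

WATER_MASS = 18.010565
PROTON_MASS = 1.0072765
HYDROGEN_MASS = 1.0078250319
#: Neutral mass lost per disulfide bond (two hydrogens).
DISULFIDE_DELTA = 2 * HYDROGEN_MASS

#: Named modification deltas (Da).
MOD_MASS: dict[str, float] = {
    "Carbamidomethyl": 57.021464,
    "Hyp": 15.994915,
    "Oxidation": 15.994915,
    "Phospho": 79.966331,
    "Acetyl": 42.010565,
    "Deamidation": 0.984016,
}

#: Canonical residue alphabet; X is allowed in sequences but has no mass and
#: is never a cleavage site.
CANONICAL_RESIDUES = frozenset(RESIDUE_MASS)
ALLOWED_RESIDUES = CANONICAL_RESIDUES | {"X"}

#: Average residue frequencies of a large curated protein database,
#: normalised to sum to exactly 1.
_RAW_BACKGROUND = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0966, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}
_total = sum(_RAW_BACKGROUND.values())
BACKGROUND_FREQUENCIES: dict[str, float] = {
    aa: f / _total for aa, f in _RAW_BACKGROUND.items()
}

#: Residues treated as basophilic in cleavage-context modelling.
BASOPHILIC_RESIDUES = frozenset({"K", "R", "H"})

GAP_SYMBOL = "-"
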