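"""Shared chemical reference tables.

Single place for van-der-Waals radii, average residue masses, chromophore
extinction coefficients, hydrogen-bond donor/acceptor typing, charged-group
typing, aromatic-ring definitions and atomic hydrophobicity constants.
Values are standard published ones; everything is plain data so callers can
copy and override.
"""

from __future__ import annotations

# --- van der Waals radii (Bondi), Å, element-keyed -------------------------

VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
#: fallback radius for elements missing from VDW_RADII
VDW_DEFAULT = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), VDW_DEFAULT)


# --- average residue masses (IUPAC 2021 atomic weights), Da ----------------
# Mass of the residue (monomer minus water); add WATER_MASS once per chain.

RESIDUE_AVERAGE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.01528
HYDROGEN_MASS = 1.00794
PROTON_MASS = 1.00794  # average-mass convention: m/z uses H mass

# --- extinction coefficients at 280 nm, M^-1 cm^-1 (Pace et al.) -----------

EPS280_TRP = 5500
EPS280_TYR = 1490
EPS280_CYSTINE = 125

# --- hydrogen-bond donor / acceptor heavy atoms ----------------------------
# Keyed by residue name; "*" applies to every amino-acid residue (backbone).
# Donors are heavy atoms carrying a polar hydrogen; acceptors bear lone pairs.

BACKBONE_DONORS = ("N",)
BACKBONE_ACCEPTORS = ("O", "OXT")

SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "TRP": ("NE1",),
    # glycan units (receptor N-glycosylation)
    "NAG": ("O3", "O4", "O6", "N2"),
    "MAN": ("O2", "O3", "O4", "O6"),
    "BMA": ("O2", "O3", "O4", "O6"),
}

SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "MET": ("SD",),
    "NAG": ("O3", "O4", "O5", "O6", "O7"),
    "MAN": ("O2", "O3", "O4", "O5", "O6"),
    "BMA": ("O2", "O3", "O4", "O5", "O6"),
}

# --- charged groups for salt-bridge detection ------------------------------

POSITIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
}
# His is neutral by default; enabled via InteractionGeometry.his_charged
POSITIVE_ATOMS_HIS: tuple[str, ...] = ("ND1", "NE2")

NEGATIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
CTERM_NEGATIVE: tuple[str, ...] = ("OXT",)

# --- aromatic rings for stacking detection ---------------------------------

AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ),
}

# --- atomic hydrophobicity constants ---------------------------------------
# Ghose–Crippen-style signed constants, simplified to the level the
# molecular-hydrophobicity-potential complementarity score needs: apolar
# atoms positive, polar/charged atoms negative.  Lookup order:
# (residue, atom name) override, then element default.

MHP_ELEMENT: dict[str, float] = {
    "C": 0.35,
    "S": 0.30,
    "N": -0.40,
    "O": -0.40,
    "H": 0.10,
    "P": -0.30,
}

MHP_ATOM_OVERRIDES: dict[tuple[str, str], float] = {
    # backbone carbonyl carbon is attached to polar O; slightly less apolar
    ("*", "C"): 0.10,
    ("*", "CA"): 0.25,
    # synthetic residues used by the generator (see synthgen)
    ("HPB", "C1"): 0.50,
    ("POL", "C1"): -0.50,
}


def mhp_constant(res_name: str, atom_name: str, element: str) -> float:
    for key in ((res_name, atom_name), ("*", atom_name)):
        if key in MHP_ATOM_OVERRIDES:
            return MHP_ATOM_OVERRIDES[key]
    return MHP_ELEMENT.get(element.upper(), 0.0)
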