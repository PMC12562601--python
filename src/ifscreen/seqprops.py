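"""Sequence-derived protein properties: average mass, m/z, extinction.

Average (not monoisotopic) masses throughout, from the IUPAC atomic-weight
table in :mod:`ifscreen.tables`.  Disulfide oxidation removes two hydrogen
atoms per bridge.  The 280 nm molar extinction coefficient uses the
standard per-chromophore values (Trp 5500, Tyr 1490, cystine 125
M⁻¹·cm⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass

from .tables import (EPS280_CYSTINE, EPS280_TRP, EPS280_TYR, HYDROGEN_MASS,
                     PROTON_MASS, RESIDUE_AVERAGE_MASS, WATER_MASS)

#: mature water-soluble PSCA construct: N-terminal Met (start codon)
#: followed by the Ly6 domain Leu12–Ser86 of human PSCA (UniProt O43653);
#: five disulfide bridges.  Mature numbering: Met0, Leu1 ... Ser75.
WS_PSCA_SEQUENCE = (
    "M"
    "LLCYSCKAQVSNEDCLQVENCTQLGEQCWTARIRAVGLLTVISKGCSLNCVDDSQDYYVGKKNITCCDTDLCNAS"
)
WS_PSCA_DISULFIDES = 5


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter sequence plus its disulfide count (free N/C termini)."""

    residues: str
    n_disulfides: int = 0

    def __post_init__(self):
        bad = set(self.residues) - set(RESIDUE_AVERAGE_MASS)
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(bad)}")
        if 2 * self.n_disulfides > self.residues.count("C"):
            raise ValueError("more disulfides than cysteine pairs")

    def __len__(self):
        return len(self.residues)


WS_PSCA = ProteinSequence(WS_PSCA_SEQUENCE, WS_PSCA_DISULFIDES)


def average_mass(seq: ProteinSequence, oxidized: bool = False) -> float:
    """Average molecular mass in Da; oxidized removes 2 H per disulfide."""
    mass = sum(RESIDUE_AVERAGE_MASS[c] for c in seq.residues) + WATER_MASS
    if oxidized:
        mass -= 2.0 * HYDROGEN_MASS * seq.n_disulfides
    return mass


def mz_multiply_protonated(seq: ProteinSequence, z: int,
                           oxidized: bool = False) -> float:
    """Average m/z of the [M+zH]^z+ ion."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (average_mass(seq, oxidized) + z * PROTON_MASS) / z


def extinction_280(seq: ProteinSequence,
                   all_cys_as_cystine: bool = False) -> float:
    """Molar extinction coefficient at 280 nm, M⁻¹·cm⁻¹.

    Cystine count is ``n_disulfides`` by default; with
    ``all_cys_as_cystine`` every cysteine is assumed paired (count // 2).
    """
    n_trp = seq.residues.count("W")
    n_tyr = seq.residues.count("Y")
    n_cystine = (seq.residues.count("C") // 2 if all_cys_as_cystine
                 else seq.n_disulfides)
    return EPS280_TRP * n_trp + EPS280_TYR * n_tyr + EPS280_CYSTINE * n_cystine


def property_report(seq: ProteinSequence) -> dict:
    """All derived properties in one JSON-ready dict."""
    return {
        "n_residues": len(seq),
        "n_disulfides": seq.n_disulfides,
        "average_mass_reduced_da": average_mass(seq, oxidized=False),
        "average_mass_oxidized_da": average_mass(seq, oxidized=True),
        "mz_2plus_oxidized_da": mz_multiply_protonated(seq, 2, oxidized=True),
        "extinction_280_M_cm": extinction_280(seq),
    }
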