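"""Interface descriptors for one receptor/ligand pose.

The four pose-filtering quantities — buried surface area (BSA), number of
intermolecular hydrogen bonds, number of intermolecular ionic bridges and
the molecular-hydrophobicity-potential (MHP) complementarity score — plus
aromatic stacking contacts and a typed per-residue-pair contact
enumeration.

Geometry conventions (all configurable via :class:`InteractionGeometry`):

* H-bond: donor-heavy to acceptor-heavy distance <= 3.5 Å; when the donor
  carries explicit hydrogens the D-H···A angle must also be >= 120°.
  Structures without hydrogens fall back to the distance criterion.
* Ionic bridge: side-chain charged N (Arg, Lys; His optional) to
  carboxylate O (Asp, Glu, C-terminal OXT) within 4.0 Å; one bridge per
  residue pair.
* Stacking: ring-centroid distance <= 5.5 Å with interplanar angle in a
  parallel (0-30°) or T-shaped (60-90°) band.
* SASA: Shrake-Rupley sphere sampling, probe 1.4 Å, 960 points per atom.
* MHP: field at a surface point p is sum_i f_i * exp(-d(p, i) / lambda)
  with lambda = 2 Å and atomic constants from :mod:`ifscreen.tables`; the
  complementarity score is the fraction of buried surface points where
  both partners' fields share a sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import tables
from .structmodel import Residue, StructureModel, merge

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
STANDARD_AA = set(THREE_TO_ONE)
GLYCAN_RESIDUES = {"MAN", "NAG", "BMA", "FUC", "GAL", "SIA"}


@dataclass
class InteractionGeometry:
    """Geometric cutoffs for all interface detectors."""

    hbond_dist_max: float = 3.5      # Å, donor heavy atom to acceptor
    hbond_angle_min: float = 120.0   # degrees, D-H···A, used when H present
    ionic_dist_max: float = 4.0      # Å
    his_charged: bool = False
    stacking_centroid_max: float = 5.5            # Å
    stacking_angle_bands: tuple = ((0.0, 30.0), (60.0, 90.0))  # degrees
    sasa_probe: float = 1.4          # Å
    sasa_points: int = 960           # sample points per atom
    mhp_lambda: float = 2.0          # Å, field decay length
    clash_dist: float = 1.0          # Å, inter-partner distance treated as a clash

    def __post_init__(self):
        for name in ("hbond_dist_max", "ionic_dist_max", "stacking_centroid_max",
                     "sasa_probe", "mhp_lambda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for lo, hi in self.stacking_angle_bands:
            if not (0.0 <= lo <= hi <= 90.0):
                raise ValueError("stacking angle bands must lie within [0, 90]°")


@dataclass
class InterfaceDescriptor:
    """The pose-level quantities the non-specific filter thresholds."""

    bsa: float
    n_hbonds: int
    n_ionic: int
    mhp_score: float | None
    n_stacking: int = 0

    def __post_init__(self):
        if self.bsa < 0 or self.n_hbonds < 0 or self.n_ionic < 0 or self.n_stacking < 0:
            raise ValueError("descriptor fields must be non-negative")
        if self.mhp_score is not None and not (0.0 <= self.mhp_score <= 1.0):
            raise ValueError("mhp_score must be in [0, 1] when defined")


@dataclass(frozen=True)
class HBond:
    donor_res: tuple
    acceptor_res: tuple
    donor_atom: str
    acceptor_atom: str
    distance: float
    angle: float | None  # None when no hydrogens are present


@dataclass(frozen=True)
class SaltBridge:
    positive_res: tuple
    negative_res: tuple
    min_distance: float


@dataclass(frozen=True)
class StackingContact:
    res_a: tuple
    res_b: tuple
    centroid_distance: float
    interplanar_angle: float


@dataclass(frozen=True)
class ContactRecord:
    """Union of interaction kinds between one ligand and one receptor residue."""

    ligand_residue: tuple      # (chain_id, seq_id, res_name)
    receptor_residue: tuple    # (chain_id, seq_id, res_name)
    receptor_role: str         # '+', '-', or 'other'
    kinds: frozenset           # subset of {'H', 'I', 'S'}
    partner_is_glycan: bool = False
    glycan_parent: int | None = None

    def __post_init__(self):
        if not self.kinds:
            raise ValueError("contact must have at least one interaction kind")

    @staticmethod
    def _short(res: tuple) -> str:
        chain, seq, name = res
        one = THREE_TO_ONE.get(name)
        return f"{one}{seq}" if one else f"{name}{seq}"

    @property
    def ligand_label(self) -> str:
        return self._short(self.ligand_residue)

    @property
    def receptor_label(self) -> str:
        base = self._short(self.receptor_residue)
        if self.partner_is_glycan and self.glycan_parent is not None:
            base = f"{self.receptor_residue[2]}(N{self.glycan_parent})"
        return f"{base}({self.receptor_role})"


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _accessible_masks(coords: np.ndarray, radii: np.ndarray, probe: float,
                      n_points: int, obstacles: tuple | None = None
                      ) -> np.ndarray:
    """(n_atoms, n_points) boolean: surface sample point solvent-accessible.

    ``obstacles`` optionally adds further occluding spheres
    (coords, radii), e.g. the binding partner when evaluating one side of
    a complex; occlusion is order-independent.
    """
    unit = _sphere_points(n_points)
    ext = radii + probe
    if obstacles is not None:
        all_coords = np.concatenate([coords, obstacles[0]])
        all_ext = np.concatenate([ext, obstacles[1] + probe])
    else:
        all_coords, all_ext = coords, ext
    tree = cKDTree(all_coords)
    masks = np.ones((len(coords), n_points), dtype=bool)
    rmax = all_ext.max()
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * unit
        neigh = tree.query_ball_point(coords[i], ext[i] + rmax)
        for j in neigh:
            if j == i:
                continue
            d2 = np.sum((pts - all_coords[j]) ** 2, axis=1)
            masks[i] &= d2 >= all_ext[j] ** 2
    return masks


def sasa(structure: StructureModel, geometry: InteractionGeometry | None = None
         ) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å² (Shrake-Rupley)."""
    geometry = geometry or InteractionGeometry()
    if structure.n_atoms == 0:
        raise ValueError("no atoms")
    coords = structure.coords[0]
    radii = structure.radii()
    masks = _accessible_masks(coords, radii, geometry.sasa_probe, geometry.sasa_points)
    ext = radii + geometry.sasa_probe
    frac = masks.mean(axis=1)
    return 4.0 * np.pi * ext ** 2 * frac


def buried_surface_area(receptor: StructureModel, ligand: StructureModel,
                        geometry: InteractionGeometry | None = None) -> float:
    """BSA = SASA(receptor) + SASA(ligand) - SASA(complex), Å² (clamped >= 0)."""
    geometry = geometry or InteractionGeometry()
    _check_clash(receptor, ligand, geometry)
    buried = 0.0
    for own, other in ((receptor, ligand), (ligand, receptor)):
        coords = own.coords[0]
        radii = own.radii()
        ext = radii + geometry.sasa_probe
        alone = _accessible_masks(coords, radii, geometry.sasa_probe,
                                  geometry.sasa_points)
        in_complex = _accessible_masks(
            coords, radii, geometry.sasa_probe, geometry.sasa_points,
            obstacles=(other.coords[0], other.radii()))
        frac_lost = (alone & ~in_complex).mean(axis=1)
        buried += float((4.0 * np.pi * ext ** 2 * frac_lost).sum())
    return max(0.0, buried)


def _check_clash(receptor: StructureModel, ligand: StructureModel,
                 geometry: InteractionGeometry) -> None:
    tree = cKDTree(receptor.coords[0])
    d, _ = tree.query(ligand.coords[0], k=1)
    if np.min(d) < geometry.clash_dist:
        raise ValueError(
            f"steric clash: inter-partner atom distance {np.min(d):.2f} Å "
            f"< {geometry.clash_dist} Å"
        )


# ---------------------------------------------------------------------------
# Typed interaction detectors
# ---------------------------------------------------------------------------

def _residue_atoms(structure: StructureModel, res: Residue):
    for ai in range(res.start, res.stop):
        yield ai, structure.atoms[ai]


def _donor_atoms(structure: StructureModel):
    """Yield (atom index, residue, attached hydrogen coords list)."""
    coords = structure.coords[0]
    for res in structure.residues:
        names = {}
        hydrogens = []
        for ai, atom in _residue_atoms(structure, res):
            names[atom.name] = ai
            if atom.element.upper() == "H":
                hydrogens.append(ai)
        donors = []
        if res.res_name in STANDARD_AA and res.res_name != "PRO":
            donors += [n for n in tables.BACKBONE_DONORS if n in names]
        donors += [n for n in tables.SIDECHAIN_DONORS.get(res.res_name, ())
                   if n in names]
        for name in donors:
            ai = names[name]
            att = [hi for hi in hydrogens
                   if np.linalg.norm(coords[hi] - coords[ai]) <= 1.3]
            yield ai, res, att


def _acceptor_atoms(structure: StructureModel):
    for res in structure.residues:
        names = {a.name: ai for ai, a in _residue_atoms(structure, res)}
        acceptors = []
        if res.res_name in STANDARD_AA:
            acceptors += [n for n in tables.BACKBONE_ACCEPTORS if n in names]
        acceptors += [n for n in tables.SIDECHAIN_ACCEPTORS.get(res.res_name, ())
                      if n in names]
        for name in acceptors:
            yield names[name], res


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b (degrees) of the a-b-c triple."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(receptor: StructureModel, ligand: StructureModel,
                  geometry: InteractionGeometry | None = None) -> list[HBond]:
    """Intermolecular hydrogen bonds (both donor directions)."""
    geometry = geometry or InteractionGeometry()
    out: list[HBond] = []
    seen_pairs: set[frozenset] = set()  # one bond per unordered atom pair
    for donor_side, acceptor_side in ((receptor, ligand), (ligand, receptor)):
        dc = donor_side.coords[0]
        ac = acceptor_side.coords[0]
        acceptors = list(_acceptor_atoms(acceptor_side))
        if not acceptors:
            continue
        acc_tree = cKDTree(ac[[ai for ai, _ in acceptors]])
        for dai, dres, hydrogens in _donor_atoms(donor_side):
            for k in acc_tree.query_ball_point(dc[dai], geometry.hbond_dist_max):
                aai, ares = acceptors[k]
                dist = float(np.linalg.norm(dc[dai] - ac[aai]))
                angle = None
                if hydrogens:
                    angle = max(
                        _angle_deg(dc[dai], dc[hi], ac[aai]) for hi in hydrogens
                    )
                    if angle < geometry.hbond_angle_min:
                        continue
                donor_key = (dres.chain_id, dres.seq_id, dres.res_name)
                acc_key = (ares.chain_id, ares.seq_id, ares.res_name)
                pair_key = frozenset([
                    (donor_key, donor_side.atoms[dai].name),
                    (acc_key, acceptor_side.atoms[aai].name)])
                if pair_key in seen_pairs:
                    continue
                seen_pairs.add(pair_key)
                out.append(HBond(donor_key, acc_key,
                                 donor_side.atoms[dai].name,
                                 acceptor_side.atoms[aai].name, dist, angle))
    return out


def _charged_atoms(structure: StructureModel, geometry: InteractionGeometry):
    pos, neg = [], []
    for res in structure.residues:
        names = {a.name: ai for ai, a in _residue_atoms(structure, res)}
        pnames = tables.POSITIVE_ATOMS.get(res.res_name, ())
        if geometry.his_charged and res.res_name == "HIS":
            pnames = tables.POSITIVE_ATOMS_HIS
        for n in pnames:
            if n in names:
                pos.append((names[n], res))
        for n in tables.NEGATIVE_ATOMS.get(res.res_name, ()):
            if n in names:
                neg.append((names[n], res))
        for n in tables.CTERM_NEGATIVE:
            if n in names:
                neg.append((names[n], res))
    return pos, neg


def detect_ionic(receptor: StructureModel, ligand: StructureModel,
                 geometry: InteractionGeometry | None = None) -> list[SaltBridge]:
    """Intermolecular salt bridges, deduplicated to one per residue pair."""
    geometry = geometry or InteractionGeometry()
    bridges: dict[tuple, float] = {}
    rp, rn = _charged_atoms(receptor, geometry)
    lp, ln = _charged_atoms(ligand, geometry)
    rc, lc = receptor.coords[0], ligand.coords[0]
    for plus, minus, pc, mc in ((rp, ln, rc, lc), (lp, rn, lc, rc)):
        for pai, pres in plus:
            for mai, mres in minus:
                d = float(np.linalg.norm(pc[pai] - mc[mai]))
                if d <= geometry.ionic_dist_max:
                    pkey = (pres.chain_id, pres.seq_id, pres.res_name)
                    mkey = (mres.chain_id, mres.seq_id, mres.res_name)
                    key = (pkey, mkey)
                    bridges[key] = min(bridges.get(key, np.inf), d)
    return [SaltBridge(p, m, d) for (p, m), d in bridges.items()]


def _rings(structure: StructureModel):
    coords = structure.coords[0]
    for res in structure.residues:
        names = {a.name: ai for ai, a in _residue_atoms(structure, res)}
        for ring in tables.AROMATIC_RINGS.get(res.res_name, ()):
            if all(n in names for n in ring):
                pts = coords[[names[n] for n in ring]]
                centroid = pts.mean(axis=0)
                _, _, vt = np.linalg.svd(pts - centroid)
                yield res, centroid, vt[2]


def detect_stacking(receptor: StructureModel, ligand: StructureModel,
                    geometry: InteractionGeometry | None = None
                    ) -> list[StackingContact]:
    """Aromatic ring stacking across the interface (parallel and T bands)."""
    geometry = geometry or InteractionGeometry()
    out = []
    lig_rings = list(_rings(ligand))
    for rres, rcent, rnorm in _rings(receptor):
        for lres, lcent, lnorm in lig_rings:
            d = float(np.linalg.norm(rcent - lcent))
            if d > geometry.stacking_centroid_max:
                continue
            cosang = abs(float(np.dot(rnorm, lnorm)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            if any(lo <= angle <= hi for lo, hi in geometry.stacking_angle_bands):
                out.append(StackingContact(
                    (rres.chain_id, rres.seq_id, rres.res_name),
                    (lres.chain_id, lres.seq_id, lres.res_name), d, angle))
    return out


# ---------------------------------------------------------------------------
# MHP complementarity
# ---------------------------------------------------------------------------

def _mhp_constants(structure: StructureModel) -> np.ndarray:
    out = np.empty(structure.n_atoms)
    for res in structure.residues:
        for ai, atom in _residue_atoms(structure, res):
            out[ai] = tables.mhp_constant(res.res_name, atom.name, atom.element)
    return out


def _field(points: np.ndarray, coords: np.ndarray, consts: np.ndarray,
           lam: float) -> np.ndarray:
    vals = np.zeros(len(points))
    for start in range(0, len(points), 2048):
        chunk = points[start : start + 2048]
        d = np.sqrt(((chunk[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
        vals[start : start + len(chunk)] = (consts * np.exp(-d / lam)).sum(axis=1)
    return vals


def mhp_complementarity(receptor: StructureModel, ligand: StructureModel,
                        geometry: InteractionGeometry | None = None) -> float | None:
    """Fraction of buried surface points where both partners' MHP fields
    share a sign, pooled over both partners' buried surfaces.

    Returns None (with a warning) when the interface buries no surface
    points — the score is undefined for non-touching partners.
    """
    geometry = geometry or InteractionGeometry()
    unit = _sphere_points(geometry.sasa_points)
    n_agree = 0
    n_total = 0
    pair = (receptor.single(), ligand.single())
    complex_model = merge(*pair)
    ccoords = complex_model.coords[0]
    cradii = complex_model.radii()
    cmask = _accessible_masks(ccoords, cradii, geometry.sasa_probe,
                              geometry.sasa_points)
    offsets = (0, receptor.n_atoms)
    consts = (_mhp_constants(receptor), _mhp_constants(ligand))
    for side in (0, 1):
        own = pair[side]
        other = pair[1 - side]
        coords = own.coords[0]
        radii = own.radii()
        alone = _accessible_masks(coords, radii, geometry.sasa_probe,
                                  geometry.sasa_points)
        off = offsets[side]
        incomplex = cmask[off : off + own.n_atoms]
        buried = alone & ~incomplex
        pts = []
        for i in range(own.n_atoms):
            sel = buried[i]
            if sel.any():
                pts.append(coords[i] + (radii[i] + geometry.sasa_probe) * unit[sel])
        if not pts:
            continue
        pts = np.concatenate(pts)
        f_own = _field(pts, coords, consts[side], geometry.mhp_lambda)
        f_other = _field(pts, other.coords[0], consts[1 - side], geometry.mhp_lambda)
        n_agree += int(np.sum(f_own * f_other > 0))
        n_total += len(pts)
    if n_total == 0:
        warnings.warn("no buried surface points; MHP complementarity undefined")
        return None
    return n_agree / n_total


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def describe_interface(receptor: StructureModel, ligand: StructureModel,
                       geometry: InteractionGeometry | None = None
                       ) -> InterfaceDescriptor:
    """All pose descriptors in one pass.

    H-bonds are counted at atom-pair level, ionic bridges at residue-pair
    level (deduplicated), matching the filter conventions documented in
    the methods note.
    """
    geometry = geometry or InteractionGeometry()
    return InterfaceDescriptor(
        bsa=buried_surface_area(receptor, ligand, geometry),
        n_hbonds=len(detect_hbonds(receptor, ligand, geometry)),
        n_ionic=len(detect_ionic(receptor, ligand, geometry)),
        mhp_score=mhp_complementarity(receptor, ligand, geometry),
        n_stacking=len(detect_stacking(receptor, ligand, geometry)),
    )


def enumerate_contacts(receptor: StructureModel, ligand: StructureModel,
                       geometry: InteractionGeometry | None = None,
                       partition: dict[str, str] | None = None,
                       glycan_parents: dict[tuple, int] | None = None
                       ) -> list[ContactRecord]:
    """Typed residue-pair contact list across the interface.

    ``partition`` maps every receptor chain id to its subunit role
    ('+' primary, '-' complementary, or 'other').  Glycan residues
    (MAN/NAG/...) are flagged; ``glycan_parents`` may map
    ``(chain_id, seq_id)`` of a glycan residue to the parent
    glycosylated residue's number.
    """
    geometry = geometry or InteractionGeometry()
    partition = partition or {}
    for cid in {r.chain_id for r in receptor.residues}:
        if cid not in partition:
            raise ValueError(f"receptor chain {cid!r} has no (+)/(-) role assigned")

    grouped: dict[tuple, set] = {}

    def add(lig_key, rec_key, kind):
        grouped.setdefault((lig_key, rec_key), set()).add(kind)

    for hb in detect_hbonds(receptor, ligand, geometry):
        # donor may be on either side; receptor residues have chain in partition
        if hb.donor_res[0] in partition:
            add(hb.acceptor_res, hb.donor_res, "H")
        else:
            add(hb.donor_res, hb.acceptor_res, "H")
    for sb in detect_ionic(receptor, ligand, geometry):
        if sb.positive_res[0] in partition:
            add(sb.negative_res, sb.positive_res, "I")
        else:
            add(sb.positive_res, sb.negative_res, "I")
    for st in detect_stacking(receptor, ligand, geometry):
        add(st.res_b, st.res_a, "S")

    records = []
    for (lig_key, rec_key), kinds in sorted(grouped.items()):
        is_glycan = rec_key[2] in GLYCAN_RESIDUES
        parent = None
        if is_glycan and glycan_parents:
            parent = glycan_parents.get((rec_key[0], rec_key[1]))
        records.append(ContactRecord(
            ligand_residue=lig_key,
            receptor_residue=rec_key,
            receptor_role=partition.get(rec_key[0], "other"),
            kinds=frozenset(kinds),
            partner_is_glycan=is_glycan,
            glycan_parent=parent,
        ))
    return records
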