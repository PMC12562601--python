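"""Coordinate data model for ensembles, poses and trajectory frames.

A :class:`StructureModel` is a light hierarchical container: one shared
topology (chains -> residues -> atoms) plus ``M`` coordinate sets of
identical atom ordering.  Multi-model PDB files (NMR ensembles, docking
poses dumped as MODEL blocks, MD frame dumps) map onto it directly.
Author residue numbering and insertion codes are preserved verbatim —
the receptor and ligand residue numbers used throughout the analysis are
author numbers, never renumbered.

Geometric primitives living here: residue-range selection, Kabsch
superposition, ensemble RMSD (mean-pairwise or to-the-mean) and
per-residue RMSF.  All lengths are in Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .tables import VDW_RADII, vdw_radius


class TopologyError(ValueError):
    """Models of one file disagree in atom count or ordering."""


class SelectionError(ValueError):
    """A residue-range selection matched nothing."""


BACKBONE_ATOMS = ("N", "CA", "C")
BACKBONE_O_ATOMS = ("N", "CA", "C", "O")

_ATOM_FILTERS: dict[str, tuple[str, ...] | None] = {
    "all": None,
    "backbone": BACKBONE_ATOMS,
    "backbone_o": BACKBONE_O_ATOMS,
    "CA": ("CA",),
    "ca": ("CA",),
}


@dataclass(frozen=True)
class Atom:
    """One atom of the shared topology (coordinates live on the model)."""

    name: str
    element: str
    hetero: bool = False

    @property
    def radius(self) -> float:
        return vdw_radius(self.element)


@dataclass(frozen=True)
class Residue:
    """Topology residue: identity plus the atom slice [start, stop)."""

    chain_id: str
    seq_id: int
    icode: str
    res_name: str
    start: int
    stop: int

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def label(self) -> str:
        ic = self.icode.strip()
        return f"{self.chain_id}:{self.res_name}{self.seq_id}{ic}"


@dataclass(frozen=True)
class RegionSpec:
    """Inclusive residue ranges, e.g. the ordered-core segments of a chain.

    ``RegionSpec.from_string("A:1-33,A:41-50,A:63-74")`` parses the CLI
    syntax.  Segments must not overlap within a chain.
    """

    segments: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        per_chain: dict[str, list[tuple[int, int]]] = {}
        for chain, start, end in self.segments:
            if start > end:
                raise ValueError(f"segment {chain}:{start}-{end} has start > end")
            per_chain.setdefault(chain, []).append((start, end))
        for chain, segs in per_chain.items():
            segs = sorted(segs)
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping segments in chain {chain}: "
                        f"{s1}-{e1} and {s2}-{e2}"
                    )

    @classmethod
    def from_string(cls, text: str) -> "RegionSpec":
        segments = []
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            chain, _, rng = part.partition(":")
            if not rng:
                raise ValueError(f"bad region segment {part!r}; expected CHAIN:START-END")
            lo, _, hi = rng.partition("-")
            segments.append((chain, int(lo), int(hi or lo)))
        return cls(tuple(segments))

    def contains(self, chain_id: str, seq_id: int) -> bool:
        return any(
            chain_id == c and s <= seq_id <= e for c, s, e in self.segments
        )


@dataclass
class StructureModel:
    """Shared topology + ``(n_models, n_atoms, 3)`` coordinates."""

    atoms: list[Atom]
    residues: list[Residue]
    coords: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1:] != (len(self.atoms), 3):
            raise TopologyError(
                f"coordinate array {self.coords.shape} does not match "
                f"{len(self.atoms)} topology atoms"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != self.n_models:
                raise ValueError("frame_times length != number of models")
            if np.any(np.diff(self.frame_times) <= 0):
                raise ValueError("frame_times must be strictly increasing")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise TopologyError("duplicate (chain, seq_id, icode) residue keys")

    # -- basic views --------------------------------------------------------

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    def model(self, i: int) -> np.ndarray:
        return self.coords[i]

    def residue_of_atom(self) -> np.ndarray:
        """Residue index for each atom."""
        out = np.empty(self.n_atoms, dtype=int)
        for ri, r in enumerate(self.residues):
            out[r.start : r.stop] = ri
        return out

    def subset_models(self, indices) -> "StructureModel":
        indices = list(indices)
        times = None
        if self.frame_times is not None:
            times = self.frame_times[indices]
        return StructureModel(self.atoms, self.residues, self.coords[indices], times)

    def single(self, i: int = 0) -> "StructureModel":
        return self.subset_models([i])


def merge(a: StructureModel, b: StructureModel) -> StructureModel:
    """Concatenate two single-model structures into one complex."""
    if a.n_models != 1 or b.n_models != 1:
        raise ValueError("merge expects single-model structures")
    offset = a.n_atoms
    residues = list(a.residues) + [
        replace(r, start=r.start + offset, stop=r.stop + offset) for r in b.residues
    ]
    coords = np.concatenate([a.coords, b.coords], axis=1)
    return StructureModel(list(a.atoms) + list(b.atoms), residues, coords)


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def read_structure(path, dialect: str = "pdb") -> StructureModel:
    """Read a (multi-model) PDB file into a StructureModel.

    All MODEL blocks must share one topology (same atoms, same order);
    author numbering and insertion codes are preserved.  Altloc 'A' is
    taken where alternates exist.
    """
    if dialect not in ("pdb", "cif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()
    if len(st) == 0:
        raise TopologyError(f"{path}: no models")

    atoms: list[Atom] = []
    residues: list[Residue] = []
    signature: list[tuple] = []
    first = st[0]
    for chain in first:
        for res in chain:
            start = len(atoms)
            for at in res:
                el = at.element.name
                if el == "X":
                    warnings.warn(
                        f"unknown element for atom {at.name} in {res.name}; "
                        f"using fallback radius"
                    )
                atoms.append(Atom(at.name, el, res.het_flag == "H"))
                signature.append((chain.name, res.seqid.num, res.name, at.name))
            residues.append(
                Residue(
                    chain.name,
                    res.seqid.num,
                    res.seqid.icode.strip(),
                    res.name,
                    start,
                    len(atoms),
                )
            )
    n_atoms = len(atoms)

    coords = np.empty((len(st), n_atoms, 3))
    for mi, model in enumerate(st):
        i = 0
        for chain in model:
            for res in chain:
                for at in res:
                    if i >= n_atoms or signature[i] != (
                        chain.name,
                        res.seqid.num,
                        res.name,
                        at.name,
                    ):
                        raise TopologyError(
                            f"{path}: model {mi + 1} topology differs from model 1"
                        )
                    coords[mi, i] = (at.pos.x, at.pos.y, at.pos.z)
                    i += 1
        if i != n_atoms:
            raise TopologyError(
                f"{path}: model {mi + 1} has {i} atoms, model 1 has {n_atoms}"
            )
    return StructureModel(atoms, residues, coords)


def write_structure(structure: StructureModel, path) -> None:
    """Write as (multi-model) PDB; numbering written verbatim."""
    st = gemmi.Structure()
    st.name = "ifscreen"
    for mi in range(structure.n_models):
        model = gemmi.Model(mi + 1)
        chains: dict[str, gemmi.Chain] = {}
        for res in structure.residues:
            if res.chain_id not in chains:
                chains[res.chain_id] = gemmi.Chain(res.chain_id)
                model.add_chain(chains[res.chain_id])
            chain = model[res.chain_id]
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            gres.het_flag = "H" if (structure.atoms[res.start].hetero) else "A"
            for ai in range(res.start, res.stop):
                atom = structure.atoms[ai]
                gat = gemmi.Atom()
                gat.name = atom.name
                gat.element = gemmi.Element(atom.element)
                x, y, z = structure.coords[mi, ai]
                gat.pos = gemmi.Position(x, y, z)
                gres.add_atom(gat)
            chain.add_residue(gres)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select(
    structure: StructureModel,
    region: RegionSpec | None = None,
    atom_filter: str = "all",
) -> StructureModel:
    """Sub-structure over a residue region and an atom-name filter.

    ``atom_filter`` is one of ``all``, ``backbone`` (N, CA, C),
    ``backbone_o`` (N, CA, C, O) or ``CA``.  Model multiplicity and
    ordering are preserved.  Raises :class:`SelectionError` naming the
    missing segments when nothing matches.
    """
    if atom_filter not in _ATOM_FILTERS:
        raise ValueError(f"unknown atom filter {atom_filter!r}")
    allowed = _ATOM_FILTERS[atom_filter]

    matched_segments: set[tuple] = set()
    new_atoms: list[Atom] = []
    new_residues: list[Residue] = []
    atom_idx: list[int] = []
    for res in structure.residues:
        if region is not None:
            hit = [
                seg
                for seg in region.segments
                if seg[0] == res.chain_id and seg[1] <= res.seq_id <= seg[2]
            ]
            if not hit:
                continue
            matched_segments.update(hit)
        start = len(new_atoms)
        for ai in range(res.start, res.stop):
            atom = structure.atoms[ai]
            if allowed is not None and atom.name not in allowed:
                continue
            new_atoms.append(atom)
            atom_idx.append(ai)
        if len(new_atoms) > start:
            new_residues.append(replace(res, start=start, stop=len(new_atoms)))

    if region is not None:
        missing = [s for s in region.segments if s not in matched_segments]
        if missing:
            desc = ", ".join(f"{c}:{s}-{e}" for c, s, e in missing)
            raise SelectionError(f"region segments matched no residues: {desc}")
    if not new_atoms:
        raise SelectionError("selection is empty")

    coords = structure.coords[:, atom_idx]
    return StructureModel(new_atoms, new_residues, coords, structure.frame_times)


# ---------------------------------------------------------------------------
# Superposition and ensemble statistics
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.
    The rotation is proper (det +1).  Fewer than 3 atoms or a collinear
    point set raises ValueError.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superpose expects two equal (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise ValueError("need at least 3 atoms to superpose")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    sv = np.linalg.svd(x, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("collinear (rank-deficient) atom set")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    moved = x @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return rot, trans, rmsd


def _aligned_stack(coords: np.ndarray, n_iter: int = 5) -> np.ndarray:
    """Iteratively superpose all models onto their mean."""
    out = coords.copy()
    ref = out[0]
    for _ in range(n_iter):
        for i in range(len(out)):
            rot, trans, _ = superpose(out[i], ref)
            out[i] = out[i] @ rot.T + trans
        ref = out.mean(axis=0)
    return out


def ensemble_rmsd(
    structure: StructureModel,
    region: RegionSpec | None = None,
    mode: str = "mean_pairwise",
    atom_filter: str = "backbone",
) -> float:
    """Ensemble backbone RMSD over a region, in Å.

    ``mean_pairwise``: average of all pairwise superposed RMSDs (each pair
    superposed on the selection itself).  ``to_mean``: models iteratively
    aligned to their mean structure; the average of per-model RMSDs to
    that mean is returned.
    """
    if structure.n_models < 2:
        raise ValueError("ensemble RMSD needs at least 2 models")
    sub = select(structure, region, atom_filter)
    coords = sub.coords
    if mode == "mean_pairwise":
        vals = []
        m = len(coords)
        for i in range(m):
            for j in range(i + 1, m):
                vals.append(superpose(coords[i], coords[j])[2])
        return float(np.mean(vals))
    if mode == "to_mean":
        aligned = _aligned_stack(coords)
        mean = aligned.mean(axis=0)
        per_model = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=1))
        return float(np.mean(per_model))
    raise ValueError(f"unknown mode {mode!r}")


def rmsf(structure: StructureModel, region: RegionSpec | None = None) -> "pd.Series":
    """Per-residue Cα RMSF in Å after iterative alignment to the mean."""
    import pandas as pd

    if structure.n_models < 2:
        raise ValueError("RMSF needs at least 2 models")
    sub = select(structure, region, "CA")
    aligned = _aligned_stack(sub.coords)
    mean = aligned.mean(axis=0)
    vals = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    labels = [r.label for r in sub.residues]
    return pd.Series(vals, index=labels, name="rmsf_A")
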