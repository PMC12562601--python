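"""Seeded synthetic data with planted ground truth for every stage.

The generators stand in for the outputs of a docking engine and an MD
engine: toy two-chain complexes whose interactions are planted by
construction, pose ensembles with planted descriptor values and contact
lists, pseudo-trajectories with planted contact on/off schedules and RMSD
steps, Hill dose-response tables, and threshold-spanning NMR observable
tables.  Everything is deterministic under its seed and returns the truth
alongside the data.

Construction margins: planted interactions sit >= 10% inside the default
detector cutoffs and planted negatives >= 25% outside, so detector-vs-
truth checks are exact, not statistical.  Chains are minimal scaffolds
(interaction atoms plus sparse backbones); no physical realism is
intended — the fixtures exercise logic, not biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import ContactRecord, InterfaceDescriptor
from .pharmfit import DoseResponseDataset, hill_response
from .postscore import (NonSpecificCriteria, Pose, PoseEnsemble,
                        SpecificContactRule)
from .structmodel import Atom, Residue, StructureModel, merge

# layout constants for the toy complexes (Å)
_SLOT = 10.0          # x spacing between planted units
_LIG_Y = 0.0          # ligand backbone row
_REC_Y = 12.0         # receptor backbone row
_HB_DIST = 2.9        # planted H-bond length  (cutoff 3.5, ~17% inside)
_ION_DIST = 3.0       # planted salt-bridge length (cutoff 4.0, 25% inside)
_STACK_DIST = 4.0     # planted ring-centroid distance (cutoff 5.5)
_BSA_DIST = 2.5       # planted carbon-carbon burial distance

_REC_NAMES = {147: "LYS", 186: "ARG", 192: "ASP", 193: "ASP", 170: "ASP",
              171: "ASP", 196: "GLU", 194: "LYS", 208: "LYS"}
_LIG_NAMES = {13: "GLU", 14: "ASP", 32: "ARG", 34: "ARG", 52: "ASP",
              53: "ASP", 68: "ASP", 61: "LYS"}


# ---------------------------------------------------------------------------
# Toy complexes with planted interactions
# ---------------------------------------------------------------------------

@dataclass
class PlantedPair:
    """One planted intermolecular interaction (or burial/MHP unit)."""

    kind: str                   # 'H', 'I', 'S', 'BSA', 'MHP+', 'MHP-'
    lig_seq: int
    rec_seq: int
    lig_name: str = ""
    rec_name: str = ""
    rec_role: str = "+"


@dataclass
class ToyComplex:
    receptor: StructureModel
    ligand: StructureModel
    partition: dict[str, str]
    truth_contacts: list[ContactRecord]
    truth: dict
    #: per planted pair: ligand atom index (in the ligand model) whose
    #: displacement toggles the interaction, with its on/off positions
    toggles: dict[tuple[int, int], tuple[int, np.ndarray, np.ndarray]]

    @property
    def complex(self) -> StructureModel:
        return merge(self.receptor.single(), self.ligand.single())


class _Builder:
    def __init__(self):
        self.atoms: list[Atom] = []
        self.residues: list[Residue] = []
        self.coords: list[np.ndarray] = []

    def add_residue(self, chain, seq, name, atom_list):
        start = len(self.atoms)
        for aname, element, xyz in atom_list:
            self.atoms.append(Atom(aname, element))
            self.coords.append(np.asarray(xyz, dtype=float))
        self.residues.append(Residue(chain, seq, "", name, start, len(self.atoms)))
        return start

    def build(self) -> StructureModel:
        return StructureModel(self.atoms, self.residues,
                              np.asarray(self.coords)[None])


def _backbone(x, y, z=0.0):
    return [("N", "N", (x - 1.2, y, z)), ("CA", "C", (x, y, z)),
            ("C", "C", (x + 1.2, y, z)), ("O", "O", (x + 1.2, y, z + 1.2))]


def _ring(center, radius=1.39):
    """Hexagon in the x-z plane (normal along y)."""
    pts = []
    for k in range(6):
        a = k * math.pi / 3
        pts.append((center[0] + radius * math.cos(a), center[1],
                    center[2] + radius * math.sin(a)))
    return pts


def _cap_pair_area(r1: float, r2: float, probe: float, d: float) -> float:
    """Analytic BSA of two spheres at distance d (sum of both caps), Å²."""
    area = 0.0
    for ra, rb in ((r1, r2), (r2, r1)):
        Ra, Rb = ra + probe, rb + probe
        h = Ra - (d * d + Ra * Ra - Rb * Rb) / (2 * d)
        area += 2 * math.pi * Ra * max(h, 0.0)
    return area


def make_toy_complex(
    hbond_pairs=3,
    ionic_pairs=2,
    stacking_pairs=0,
    bsa_pairs: int = 0,
    target_bsa: float | None = None,
    mhp_agree_pairs: int = 0,
    mhp_disagree_pairs: int = 0,
    pairs: list[PlantedPair] | None = None,
    tail_residues: int = 0,
    seed: int = 0,
) -> ToyComplex:
    """Two-chain toy complex in which every interaction is planted.

    ``hbond_pairs`` / ``ionic_pairs`` / ``stacking_pairs`` may be counts
    (auto-numbered Ser-Ser, Arg-Asp and Tyr-Phe pairs) or be given
    explicitly through ``pairs`` as :class:`PlantedPair` items with real
    residue numbers and roles.  ``target_bsa`` plants enough isolated
    carbon-carbon burial units to reach that buried area analytically.
    ``tail_residues`` appends a non-interface ligand tail (seq 901..)
    used by the trajectory generator for planted RMSD steps.

    Receptor residues with role '+' go to chain P, role '-' to chain M;
    the ligand is chain L.  Returns the structures, the partition, the
    exact truth contact list and per-pair toggle handles.
    """
    rng = np.random.default_rng(seed)
    planted: list[PlantedPair] = list(pairs or [])
    next_seq = 500

    def auto(kind, n, lig_name, rec_name):
        nonlocal next_seq
        for _ in range(n):
            planted.append(PlantedPair(kind, next_seq, next_seq,
                                       lig_name, rec_name))
            next_seq += 1

    if isinstance(hbond_pairs, int):
        auto("H", hbond_pairs, "SER", "SER")
    else:
        planted += list(hbond_pairs)
    if isinstance(ionic_pairs, int):
        auto("I", ionic_pairs, "ARG", "ASP")
    else:
        planted += list(ionic_pairs)
    if isinstance(stacking_pairs, int):
        auto("S", stacking_pairs, "TYR", "PHE")
    else:
        planted += list(stacking_pairs)

    n_bsa = bsa_pairs
    pair_area = _cap_pair_area(1.70, 1.70, 1.4, _BSA_DIST)
    if target_bsa is not None:
        n_bsa = max(n_bsa, int(round(target_bsa / pair_area)))
    for _ in range(n_bsa):
        planted.append(PlantedPair("BSA", next_seq, next_seq, "HPB", "HPB"))
        next_seq += 1
    for _ in range(mhp_agree_pairs):
        planted.append(PlantedPair("MHP+", next_seq, next_seq, "HPB", "HPB"))
        next_seq += 1
    for _ in range(mhp_disagree_pairs):
        planted.append(PlantedPair("MHP-", next_seq, next_seq, "HPB", "POL"))
        next_seq += 1

    lig = _Builder()
    recP = _Builder()
    recM = _Builder()
    truth_contacts: list[ContactRecord] = []
    toggles: dict = {}
    counts = {"H": 0, "I": 0, "S": 0}

    for slot, p in enumerate(planted):
        x = slot * _SLOT + float(rng.uniform(-0.03, 0.03))
        rec = recP if p.rec_role == "+" else recM
        rec_chain = "P" if p.rec_role == "+" else "M"
        lig_name = p.lig_name or _LIG_NAMES.get(p.lig_seq, "SER")
        rec_name = p.rec_name or _REC_NAMES.get(p.rec_seq, "ASP")
        kinds = None
        if p.kind == "H":
            gap_mid = (_LIG_Y + _REC_Y) / 2
            on = np.array([x, gap_mid - _HB_DIST / 2, 0.0])
            li = lig.add_residue("L", p.lig_seq, lig_name,
                                 _backbone(x, _LIG_Y) + [("OG", "O", on)])
            rec.add_residue(rec_chain, p.rec_seq, rec_name,
                            _backbone(x, _REC_Y) +
                            [("OG", "O", (x, gap_mid + _HB_DIST / 2, 0.0))])
            kinds = frozenset({"H"})
            counts["H"] += 1
            toggles[(p.lig_seq, p.rec_seq)] = (
                li + 4, on, np.array([x, _LIG_Y + 0.5, 0.0]))
        elif p.kind == "I":
            gap_mid = (_LIG_Y + _REC_Y) / 2
            on = np.array([x, gap_mid - _ION_DIST / 2, 0.0])
            # positive side on the ligand unless the ligand residue is acidic
            lig_positive = lig_name in ("ARG", "LYS")
            lig_atom = ("NH1", "N") if lig_name == "ARG" else \
                       (("NZ", "N") if lig_name == "LYS" else
                        (("OD1", "O") if lig_name == "ASP" else ("OE1", "O")))
            rec_atom = ("OD1", "O") if rec_name == "ASP" else \
                       (("OE1", "O") if rec_name == "GLU" else
                        (("NZ", "N") if rec_name == "LYS" else ("NH1", "N")))
            li = lig.add_residue("L", p.lig_seq, lig_name,
                                 _backbone(x, _LIG_Y) + [(*lig_atom, on)])
            rec.add_residue(rec_chain, p.rec_seq, rec_name,
                            _backbone(x, _REC_Y) +
                            [(*rec_atom, (x, gap_mid + _ION_DIST / 2, 0.0))])
            # a 3 Å N–O salt bridge is also a hydrogen bond by construction
            kinds = frozenset({"I", "H"})
            counts["I"] += 1
            counts["H"] += 1
            toggles[(p.lig_seq, p.rec_seq)] = (
                li + 4, on, np.array([x, _LIG_Y + 0.5, 0.0]))
        elif p.kind == "S":
            gap_mid = (_LIG_Y + _REC_Y) / 2
            lo = gap_mid - _STACK_DIST / 2
            hi = gap_mid + _STACK_DIST / 2
            ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
            lig.add_residue(
                "L", p.lig_seq, lig_name, _backbone(x, _LIG_Y) +
                [(n, "C", pt) for n, pt in
                 zip(ring_names, _ring((x, lo, 0.0)))])
            rec.add_residue(
                rec_chain, p.rec_seq, rec_name, _backbone(x, _REC_Y) +
                [(n, "C", pt) for n, pt in
                 zip(ring_names, _ring((x, hi, 0.0)))])
            kinds = frozenset({"S"})
            counts["S"] += 1
        elif p.kind in ("BSA", "MHP+", "MHP-"):
            gap_mid = (_LIG_Y + _REC_Y) / 2
            lig.add_residue("L", p.lig_seq, p.lig_name,
                            [("C1", "C", (x, gap_mid - _BSA_DIST / 2, 0.0))])
            rec.add_residue(rec_chain, p.rec_seq, p.rec_name,
                            [("C1", "C", (x, gap_mid + _BSA_DIST / 2, 0.0))])
        else:
            raise ValueError(f"unknown planted kind {p.kind!r}")
        if kinds:
            truth_contacts.append(ContactRecord(
                ("L", p.lig_seq, lig_name),
                (rec_chain, p.rec_seq, rec_name),
                p.rec_role, kinds))

    for t in range(tail_residues):
        x = t * _SLOT
        y = -20.0 - 2.0 * (t % 2)
        lig.add_residue("L", 901 + t, "ALA", [("CA", "C", (x, y, 0.0))])

    if not recP.atoms and not recM.atoms:
        raise ValueError("infeasible spec: no receptor residues planted")
    if not lig.atoms:
        raise ValueError("infeasible spec: no ligand residues planted")

    # assemble receptor (chains P and M in one model)
    rb = _Builder()
    for b in (recP, recM):
        for res in b.residues:
            rb.add_residue(res.chain_id, res.seq_id, res.res_name,
                           [(b.atoms[i].name, b.atoms[i].element, b.coords[i])
                            for i in range(res.start, res.stop)])
    receptor = rb.build()
    ligand = lig.build()
    partition = {}
    if recP.atoms:
        partition["P"] = "+"
    if recM.atoms:
        partition["M"] = "-"

    truth = {
        "n_hbond_pairs": counts["H"],
        "n_ionic_pairs": counts["I"],
        "n_stacking_pairs": counts["S"],
        "n_bsa_pairs": n_bsa,
        "bsa_analytic": n_bsa * pair_area,
        "mhp_agree_pairs": mhp_agree_pairs,
        "mhp_disagree_pairs": mhp_disagree_pairs,
    }
    return ToyComplex(receptor, ligand, partition, truth_contacts, truth,
                      toggles)


# ---------------------------------------------------------------------------
# Pose ensembles with planted filter labels
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPoses:
    ensemble: PoseEnsemble
    descriptors: list[InterfaceDescriptor]
    contacts: list[list[ContactRecord]]
    truth: dict


def _contact(rec_seq, role, lig_seq, kinds=("I", "H")) -> ContactRecord:
    chain = "P" if role == "+" else "M"
    return ContactRecord(
        ("L", lig_seq, _LIG_NAMES.get(lig_seq, "SER")),
        (chain, rec_seq, _REC_NAMES.get(rec_seq, "ASP")),
        role, frozenset(kinds))


def make_pose_ensemble(
    n_poses: int = 200,
    n_pass_nonspecific: int = 37,
    n_pass_specific: int = 14,
    rules: tuple[SpecificContactRule, ...] = (),
    criteria: NonSpecificCriteria | None = None,
    n_boundary: int = 0,
    interface_label: str = "custom",
    seed: int = 0,
) -> SyntheticPoses:
    """Pose ensemble whose filter survivors are planted exactly.

    ``n_pass_nonspecific`` poses receive descriptors >= every threshold
    with >= 5% margin (of which ``n_boundary`` sit exactly on the
    thresholds, exercising the inclusive comparisons); the rest fail a
    seeded non-empty subset of criteria by >= 25%.  Among the passing
    poses, ``n_pass_specific`` receive contact lists satisfying every
    rule; the others miss at least one rule.
    """
    if not (0 <= n_pass_specific <= n_pass_nonspecific <= n_poses):
        raise ValueError(
            "need n_pass_specific <= n_pass_nonspecific <= n_poses")
    if n_boundary > n_pass_nonspecific:
        raise ValueError("boundary poses must be passing poses")
    criteria = criteria or NonSpecificCriteria()
    rng = np.random.default_rng(seed)

    order = rng.permutation(n_poses)
    pass_ids = sorted(int(i) for i in order[:n_pass_nonspecific])
    pass_set = set(pass_ids)
    boundary_ids = set(pass_ids[:n_boundary])
    spec_ids = sorted(int(i) for i in
                      rng.permutation(pass_ids)[:n_pass_specific])
    spec_set = set(spec_ids)

    fields = ("bsa", "mhp", "ionic", "hbond")
    tallies = {f: 0 for f in fields}
    descriptors: list[InterfaceDescriptor] = []
    contacts: list[list[ContactRecord]] = []
    poses: list[Pose] = []

    for i in range(n_poses):
        if i in boundary_ids:
            d = InterfaceDescriptor(bsa=criteria.bsa_min,
                                    n_hbonds=criteria.hbond_min,
                                    n_ionic=criteria.ionic_min,
                                    mhp_score=criteria.mhp_min)
        elif i in pass_set:
            d = InterfaceDescriptor(
                bsa=criteria.bsa_min * (1.05 + 0.3 * rng.random()),
                n_hbonds=int(math.ceil(criteria.hbond_min * 1.05))
                + int(rng.integers(0, 5)),
                n_ionic=int(math.ceil(criteria.ionic_min * 1.05))
                + int(rng.integers(0, 4)),
                mhp_score=min(1.0, criteria.mhp_min * 1.05
                              + 0.3 * rng.random()),
            )
        else:
            fail = sorted(rng.choice(4, size=int(rng.integers(1, 5)),
                                     replace=False))
            vals = {
                "bsa": criteria.bsa_min * (1.05 + 0.3 * rng.random()),
                "mhp": min(1.0, criteria.mhp_min * 1.05 + 0.3 * rng.random()),
                "ionic": int(math.ceil(criteria.ionic_min * 1.05))
                + int(rng.integers(0, 4)),
                "hbond": int(math.ceil(criteria.hbond_min * 1.05))
                + int(rng.integers(0, 5)),
            }
            for fi in fail:
                f = fields[fi]
                tallies[f] += 1
                if f == "bsa":
                    vals["bsa"] = criteria.bsa_min * 0.75 * rng.random()
                elif f == "mhp":
                    vals["mhp"] = criteria.mhp_min * 0.75 * rng.random()
                elif f == "ionic":
                    vals["ionic"] = int(rng.integers(
                        0, max(int(criteria.ionic_min * 0.75), 1)))
                else:
                    vals["hbond"] = int(rng.integers(
                        0, max(int(criteria.hbond_min * 0.75), 1)))
            d = InterfaceDescriptor(bsa=vals["bsa"], n_hbonds=vals["hbond"],
                                    n_ionic=vals["ionic"],
                                    mhp_score=vals["mhp"])
        descriptors.append(d)

        # contact list: decoys everywhere, rule contacts where planted
        clist = [_contact(999, "+", 499, kinds=("H",))]
        if rules:
            if i in spec_set:
                for r in rules:
                    rec_seq, role = sorted(r.receptor_residues)[
                        int(rng.integers(0, len(r.receptor_residues)))]
                    lig_seq = sorted(r.ligand_residues)[
                        int(rng.integers(0, len(r.ligand_residues)))]
                    clist.append(_contact(rec_seq, role, lig_seq))
            else:
                drop = int(rng.integers(0, len(rules)))
                for ri, r in enumerate(rules):
                    if ri == drop:
                        continue
                    rec_seq, role = sorted(r.receptor_residues)[0]
                    lig_seq = sorted(r.ligand_residues)[0]
                    clist.append(_contact(rec_seq, role, lig_seq))
        contacts.append(clist)
        poses.append(Pose(i, int(rng.integers(0, 93)),
                          int(rng.integers(0, 53)),
                          float(rng.normal(1000.0, 100.0))))

    ensemble = PoseEnsemble(poses, interface_label)
    truth = {
        "pass_nonspecific": pass_ids,
        "pass_specific": spec_ids,
        "boundary_ids": sorted(boundary_ids),
        "rejection_tallies": tallies,
    }
    return SyntheticPoses(ensemble, descriptors, contacts, truth)


# ---------------------------------------------------------------------------
# Pseudo-trajectories with planted schedules
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTrajectory:
    frames: StructureModel          # merged complex, frame_times set
    partition: dict[str, str]
    ligand_chains: set[str]
    schedules: dict[tuple[int, int], np.ndarray]
    truth: dict


def make_trajectory(
    n_frames: int = 100,
    dt_ns: float = 5.0,
    schedules: dict[tuple[int, int], np.ndarray] | None = None,
    hbond_pairs: int = 1,
    ionic_pairs: int = 1,
    step_frame: int | None = None,
    step_magnitude: float = 3.0,
    seed: int = 0,
) -> SyntheticTrajectory:
    """Pseudo-trajectory with planted per-frame contact schedules.

    ``schedules`` maps (ligand seq, receptor seq) of a planted pair to a
    boolean per-frame presence array; unscheduled pairs stay on in every
    frame.  ``step_frame`` plants an RMSD step of about
    ``step_magnitude`` Å in the ligand tail region (chain L, residues
    901–908) at that frame; the achieved jump is reported in the truth.
    """
    schedules = schedules or {}
    for key, sched in schedules.items():
        if len(sched) != n_frames:
            raise ValueError(f"schedule for {key} has wrong length")
    toy = make_toy_complex(hbond_pairs=hbond_pairs, ionic_pairs=ionic_pairs,
                           tail_residues=8, seed=seed)
    base = toy.complex
    missing = set(schedules) - set(toy.toggles)
    if missing:
        raise ValueError(f"schedules reference unplanted pairs: {missing}")

    lig_offset = toy.receptor.n_atoms  # ligand atoms follow receptor in merge
    tail_idx = [ai for r in base.residues if r.chain_id == "L"
                and r.seq_id >= 901 for ai in range(r.start, r.stop)]

    coords = np.repeat(base.coords, n_frames, axis=0)
    for (lig_seq, rec_seq), sched in schedules.items():
        ai, on_pos, off_pos = toy.toggles[(lig_seq, rec_seq)]
        ai += lig_offset
        for f in range(n_frames):
            coords[f, ai] = on_pos if sched[f] else off_pos

    achieved_jump = 0.0
    if step_frame is not None:
        disp = np.zeros((len(tail_idx), 3))
        disp[:, 2] = step_magnitude * np.where(
            np.arange(len(tail_idx)) % 2 == 0, 1.0, -1.0)
        for f in range(step_frame, n_frames):
            coords[f, tail_idx] += disp
        from .structmodel import superpose

        before = coords[0, tail_idx]
        after = coords[step_frame, tail_idx]
        achieved_jump = superpose(after, before)[2]

    times = dt_ns * np.arange(1, n_frames + 1)
    frames = StructureModel(base.atoms, base.residues, coords, times)
    truth = {
        "schedules": {k: np.asarray(v, dtype=bool)
                      for k, v in schedules.items()},
        "always_on": [k for k in toy.toggles if k not in schedules],
        "step_frame": step_frame,
        "achieved_rmsd_jump": achieved_jump,
        "tail_region": ("L", 901, 908),
        "times_ns": times,
    }
    return SyntheticTrajectory(frames, toy.partition, {"L"}, schedules, truth)


# ---------------------------------------------------------------------------
# Dose-response and NMR tables
# ---------------------------------------------------------------------------

#: the receptor panel parameters used as generator defaults
DEFAULT_HILL_PARAMS = (("HS a4b2", 27.0, 1.4), ("LS a4b2", 15.0, 0.7),
                       ("a3b2", 50.0, 1.2))
DEFAULT_BOTTOM = 31.0
DEFAULT_DOSES = (3.0, 10.0, 30.0, 100.0)   # μM, half-log steps


def make_dose_response(
    params=DEFAULT_HILL_PARAMS,
    bottom: float = DEFAULT_BOTTOM,
    top: float = 100.0,
    doses=DEFAULT_DOSES,
    n_replicates: int = 6,
    sigma: float = 5.0,
    seed: int = 0,
) -> tuple[list[DoseResponseDataset], dict]:
    """Hill-model datasets with Gaussian noise (σ in response percent)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    datasets = []
    for label, ic50, nh in params:
        d = np.tile(np.asarray(doses, dtype=float), n_replicates)
        reps = np.repeat(np.arange(n_replicates), len(doses))
        clean = hill_response(d, ic50, nh, bottom, top)
        noisy = clean + rng.normal(0.0, sigma, size=len(d)) if sigma > 0 \
            else clean
        datasets.append(DoseResponseDataset(label, d, noisy, reps))
    truth = {"params": {label: {"ic50": ic50, "nh": nh}
                        for label, ic50, nh in params},
             "bottom": bottom, "top": top, "sigma": sigma}
    return datasets, truth


def make_nmr_table(seed: int = 0, n_filler: int = 6
                   ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Threshold-spanning relaxation and exchange tables with truth counts.

    The deterministic core places records exactly on and on both sides of
    every classification boundary; ``n_filler`` seeded unambiguous
    records (margins >= 25% from every threshold) are appended.
    """
    rng = np.random.default_rng(seed)
    # (s2, rex, r1, r2, hnco_ratio) -> expected (fast, slow)
    core = [
        (0.79, 0.5, 1.0, 5.0, 1.0, True, False),
        (0.80, 0.5, 1.0, 5.0, 1.0, False, False),
        (0.95, 0.5, 1.0, 5.0, 1.0, False, False),
        (0.95, 3.1, 1.0, 5.0, 1.0, False, True),
        (0.95, 3.0, 1.0, 5.0, 1.0, False, False),
        (0.95, 0.5, 2.0, 9.0, 1.0, False, True),    # product 18 > 16
        (0.95, 0.5, 4.0, 4.0, 1.0, False, False),   # product 16, boundary
        (0.95, 0.5, 1.0, 5.0, 0.19, False, True),   # broadened
        (0.95, 0.5, 1.0, 5.0, 0.20, False, False),  # boundary ratio
        (0.95, 0.5, 1.0, 5.0, 0.0, False, True),    # invisible peak
        (0.50, 5.0, 3.0, 9.0, 0.1, True, True),
    ]
    rows = []
    n_fast = n_slow = 0
    for i, (s2, rex, r1, r2, ratio, fast, slow) in enumerate(core):
        rows.append({"residue": i + 1, "s2": s2, "rex": rex, "r1": r1,
                     "r2": r2, "het_noe": 0.8, "hnco_ratio": ratio})
        n_fast += fast
        n_slow += slow
    for j in range(n_filler):
        flagged = bool(rng.integers(0, 2))
        s2 = float(rng.uniform(0.3, 0.6)) if flagged else \
            float(rng.uniform(0.85, 1.0))
        rex = float(rng.uniform(4.0, 8.0)) if flagged else \
            float(rng.uniform(0.0, 2.0))
        rows.append({"residue": 100 + j, "s2": s2, "rex": rex, "r1": 1.0,
                     "r2": 5.0, "het_noe": 0.8, "hnco_ratio": 1.0})
        n_fast += flagged
        n_slow += flagged
    relax = pd.DataFrame(rows)

    # (dHN_dT ppb/K, t_half min) -> expected donor flag
    ex_core = [
        (-3.0, 60.0, True),
        (-6.0, 60.0, False),
        (-4.5, 21.0, False),   # gradient exactly on the (strict) boundary
        (-3.0, 20.0, False),   # half-exchange exactly on the boundary
        (-4.4, 20.5, True),
        (-4.6, 19.0, False),
    ]
    ex_rows = [{"residue": i + 1, "dHN_dT": g, "t_half_min": t}
               for i, (g, t, _) in enumerate(ex_core)]
    exchange = pd.DataFrame(ex_rows)
    truth = {
        "n_fast_mobility": int(n_fast),
        "n_slow_exchange": int(n_slow),
        "n_hbond_donor": sum(d for *_, d in ex_core),
    }
    return relax, exchange, truth
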