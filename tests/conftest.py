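"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ifscreen.structmodel import Atom, Residue, StructureModel


def build_chain(n_res: int, chain_id: str = "A", seed: int = 0,
                atoms=("N", "CA", "C")) -> StructureModel:
    """Non-degenerate single-model chain with the given backbone atoms."""
    rng = np.random.default_rng(seed)
    alist, rlist, coords = [], [], []
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    for i in range(n_res):
        start = len(alist)
        base = np.array([3.8 * i, 2.0 * np.sin(i), 1.5 * np.cos(0.7 * i)])
        for j, name in enumerate(atoms):
            alist.append(Atom(name, elements.get(name, "C")))
            coords.append(base + 0.8 * rng.standard_normal(3) * 0.1
                          + np.array([1.2 * j, 0.0, 0.0]))
        rlist.append(Residue(chain_id, i + 1, "", "ALA", start, len(alist)))
    return StructureModel(alist, rlist, np.asarray(coords)[None])


def build_ensemble(n_models: int, n_res: int, sigma: float, seed: int = 0,
                   atoms=("N", "CA", "C")) -> StructureModel:
    """Ensemble: one base chain plus iid Gaussian jitter per model."""
    base = build_chain(n_res, seed=seed, atoms=atoms)
    rng = np.random.default_rng(seed + 1)
    coords = np.repeat(base.coords, n_models, axis=0)
    coords += sigma * rng.standard_normal(coords.shape)
    return StructureModel(base.atoms, base.residues, coords)


def random_rigid_motion(seed: int):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-20, 20, 3)
    return rot, trans


def scipy_pair_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent superposed-RMSD via scipy's align_vectors."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(bc, ac)
    moved = rot.apply(ac)
    return float(np.sqrt(np.mean(np.sum((moved - bc) ** 2, axis=1))))


def brute_force_gromos(matrix: np.ndarray, cutoff: float):
    """Plain-set re-derivation of the neighbor-count recursion."""
    n = len(matrix)
    remaining = set(range(n))
    clusters = []
    while remaining:
        best, best_nb = None, None
        for i in sorted(remaining):
            nb = {j for j in remaining if matrix[i, j] <= cutoff}
            if best_nb is None or len(nb) > len(best_nb):
                best, best_nb = i, nb
        clusters.append((best, sorted(best_nb)))
        remaining -= best_nb
    clusters.sort(key=lambda c: -len(c[1]))
    return clusters


def grid_sasa(coords: np.ndarray, radii: np.ndarray, probe: float,
              n_samples: int = 10000, seed: int = 0) -> np.ndarray:
    """Dense random-direction numeric SASA oracle (per atom, Å²)."""
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_samples, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    ext = radii + probe
    out = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * dirs
        free = np.ones(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.sum((pts - coords[j]) ** 2, axis=1) >= ext[j] ** 2
        out[i] = 4 * np.pi * ext[i] ** 2 * free.mean()
    return out


@pytest.fixture
def toy_hb_ionic():
    from ifscreen import synthgen

    return synthgen.make_toy_complex(hbond_pairs=3, ionic_pairs=2, seed=11)
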