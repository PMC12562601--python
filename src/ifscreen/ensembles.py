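"""Conformational-ensemble RMSD matrices and gromos (Daura) clustering.

Representative conformers of an MD-derived ensemble feed ensemble docking:
each ligand representative is docked against each receptor-site
representative.  Clustering follows the neighbor-count algorithm of Daura
et al.: the conformer with the most neighbors within the RMSD cutoff
becomes a cluster representative, it and its neighbors are removed, and
the step repeats until no conformers remain.

The cutoffs used in the original screening (0.250 nm for the ligand
ensemble; 0.140 / 0.150 / 0.172 nm for the three receptor-interface
ensembles) are shipped as presets in Å under :data:`PRESET_CUTOFFS_A`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structmodel import RegionSpec, StructureModel, select, superpose

#: clustering cutoffs used in the original study, converted nm -> Å
PRESET_CUTOFFS_A: dict[str, float] = {
    "ligand": 2.50,
    "b2p_b2m": 1.40,
    "a4p_b2m": 1.50,
    "b2p_a4m": 1.72,
}

#: cluster counts reported for those ensembles (narrative reference only;
#: they require the original trajectories to reproduce)
PRESET_CLUSTER_COUNTS: dict[str, int] = {
    "ligand": 93,
    "b2p_b2m": 53,
    "a4p_b2m": 54,
    "b2p_a4m": 57,
}


@dataclass
class ClusterConfig:
    cutoff: float                     # Å
    selection: RegionSpec | None = None
    atom_filter: str = "backbone"
    exclusions: RegionSpec | None = None

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ClusterResult:
    """Ordered clusters: (representative index, member indices)."""

    clusters: list[tuple[int, list[int]]]
    config: ClusterConfig | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        return [len(m) for _, m in self.clusters]

    def membership(self) -> dict[int, int]:
        out = {}
        for ci, (_, members) in enumerate(self.clusters):
            for m in members:
                out[m] = ci
        return out


def _apply_selection(structure: StructureModel, config: ClusterConfig
                     ) -> StructureModel:
    sub = select(structure, config.selection, config.atom_filter)
    if config.exclusions is None:
        return sub
    keep_res = [
        r for r in sub.residues
        if not config.exclusions.contains(r.chain_id, r.seq_id)
    ]
    if not keep_res:
        raise ValueError("selection empty after exclusions")
    idx = [ai for r in keep_res for ai in range(r.start, r.stop)]
    from dataclasses import replace

    new_res = []
    pos = 0
    for r in keep_res:
        n = r.stop - r.start
        new_res.append(replace(r, start=pos, stop=pos + n))
        pos += n
    return StructureModel(
        [sub.atoms[i] for i in idx], new_res, sub.coords[:, idx], sub.frame_times
    )


def rmsd_matrix(structure: StructureModel, config: ClusterConfig) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs over the selection, Å."""
    if structure.n_models < 2:
        raise ValueError("need at least 2 models")
    sub = _apply_selection(structure, config)
    n = sub.n_models
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = superpose(sub.coords[i], sub.coords[j])[2]
    return mat


def gromos_cluster(matrix: np.ndarray, cutoff: float,
                   config: ClusterConfig | None = None) -> ClusterResult:
    """Daura neighbor-count clustering of a pairwise RMSD matrix.

    The neighbor relation is inclusive (distance <= cutoff); ties in
    neighbor count are broken toward the lowest structure index, making
    the partition deterministic.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if np.isnan(matrix).any():
        raise ValueError("NaN entries in RMSD matrix")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("matrix must be symmetric")
    n = len(matrix)
    adjacency = matrix <= cutoff
    np.fill_diagonal(adjacency, True)

    remaining = list(range(n))
    clusters: list[tuple[int, list[int]]] = []
    while remaining:
        counts = [int(adjacency[i, remaining].sum()) for i in remaining]
        best = int(np.argmax(counts))  # argmax returns the first (lowest-index) tie
        rep = remaining[best]
        members = [j for j in remaining if adjacency[rep, j]]
        clusters.append((rep, members))
        remaining = [j for j in remaining if j not in members]

    # stable sort by descending size keeps discovery order within equal sizes
    clusters = sorted(clusters, key=lambda c: -len(c[1]))
    return ClusterResult(clusters, config)


def representatives(result: ClusterResult, structure: StructureModel
                    ) -> StructureModel:
    """Multi-model structure of cluster representatives, in cluster order."""
    idx = [rep for rep, _ in result.clusters]
    if any(i < 0 or i >= structure.n_models for i in idx):
        raise ValueError("representative index out of range")
    sub = structure.subset_models(idx)
    sub.frame_times = None
    return sub
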