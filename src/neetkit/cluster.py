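"""GROMOS-style conformational clustering of trajectory snapshots.

The greedy neighbor-count algorithm: under a pairwise backbone-RMSD
cutoff (0.11 nm in the NEET MD analysis), repeatedly take the frame with
the most neighbors, form a cluster of it plus its neighbors, remove them,
and continue until no frames remain.  The seed frame of each cluster is
its representative conformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sites import superpose_rmsd

__all__ = [
    "ConformationSet",
    "ClusteringResult",
    "pairwise_rmsd",
    "gromos_cluster",
    "representatives",
    "read_multimodel_pdb",
]

BACKBONE_NAMES = ("N", "CA", "C")


@dataclass
class ConformationSet:
    """M frames of N selected atoms, coordinates in nm."""

    coords: np.ndarray           # (M, N, 3), nm
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (M, N, 3)")
        if not self.labels:
            self.labels = list(range(self.coords.shape[0]))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class ClusteringResult:
    """Frame clusters (each a list of frame indices, seed first) plus the
    cutoff used.  Clusters partition all frames; the representative of a
    cluster is its seed frame."""

    clusters: list[list[int]]
    representatives_idx: list[int]
    cutoff: float

    def membership(self) -> np.ndarray:
        m = {}
        for c, members in enumerate(self.clusters):
            for f in members:
                m[f] = c
        return np.array([m[f] for f in sorted(m)])


def read_multimodel_pdb(path, selection: str = "backbone") -> ConformationSet:
    """Read a multi-model PDB trajectory; coordinates converted to nm.

    ``selection``: "backbone" keeps N/CA/C, "all" keeps every atom.
    """
    from .sites import load_structure
    structure = load_structure(path, "traj")
    frames = []
    for model in structure.get_models():
        xyz = []
        for chain in model:
            for res in chain:
                for atom in res:
                    if selection == "backbone" and \
                            atom.get_name() not in BACKBONE_NAMES:
                        continue
                    xyz.append(atom.coord)
        frames.append(np.array(xyz, dtype=float) / 10.0)
    if len({f.shape for f in frames}) > 1:
        raise ValueError("frames differ in atom count")
    return ConformationSet(coords=np.stack(frames))


def pairwise_rmsd(conf: ConformationSet) -> np.ndarray:
    """Symmetric matrix of Kabsch-minimized RMSDs between all frames (nm)."""
    M = conf.n_frames
    if M < 2:
        raise ValueError("need at least 2 frames")
    if conf.coords.shape[1] < 3:
        raise ValueError("frames need at least 3 atoms")
    D = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            r, _, _ = superpose_rmsd(conf.coords[i], conf.coords[j])
            D[i, j] = D[j, i] = r
    return D


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> ClusteringResult:
    """Greedy neighbor-count clustering of a distance matrix.

    Neighbors are frames at distance <= cutoff (non-strict; boundary
    frames are rare in float data).  Ties in neighbor count go to the
    lowest frame index, for determinism.  Singletons form their own
    clusters.
    """
    D = np.asarray(matrix, float)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    M = D.shape[0]
    if D.shape != (M, M):
        raise ValueError("distance matrix must be square")
    alive = np.ones(M, bool)
    clusters, reps = [], []
    while alive.any():
        idx = np.flatnonzero(alive)
        neigh = (D[np.ix_(idx, idx)] <= cutoff).sum(axis=1)
        seed_pos = int(np.argmax(neigh))     # first max -> lowest index
        seed = int(idx[seed_pos])
        members = [seed] + [int(f) for f in idx
                            if f != seed and D[seed, f] <= cutoff]
        clusters.append(members)
        reps.append(seed)
        alive[members] = False
    return ClusteringResult(clusters=clusters, representatives_idx=reps,
                            cutoff=float(cutoff))


def representatives(result: ClusteringResult, conf: ConformationSet):
    """Representative coordinates ordered by cluster size (occupancy).

    Returns a list of dicts with frame index, coordinates, cluster size
    and occupancy fraction (summing to 1 over all clusters).
    """
    M = conf.n_frames
    order = sorted(range(len(result.clusters)),
                   key=lambda c: (-len(result.clusters[c]),
                                  result.representatives_idx[c]))
    out = []
    for c in order:
        rep = result.representatives_idx[c]
        out.append({"frame": rep, "coords": conf.coords[rep],
                    "cluster_size": len(result.clusters[c]),
                    "occupancy": len(result.clusters[c]) / M})
    return out
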