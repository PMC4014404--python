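"""Radius-cutoff k-means clustering of conformational ensembles.

Conformations sampled at a fixed temperature near the folding transition
are partitioned into structural states by adaptive k-means on the pairwise
C-alpha RMSD (each distance evaluated after optimal superposition): any
conformation farther than the radius cutoff from every current centroid
seeds a new cluster, then assignments and centroids are iterated to a
fixed point.  The representative of a cluster is the member closest to its
centroid.  A 9 A cutoff separates native from intermediate basins on
trajectories that sample both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import kabsch_rmsd, sasa_per_residue, superpose
from .structure_io import ProteinStructure

__all__ = [
    "ConformationCluster",
    "cluster_conformations",
    "representative",
    "ensemble_sasa_profile",
]


@dataclass
class ConformationCluster:
    """One structural state: members, centroid and representative."""

    members: list[int]
    centroid: np.ndarray  # (n_fit_atoms, 3)
    representative: int
    radius: float  # max member-to-centroid RMSD, A

    def __len__(self) -> int:
        return len(self.members)


def _mean_after_superposition(
    confs: np.ndarray, member_idx: list[int], ref_idx: int, n_passes: int = 2
) -> np.ndarray:
    """Coordinate mean after superposing members onto a reference frame.

    The reference starts as one member and is replaced by the running mean
    for ``n_passes`` refinements, avoiding frame artifacts of a single
    arbitrary member.
    """
    ref = confs[ref_idx]
    for _ in range(n_passes):
        acc = np.zeros_like(ref)
        for m in member_idx:
            sp = superpose(confs[m], ref)
            acc += sp.apply(confs[m])
        ref = acc / len(member_idx)
    return ref


def cluster_conformations(
    ensemble: np.ndarray | list[np.ndarray],
    radius_cutoff: float,
    atom_filter: np.ndarray | None = None,
    seed: int = 0,
    max_iter: int = 100,
) -> list[ConformationCluster]:
    """Adaptive k-means with a cluster radius cutoff.

    *ensemble* is an (M, N, 3) stack (or list) of conformations;
    *atom_filter* selects the atoms used for the RMSD metric (typically the
    C-alpha indices; all atoms when None).  Deterministic given the input
    order; *seed* is accepted for API symmetry with the other samplers but
    the algorithm draws no random numbers.
    """
    confs = np.asarray(ensemble, float)
    if confs.ndim != 3 or len(confs) == 0:
        raise ValueError("ensemble must be a non-empty (M, N, 3) stack")
    if radius_cutoff <= 0:
        raise ValueError("radius cutoff must be positive")
    if atom_filter is not None:
        confs = confs[:, np.asarray(atom_filter, int), :]
    M = len(confs)

    # pass 1: greedy seeding in input order
    centroids: list[np.ndarray] = [confs[0]]
    seeds = [0]
    assign = np.zeros(M, dtype=int)
    for m in range(1, M):
        d = [kabsch_rmsd(confs[m], c) for c in centroids]
        k = int(np.argmin(d))
        if d[k] > radius_cutoff:
            centroids.append(confs[m])
            seeds.append(m)
            assign[m] = len(centroids) - 1
        else:
            assign[m] = k

    for _ in range(max_iter):
        # centroid update: mean after superposition onto current frame
        new_centroids = []
        for k in range(len(centroids)):
            members = [m for m in range(M) if assign[m] == k]
            if not members:
                continue
            d_to_c = [kabsch_rmsd(confs[m], centroids[k]) for m in members]
            rep_local = members[int(np.argmin(d_to_c))]
            new_centroids.append(
                _mean_after_superposition(confs, members, rep_local)
            )
        centroids = new_centroids
        # reassignment, seeding new clusters beyond the cutoff
        new_assign = np.zeros(M, dtype=int)
        grew = False
        for m in range(M):
            d = [kabsch_rmsd(confs[m], c) for c in centroids]
            k = int(np.argmin(d))
            if d[k] > radius_cutoff:
                centroids.append(confs[m])
                new_assign[m] = len(centroids) - 1
                grew = True
            else:
                new_assign[m] = k
        if not grew and np.array_equal(new_assign, assign):
            break
        assign = new_assign

    clusters = []
    for k in range(len(centroids)):
        members = [m for m in range(M) if assign[m] == k]
        if not members:
            continue
        d = [kabsch_rmsd(confs[m], centroids[k]) for m in members]
        rep = members[int(np.argmin(d))]
        clusters.append(
            ConformationCluster(
                members=members,
                centroid=centroids[k],
                representative=rep,
                radius=float(max(d)),
            )
        )
    clusters.sort(key=lambda c: -len(c.members))
    return clusters


def representative(
    cluster: ConformationCluster,
    ensemble: np.ndarray,
    atom_filter: np.ndarray | None = None,
) -> int:
    """Index of the member closest to the cluster centroid (ties: lowest)."""
    if not cluster.members:
        raise ValueError("empty cluster")
    confs = np.asarray(ensemble, float)
    if atom_filter is not None:
        confs = confs[:, np.asarray(atom_filter, int), :]
    d = np.array(
        [kabsch_rmsd(confs[m], cluster.centroid) for m in cluster.members]
    )
    return cluster.members[int(np.argmin(d))]


def ensemble_sasa_profile(
    member_coords: np.ndarray,
    native: ProteinStructure,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    flag_threshold: float = 1.5,
) -> dict[int, tuple[float, float, float, bool]]:
    """Per-residue ensemble SASA versus the native structure.

    Returns ``{residue: (mean_sasa, native_sasa, fold_change, flagged)}``
    where ``flagged`` marks residues whose solvent exposure grows by at
    least *flag_threshold*-fold over native -- candidate aggregation-prone
    exposures.
    """
    member_coords = np.asarray(member_coords, float)
    if member_coords.ndim != 3 or member_coords.shape[1] != len(native):
        raise ValueError("member coordinates incompatible with the structure")
    native_sasa = sasa_per_residue(native, probe=probe,
                                   n_sphere_points=n_sphere_points)
    acc = {r: 0.0 for r in native_sasa}
    for coords in member_coords:
        s = sasa_per_residue(native, coords, probe, n_sphere_points)
        for r, v in s.items():
            acc[r] += v
    out = {}
    for r in sorted(acc):
        mean = acc[r] / len(member_coords)
        nat = native_sasa[r]
        fold = mean / nat if nat > 0 else float("inf") if mean > 0 else 1.0
        out[r] = (mean, nat, fold, fold >= flag_threshold)
    return out
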