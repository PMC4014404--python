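"""Native-centric square-well (Go) energy model.

Every heavy atom is a hard sphere.  A pair of atoms in residues separated by
more than two units of backbone distance interacts through a square well:
hard core at ``sigma = alpha * (r0i + r0j)`` (r0 the united-atom vdW radii),
attractive well of depth ``-1 eps`` extending to ``lambda * sigma`` for pairs
that are in contact in the native conformation, and a pure hard core for all
other such pairs.  Local pairs (same or adjacent residues) are governed by
the bond network instead: covalent bonds and 1-3 pseudobonds are held in
narrow infinite square wells around their native distances.

With the shipped radius table and the default parameters alpha = 0.80,
lambda = 1.6 a methyl-methyl pair attracts out to 4.71 A.  Disulfide bridges
(e.g. Cys25-Cys80 of beta-2 microglobulin) are treated through their native
contacts like any other pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ProteinStructure, RegionSpec

__all__ = [
    "ContactPair",
    "GoModel",
    "pair_params",
    "build_native_contact_map",
    "build_bond_network",
    "potential_energy",
    "fraction_native",
    "region_contact_counts",
    "HardCoreViolation",
]

#: Default exclusion: Eq-style pairs require |res_i - res_j| >= 3.
MIN_BACKBONE_SEP = 3

#: Relative half-width of bond square wells: [d0*(1-delta), d0*(1+delta)].
BOND_DELTA = 0.02

#: Covalent-bond detection cutoff (A) for inferring the bond graph from
#: native geometry; disulfide S-S bonds are slightly longer.
_COVALENT_CUTOFF = 1.9
_SS_CUTOFF = 2.3


class HardCoreViolation(Exception):
    """A pair of interacting atoms sits inside its hard core."""


def pair_params(
    r0i: float, r0j: float, alpha: float, lam: float
) -> tuple[float, float]:
    """Hard-core distance and well edge for a pair of atoms.

    ``sigma = alpha*(r0i + r0j)``, ``well_edge = lambda*sigma``.  ``lam``
    must exceed 1 so the well has nonzero width.
    """
    if r0i <= 0 or r0j <= 0 or alpha <= 0 or lam <= 0:
        raise ValueError("pair_params requires positive inputs")
    if alpha >= 1:
        raise ValueError("alpha must be < 1 (hard core inside vdW contact)")
    if lam <= 1:
        raise ValueError("lambda must be > 1 (sigma < well_edge required)")
    sigma = alpha * (r0i + r0j)
    return sigma, lam * sigma


@dataclass(frozen=True)
class ContactPair:
    """A native contact: atom indices with its square-well geometry."""

    atom_i: int
    atom_j: int
    sigma: float
    well_edge: float
    delta: int = -1  # well depth indicator, -1 eps for native pairs

    def __post_init__(self):
        if not self.sigma < self.well_edge:
            raise ValueError("sigma must be smaller than well_edge")


@dataclass
class GoModel:
    """Square-well Go model bound to a native structure."""

    structure: ProteinStructure
    alpha: float
    lam: float
    pair_i: np.ndarray  # (C,) atom indices of native contacts
    pair_j: np.ndarray
    sigma: np.ndarray  # (C,) hard-core distances of native contacts
    well_edge: np.ndarray  # (C,)
    bond_i: np.ndarray  # (B,) constrained pairs (1-2 covalent and 1-3)
    bond_j: np.ndarray
    bond_min: np.ndarray
    bond_max: np.ndarray
    epsilon: float = 1.0

    @property
    def n_contacts(self) -> int:
        return len(self.pair_i)

    @property
    def native_contacts(self) -> list[ContactPair]:
        return [
            ContactPair(int(i), int(j), float(s), float(w))
            for i, j, s, w in zip(
                self.pair_i, self.pair_j, self.sigma, self.well_edge
            )
        ]

    @property
    def radii(self) -> np.ndarray:
        return self.structure.radii

    def contact_residue_pairs(self) -> list[tuple[int, int]]:
        """Residue-number pairs of the native contacts (with multiplicity)."""
        res = self.structure.residue_numbers
        return [
            (int(res[i]), int(res[j]))
            for i, j in zip(self.pair_i, self.pair_j)
        ]


def build_bond_network(
    structure: ProteinStructure,
    explicit_bonds: Sequence[tuple[int, int]] | None = None,
    delta: float = BOND_DELTA,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Covalent 1-2 bonds plus 1-3 pseudobonds as narrow distance wells.

    Bonds are taken from *explicit_bonds* (atom index pairs) when given,
    otherwise inferred from native geometry by a covalent distance cutoff
    (1.9 A; 2.3 A for S-S).  Every bonded pair and every pair of atoms
    sharing a bonded neighbour is constrained to
    ``[d0*(1-delta), d0*(1+delta)]`` around its native distance d0.
    """
    coords = structure.coords
    n = len(coords)
    if explicit_bonds is not None:
        bonds = {tuple(sorted(map(int, b))) for b in explicit_bonds}
    else:
        tree = cKDTree(coords)
        bonds = set()
        for i, j in tree.query_pairs(_SS_CUTOFF):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            is_ss = (
                structure.atoms[i].element == "S"
                and structure.atoms[j].element == "S"
            )
            if d <= _COVALENT_CUTOFF or (is_ss and d <= _SS_CUTOFF):
                bonds.add((min(i, j), max(i, j)))
    neighbours: list[set[int]] = [set() for _ in range(n)]
    for i, j in bonds:
        neighbours[i].add(j)
        neighbours[j].add(i)
    pseudo = set()
    for k in range(n):
        nb = sorted(neighbours[k])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                pair = (nb[a], nb[b])
                if pair not in bonds:
                    pseudo.add(pair)
    all_pairs = sorted(bonds | pseudo)
    bi = np.array([p[0] for p in all_pairs], dtype=np.int64)
    bj = np.array([p[1] for p in all_pairs], dtype=np.int64)
    d0 = np.linalg.norm(coords[bi] - coords[bj], axis=1) if len(bi) else np.zeros(0)
    return bi, bj, d0 * (1 - delta), d0 * (1 + delta)


def build_native_contact_map(
    structure: ProteinStructure,
    alpha: float = 0.80,
    lam: float = 1.6,
    min_backbone_sep: int = MIN_BACKBONE_SEP,
    explicit_bonds: Sequence[tuple[int, int]] | None = None,
) -> GoModel:
    """Build the Go model: native contacts, pair geometry, bond network.

    A native contact is an unordered heavy-atom pair whose residues are
    separated by at least *min_backbone_sep* along the chain and whose
    native distance lies in ``(sigma, well_edge]``.
    """
    if not structure.has_radii:
        raise ValueError("radii must be assigned before building the model")
    if explicit_bonds is None:
        explicit_bonds = structure.bonds
    coords = structure.coords
    radii = structure.radii
    res = structure.residue_numbers
    max_cut = lam * alpha * 2 * radii.max()
    tree = cKDTree(coords)
    cand = tree.query_pairs(max_cut, output_type="ndarray")
    if len(cand):
        i, j = cand[:, 0], cand[:, 1]
        sep_ok = np.abs(res[i] - res[j]) >= min_backbone_sep
        i, j = i[sep_ok], j[sep_ok]
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        sigma = alpha * (radii[i] + radii[j])
        edge = lam * sigma
        clash = d <= sigma
        if clash.any():
            bad = [(int(a), int(b)) for a, b in zip(i[clash], j[clash])]
            raise HardCoreViolation(
                f"native structure has {clash.sum()} pair(s) inside the hard "
                f"core, e.g. atoms {bad[:5]}"
            )
        in_well = d <= edge
        i, j, sigma, edge = i[in_well], j[in_well], sigma[in_well], edge[in_well]
        order = np.lexsort((j, i))
        i, j, sigma, edge = i[order], j[order], sigma[order], edge[order]
    else:  # pragma: no cover - degenerate tiny input
        i = j = np.zeros(0, dtype=np.int64)
        sigma = edge = np.zeros(0)
    bi, bj, bmin, bmax = build_bond_network(structure, explicit_bonds)
    return GoModel(
        structure=structure,
        alpha=alpha,
        lam=lam,
        pair_i=i.astype(np.int64),
        pair_j=j.astype(np.int64),
        sigma=sigma,
        well_edge=edge,
        bond_i=bi,
        bond_j=bj,
        bond_min=bmin,
        bond_max=bmax,
    )


def _native_pair_distances(model: GoModel, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(model.structure), 3):
        raise ValueError(
            f"coordinate shape {coords.shape} incompatible with model of "
            f"{len(model.structure)} atoms"
        )
    return np.linalg.norm(coords[model.pair_i] - coords[model.pair_j], axis=1)


def _any_hard_core_overlap(model: GoModel, coords: np.ndarray) -> bool:
    """Check every interacting pair (backbone sep >= 3) against its core."""
    radii = model.radii
    res = model.structure.residue_numbers
    tree = cKDTree(coords)
    cand = tree.query_pairs(model.alpha * 2 * radii.max(), output_type="ndarray")
    if not len(cand):
        return False
    i, j = cand[:, 0], cand[:, 1]
    keep = np.abs(res[i] - res[j]) >= MIN_BACKBONE_SEP
    i, j = i[keep], j[keep]
    if not len(i):
        return False
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    return bool((d < model.alpha * (radii[i] + radii[j])).any())


def potential_energy(
    model: GoModel, coords: np.ndarray, check_clashes: bool = True
) -> float:
    """Total square-well energy of a conformation, in units of eps.

    Returns ``-eps * (number of native pairs inside their wells)``, or
    ``+inf`` when any interacting pair violates its hard core, so that
    analysis code cannot silently average over clashed conformations.
    """
    d = _native_pair_distances(model, coords)
    if check_clashes and _any_hard_core_overlap(model, np.asarray(coords, float)):
        return float("inf")
    formed = (d > model.sigma) & (d <= model.well_edge)
    return -model.epsilon * float(formed.sum())


def fraction_native(model: GoModel, coords: np.ndarray) -> float:
    """Fraction Q of native contacts formed; the folding progress coordinate."""
    if model.n_contacts == 0:
        raise ValueError("model has no native contacts")
    d = _native_pair_distances(model, coords)
    formed = (d > model.sigma) & (d <= model.well_edge)
    return float(formed.sum()) / model.n_contacts


def region_contact_counts(
    model: GoModel, regions: Iterable[RegionSpec]
) -> tuple[dict[str, int], dict[tuple[str, str], int]]:
    """Native-contact counts per region and per region pair.

    A contact counts for a region when at least one of its atoms lies in a
    residue of that region; the pairwise table counts contacts with one atom
    in each of the two regions (diagonal = both in the same region).
    """
    regions = list(regions)
    res = model.structure.residue_numbers
    for reg in regions:
        if not any(reg.contains(int(r)) for r in res):
            raise ValueError(f"region {reg.name!r} contains no atoms")
    per_region = {reg.name: 0 for reg in regions}
    pairwise: dict[tuple[str, str], int] = {}
    ri = res[model.pair_i]
    rj = res[model.pair_j]
    for reg in regions:
        in_i = np.array([reg.contains(int(r)) for r in ri])
        in_j = np.array([reg.contains(int(r)) for r in rj])
        per_region[reg.name] = int((in_i | in_j).sum())
    for a in regions:
        a_i = np.array([a.contains(int(r)) for r in ri])
        a_j = np.array([a.contains(int(r)) for r in rj])
        for b in regions:
            b_i = np.array([b.contains(int(r)) for r in ri])
            b_j = np.array([b.contains(int(r)) for r in rj])
            key = (a.name, b.name)
            pairwise[key] = int(((a_i & b_j) | (a_j & b_i)).sum())
    return per_region, pairwise
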