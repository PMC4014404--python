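"""Monte Carlo ensemble docking (MC-ED) and dimer interface statistics.

Random pairs of monomer conformations are treated as rigid bodies and
docked by Metropolis annealing of random translations and rotations along
a docking axis, optimizing shape complementarity only: the objective
maximizes the number of intermolecular residue contacts while driving
atomic clashes to zero.  Two residues are in contact in the dimer when any
atom pair sits inside the attractive range of the intramolecular square
well, ``sigma_ij < d <= lambda*sigma_ij`` with ``sigma_ij = alpha*(ri+rj)``;
an atomic clash is ``d < sigma_ij``.

The statistics over thousands of optimized poses -- the density histogram
of contact counts, the residue-pair contact probability map, the most
frequent contacts and the per-residue hot-spot profile -- summarize where
on the monomer surface geometrically matched dimer interfaces form, and
hence which residues are candidate aggregation hot spots.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure_io import ProteinStructure

__all__ = [
    "MCParams",
    "DimerPose",
    "DimerEnsemble",
    "InterfaceStatistics",
    "docking_axis",
    "intermolecular_contacts",
    "dock_pair",
    "ensemble_dock",
    "density_histogram",
    "contact_probability_map",
    "top_contacts",
    "hotspot_profile",
    "interaction_partners",
    "cation_pi_candidates",
]

DEFAULT_ALPHA = 0.80
DEFAULT_LAMBDA = 1.6

_POSITIVE_RES = {"HIS", "ARG", "LYS"}
_AROMATIC_RES = {"PHE", "TYR", "TRP", "HIS"}
_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_CHARGE_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "HIS": ("ND1", "NE2", "CE1"),
}


@dataclass(frozen=True)
class MCParams:
    """Annealing schedule and move sizes of the pairwise docking MC.

    ``n_steps`` is the total move budget, split over ``n_restarts``
    independent annealing runs from the initial axis placement (the
    best-ever pose across all restarts is returned); restarts make the
    search robust on rugged shape-complementarity landscapes.
    """

    n_steps: int = 5000
    n_restarts: int = 4
    axis_sigma: float = 1.0  # A, translation along the docking axis
    off_axis_sigma: float = 1.0  # A, perpendicular translation
    rot_sigma_deg: float = 5.0  # rotation of B about its center
    t_start: float = 0.8
    t_end: float = 0.02
    clash_weight: float = 10.0


@dataclass
class DimerPose:
    """A rigid placement of monomer B against monomer A."""

    monomer_a: int
    monomer_b: int
    rotation: np.ndarray  # (3,3), applied to B about the origin
    translation: np.ndarray  # (3,)
    contacts: frozenset  # residue pairs (res_a, res_b)
    n_clashes: int

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DimerEnsemble:
    """Optimized poses of random monomer pairs plus the convergence trace."""

    poses: list[DimerPose]
    trace_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    trace_sd: np.ndarray = field(default_factory=lambda: np.zeros(0))
    converged: bool = False

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def contact_counts(self) -> np.ndarray:
        return np.array([p.n_contacts for p in self.poses], dtype=int)


class _RigidBody:
    """Pre-extracted arrays of one conformer for fast contact evaluation."""

    def __init__(self, structure: ProteinStructure, alpha: float, lam: float):
        self.coords = structure.coords
        self.radii = structure.radii
        self.residues = structure.residue_numbers
        self.center = self.coords.mean(axis=0)
        self.alpha = alpha
        self.lam = lam
        self.max_cut = lam * alpha * 2 * self.radii.max()
        self.tree = cKDTree(self.coords)


def _as_body(
    conf: ProteinStructure | _RigidBody, alpha: float, lam: float
) -> _RigidBody:
    return conf if isinstance(conf, _RigidBody) else _RigidBody(conf, alpha, lam)


def docking_axis(
    confA: ProteinStructure | _RigidBody,
    confB: ProteinStructure | _RigidBody,
    alpha: float = DEFAULT_ALPHA,
    lam: float = DEFAULT_LAMBDA,
    margin: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Center-to-center docking axis and a contact-free initial offset.

    The axis runs from A's to B's center of geometry; B is shifted along it
    until every atom pair is beyond the maximum attractive range plus
    *margin*.  Returns ``(unit_axis, initial_translation_of_B)``.
    """
    A = _as_body(confA, alpha, lam)
    B = _as_body(confB, alpha, lam)
    delta = B.center - A.center
    norm = float(np.linalg.norm(delta))
    if norm < 1e-6:
        raise ValueError("coincident centers of geometry: axis undefined")
    axis = delta / norm
    reach = max(A.max_cut, B.max_cut) + margin
    proj_a = (A.coords - A.center) @ axis
    proj_b = (B.coords - A.center) @ axis  # B in A-centered frame
    shift = (proj_a.max() + reach) - proj_b.min()
    return axis, max(shift, 0.0) * axis


class _PairEvaluator:
    """Precomputed dense pair tables for fast repeated contact evaluation.

    For toy/monomer sizes (up to ~10^5 atom pairs) a dense distance matrix
    beats tree queries by a wide margin per MC step.
    """

    def __init__(self, A: _RigidBody, B: _RigidBody, alpha: float, lam: float):
        self.A = A
        self.B = B
        sigma = alpha * (A.radii[:, None] + B.radii[None, :])
        self.sigma2 = sigma**2
        self.well2 = (lam * sigma) ** 2

    def __call__(self, coords_b: np.ndarray) -> tuple[frozenset, int]:
        diff = self.A.coords[:, None, :] - coords_b[None, :, :]
        d2 = np.einsum("abk,abk->ab", diff, diff)
        clashes = int((d2 < self.sigma2).sum())
        ai, bi = np.nonzero((d2 > self.sigma2) & (d2 <= self.well2))
        contacts = frozenset(
            zip(self.A.residues[ai].tolist(), self.B.residues[bi].tolist())
        )
        return contacts, clashes


def intermolecular_contacts(
    confA: ProteinStructure | _RigidBody,
    confB: ProteinStructure | _RigidBody,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    lam: float = DEFAULT_LAMBDA,
) -> tuple[frozenset, int]:
    """Residue-level contact set and atomic clash count at a transform.

    B's coordinates are mapped through ``x @ R.T + t`` before evaluation.
    Multiple atomic contacts within one residue pair count once; clashes
    are counted per atom pair.
    """
    A = _as_body(confA, alpha, lam)
    B = _as_body(confB, alpha, lam)
    coords_b = B.coords
    if rotation is not None:
        coords_b = coords_b @ np.asarray(rotation).T
    if translation is not None:
        coords_b = coords_b + np.asarray(translation)
    if len(A.coords) * len(B.coords) <= 200_000:
        return _PairEvaluator(A, B, alpha, lam)(coords_b)
    cut = lam * alpha * (A.radii.max() + B.radii.max())
    pairs = A.tree.query_ball_point(coords_b, cut)
    contacts = set()
    clashes = 0
    for bi, neigh in enumerate(pairs):
        if not neigh:
            continue
        ai = np.asarray(neigh, dtype=int)
        d = np.linalg.norm(A.coords[ai] - coords_b[bi], axis=1)
        sigma = alpha * (A.radii[ai] + B.radii[bi])
        clashes += int((d < sigma).sum())
        hit = (d > sigma) & (d <= lam * sigma)
        for a in ai[hit]:
            contacts.add((int(A.residues[a]), int(B.residues[bi])))
    return frozenset(contacts), clashes


def dock_pair(
    confA: ProteinStructure | _RigidBody,
    confB: ProteinStructure | _RigidBody,
    mc: MCParams = MCParams(),
    seed: int = 0,
    monomer_a: int = 0,
    monomer_b: int = 0,
    alpha: float = DEFAULT_ALPHA,
    lam: float = DEFAULT_LAMBDA,
    axis: np.ndarray | None = None,
) -> DimerPose:
    """Optimize one rigid dimer interface by Metropolis annealing.

    The objective is ``-n_contacts + clash_weight * n_clashes``; the
    best-ever pose is returned (not the final one).  Reproducible under
    *seed*.  When the two conformers share a center of geometry (the usual
    case for same-frame ensembles) a random axis is drawn instead of the
    undefined center-to-center axis.
    """
    A = _as_body(confA, alpha, lam)
    B = _as_body(confB, alpha, lam)
    rng = np.random.default_rng(seed)
    if axis is None:
        try:
            axis, t0 = docking_axis(A, B, alpha, lam)
        except ValueError:
            v = rng.normal(size=3)
            axis = v / np.linalg.norm(v)
            reach = max(A.max_cut, B.max_cut) + 1.0
            proj_a = (A.coords - A.center) @ axis
            proj_b = (B.coords - A.center) @ axis
            t0 = ((proj_a.max() + reach) - proj_b.min()) * axis
    else:
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        _, t0 = docking_axis(A, B, alpha, lam)

    evaluate = _PairEvaluator(A, B, alpha, lam)

    def objective(Rm, tv):
        contacts, clashes = evaluate(B.coords @ Rm.T + tv)
        return -len(contacts) + mc.clash_weight * clashes, contacts, clashes

    t0 = np.asarray(t0, float)
    e0, c0, cl0 = objective(np.eye(3), t0)
    best = DimerPose(monomer_a, monomer_b, np.eye(3), t0.copy(), c0, cl0)
    best_e = e0

    n_restarts = max(mc.n_restarts, 1)
    steps = max(mc.n_steps // n_restarts, 1)
    cool = (mc.t_end / mc.t_start) ** (1.0 / steps)
    for _ in range(n_restarts):
        R, t, e = np.eye(3), t0.copy(), e0
        temp = mc.t_start
        for _ in range(steps):
            move = rng.integers(0, 3)
            R_new, t_new = R, t
            if move == 0:
                t_new = t + rng.normal(0.0, mc.axis_sigma) * axis
            elif move == 1:
                perp = rng.normal(size=3)
                perp -= (perp @ axis) * axis
                nrm = np.linalg.norm(perp)
                if nrm < 1e-12:
                    continue
                t_new = t + rng.normal(0.0, mc.off_axis_sigma) * perp / nrm
            else:
                ax = rng.normal(size=3)
                ax /= np.linalg.norm(ax)
                ang = rng.normal(0.0, math.radians(mc.rot_sigma_deg))
                dR = Rotation.from_rotvec(ang * ax).as_matrix()
                # rotate about B's current center
                center = B.center @ R.T + t
                R_new = dR @ R
                t_new = center - (B.center @ R_new.T)
            e_new, c_new, cl_new = objective(R_new, t_new)
            if e_new <= e or rng.random() < math.exp(-(e_new - e) / temp):
                R, t, e = R_new, t_new, e_new
                if e < best_e or (e == best_e and cl_new < best.n_clashes):
                    best = DimerPose(
                        monomer_a, monomer_b, np.array(R_new),
                        np.array(t_new), c_new, cl_new,
                    )
                    best_e = e
            temp *= cool
    # greedy polish of the best-ever pose with fine moves
    R, t, e = best.rotation.copy(), best.translation.copy(), best_e
    for _ in range(min(steps, 2000)):
        move = rng.integers(0, 3)
        R_new, t_new = R, t
        if move == 0:
            t_new = t + rng.normal(0.0, 0.25) * axis
        elif move == 1:
            perp = rng.normal(size=3)
            perp -= (perp @ axis) * axis
            nrm = np.linalg.norm(perp)
            if nrm < 1e-12:
                continue
            t_new = t + rng.normal(0.0, 0.25) * perp / nrm
        else:
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            dR = Rotation.from_rotvec(
                rng.normal(0.0, math.radians(1.5)) * ax
            ).as_matrix()
            center = B.center @ R.T + t
            R_new = dR @ R
            t_new = center - (B.center @ R_new.T)
        e_new, c_new, cl_new = objective(R_new, t_new)
        if e_new <= e:
            R, t, e = R_new, t_new, e_new
            if e < best_e or (e == best_e and cl_new < best.n_clashes):
                best = DimerPose(
                    monomer_a, monomer_b, np.array(R_new), np.array(t_new),
                    c_new, cl_new,
                )
                best_e = e
    return best


def ensemble_dock(
    ensembleA: list[ProteinStructure],
    ensembleB: list[ProteinStructure] | None = None,
    cap: int = 5000,
    convergence_tol: float = 0.01,
    window: int = 250,
    seed: int = 0,
    mc: MCParams = MCParams(),
    alpha: float = DEFAULT_ALPHA,
    lam: float = DEFAULT_LAMBDA,
) -> DimerEnsemble:
    """Dock random conformer pairs until the contact-count statistics settle.

    Pairs are drawn uniformly with replacement (A != B enforced when the
    ensemble has more than one member and B is the same ensemble); docking
    stops when the running mean and SD of ``n_contacts`` both change by
    less than *convergence_tol* (relative) over the last *window* pairs, or
    at *cap* pairs.
    """
    if not ensembleA:
        raise ValueError("empty ensemble")
    same = ensembleB is None
    ensembleB = ensembleA if same else ensembleB
    if cap < 2 * window:
        raise ValueError("cap must be at least twice the convergence window")
    bodiesA = [_as_body(c, alpha, lam) for c in ensembleA]
    bodiesB = bodiesA if same else [_as_body(c, alpha, lam) for c in ensembleB]
    rng = np.random.default_rng(seed)
    poses: list[DimerPose] = []
    counts: list[int] = []
    means, sds = [], []
    converged = False
    prev_mean = prev_sd = None
    while len(poses) < cap:
        ia = int(rng.integers(len(bodiesA)))
        ib = int(rng.integers(len(bodiesB)))
        if same and len(bodiesA) > 1:
            while ib == ia:
                ib = int(rng.integers(len(bodiesB)))
        pose = dock_pair(
            bodiesA[ia], bodiesB[ib], mc,
            seed=int(rng.integers(2**31 - 1)),
            monomer_a=ia, monomer_b=ib, alpha=alpha, lam=lam,
        )
        poses.append(pose)
        counts.append(pose.n_contacts)
        arr = np.asarray(counts, float)
        means.append(arr.mean())
        sds.append(arr.std())
        if len(poses) % window == 0 and len(poses) >= 2 * window:
            m, s = means[-1], sds[-1]
            if prev_mean is not None:
                dm = abs(m - prev_mean) / max(abs(prev_mean), 1e-12)
                ds = abs(s - prev_sd) / max(abs(prev_sd), 1e-12)
                if dm < convergence_tol and ds < convergence_tol:
                    converged = True
                    break
            prev_mean, prev_sd = m, s
    return DimerEnsemble(
        poses=poses,
        trace_mean=np.asarray(means),
        trace_sd=np.asarray(sds),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Interface statistics


@dataclass
class InterfaceStatistics:
    """Summary statistics of an optimized dimer ensemble."""

    histogram: dict[int, float]  # n_contacts -> density (sums to 1)
    mean: float
    mode: int
    probability_map: dict[tuple[int, int], float] | None = None
    ranked_contacts: list[tuple[tuple[int, int], float]] | None = None
    hotspots: dict[int, float] | None = None

    @classmethod
    def from_ensemble(
        cls, ensemble: DimerEnsemble, top_k: int = 50
    ) -> "InterfaceStatistics":
        stats = density_histogram(ensemble)
        stats.probability_map = contact_probability_map(ensemble)
        stats.ranked_contacts = top_contacts(stats.probability_map, top_k)
        stats.hotspots = hotspot_profile(stats.ranked_contacts, ensemble.poses)
        return stats


def density_histogram(ensemble: DimerEnsemble) -> InterfaceStatistics:
    """Normalized density of ``n_contacts`` over integer bins.

    The mode is the bin of maximal density (ties broken toward the lowest
    count); the mean is the arithmetic mean over poses.
    """
    if len(ensemble) == 0:
        raise ValueError("empty dimer ensemble")
    counts = ensemble.contact_counts
    vals, freq = np.unique(counts, return_counts=True)
    dens = freq / freq.sum()
    mode = int(vals[int(np.argmax(dens))])  # argmax returns first (lowest) tie
    return InterfaceStatistics(
        histogram={int(v): float(d) for v, d in zip(vals, dens)},
        mean=float(counts.mean()),
        mode=mode,
    )


def _sym(pair: tuple[int, int]) -> tuple[int, int]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def contact_probability_map(
    ensemble: DimerEnsemble,
) -> dict[tuple[int, int], float]:
    """P(a, b): fraction of poses containing the residue contact (a, b).

    Symmetrized over monomer exchange: the two monomers are identical
    molecules, so (a, b) and (b, a) are pooled onto the unordered pair.
    """
    if len(ensemble) == 0:
        raise ValueError("empty dimer ensemble")
    counts: Counter = Counter()
    for pose in ensemble.poses:
        seen = {_sym(c) for c in pose.contacts}
        counts.update(seen)
    n = len(ensemble)
    return {pair: c / n for pair, c in counts.items()}


def top_contacts(
    probability_map: dict[tuple[int, int], float], k: int = 50
) -> list[tuple[tuple[int, int], float]]:
    """The k most frequent contacts, ties broken by residue numbers."""
    if k <= 0:
        raise ValueError("k must be positive")
    if not probability_map:
        raise ValueError("empty probability map")
    ranked = sorted(
        probability_map.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1])
    )
    return ranked[:k]


def hotspot_profile(
    ranked_contacts: list[tuple[tuple[int, int], float]],
    poses: list[DimerPose],
) -> dict[int, float]:
    """Per-residue probability of joining any top-ranked contact in a pose.

    The highest-probability residues are the predicted dimerization hot
    spots.
    """
    top = {pair for pair, _ in ranked_contacts}
    residues = sorted({r for pair in top for r in pair})
    hits = {r: 0 for r in residues}
    for pose in poses:
        present = {_sym(c) for c in pose.contacts} & top
        involved = {r for pair in present for r in pair}
        for r in involved:
            hits[r] += 1
    n = max(len(poses), 1)
    return {r: hits[r] / n for r in residues}


def interaction_partners(
    residue: int,
    ranked_contacts: list[tuple[tuple[int, int], float]],
) -> Counter:
    """Partner residues of *residue* among the top contacts, with counts."""
    partners: Counter = Counter()
    for (a, b), _ in ranked_contacts:
        if a == residue:
            partners[b] += 1
        elif b == residue:
            partners[a] += 1
    return partners


def cation_pi_candidates(
    pose: DimerPose,
    structA: ProteinStructure,
    structB: ProteinStructure,
    distance_cutoff: float = 4.5,
) -> list[dict]:
    """Contacts pairing a positively chargeable residue with an aromatic.

    Flags every intermolecular contact between {His, Arg, Lys} and
    {Phe, Tyr, Trp, His}; when the standard ring / charge-carrier atom
    names are present the minimum ring-to-charge distance is annotated
    together with whether it meets the usual ~4.5 A cation-pi criterion
    (with a maximum contact distance of ~4.7 A in this model, every such
    contact lies within it or marginally beyond).
    """
    coords_b = pose.transform(structB.coords)
    res_index_a = structA.residue_index
    res_index_b = structB.residue_index
    out = []
    for (ra, rb) in sorted(pose.contacts):
        na, nb = structA.residue_name_of(ra), structB.residue_name_of(rb)
        flagged = (na in _POSITIVE_RES and nb in _AROMATIC_RES) or (
            nb in _POSITIVE_RES and na in _AROMATIC_RES
        )
        if not flagged:
            continue
        entry = {"pair": (ra, rb), "types": (na, nb), "min_distance": None,
                 "within_cutoff": None}
        # orient: which side carries the charge, which the ring
        for charged, aromatic, c_res, a_res, c_struct_idx in (
            (na, nb, ra, rb, "A"),
            (nb, na, rb, ra, "B"),
        ):
            if charged not in _POSITIVE_RES or aromatic not in _AROMATIC_RES:
                continue
            if c_struct_idx == "A":
                c_idx, a_idx = res_index_a[c_res], res_index_b[a_res]
                c_xyz = structA.coords[c_idx]
                a_xyz = coords_b[a_idx]
                c_names = [structA.atoms[i].name for i in c_idx]
                a_names = [structB.atoms[i].name for i in a_idx]
            else:
                c_idx, a_idx = res_index_b[c_res], res_index_a[a_res]
                c_xyz = coords_b[c_idx]
                a_xyz = structA.coords[a_idx]
                c_names = [structB.atoms[i].name for i in c_idx]
                a_names = [structA.atoms[i].name for i in a_idx]
            want_c = _CHARGE_ATOMS.get(charged, ())
            want_a = _RING_ATOMS.get(aromatic, ())
            sel_c = [k for k, nm in enumerate(c_names) if nm in want_c] or list(
                range(len(c_names))
            )
            sel_a = [k for k, nm in enumerate(a_names) if nm in want_a] or list(
                range(len(a_names))
            )
            d = np.linalg.norm(
                c_xyz[sel_c][:, None, :] - a_xyz[sel_a][None, :, :], axis=2
            ).min()
            if entry["min_distance"] is None or d < entry["min_distance"]:
                entry["min_distance"] = float(d)
        entry["within_cutoff"] = entry["min_distance"] <= distance_cutoff
        out.append(entry)
    return out
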