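"""Synthetic structures and ensembles for exercising the full pipeline.

Everything here is generated programmatically: toy native structures that
fold under the square-well model (an anti-parallel two-strand hairpin or a
compact helix-like coil of 2-4 pseudo-atom residues), thermally perturbed
conformer ensembles with a controlled mean RMSD, "detached tail"
intermediates with a conserved core and a displaced terminal segment
(emulating the strand-A-detached folding intermediate of truncated
beta-2 microglobulin produced upstream by constant-pH MD), and rigid
lock-and-key body pairs with a planted, verifiable docking optimum.

The generators are deterministic under their seeds, and every output is
clash-free and bond-consistent under its own Go model, so the DMD engine,
the structural metrics, the clustering and the docking stages can all run
on them directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .go_model import GoModel, build_native_contact_map, MIN_BACKBONE_SEP
from .mced import intermolecular_contacts
from .metrics import kabsch_rmsd, superpose
from .structure_io import (
    AtomRecord,
    ProteinStructure,
    RegionSpec,
    assign_radii,
)

__all__ = [
    "ToySpec",
    "LockKeyPair",
    "make_toy_native",
    "build_toy_model",
    "make_conformer_ensemble",
    "make_detached_tail_variant",
    "make_lock_key_pair",
]

_DEF_ALPHA = 0.80
_DEF_LAMBDA = 1.6


@dataclass(frozen=True)
class ToySpec:
    """Blueprint of a toy native structure."""

    n_residues: int = 10
    atoms_per_residue: int = 2  # 2: CA,CB; 3: +N; 4: +O
    topology: str = "hairpin"  # or "helix"
    tail_residues: int = 3  # N-terminal segment available for detachment
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("toy needs at least 4 residues")
        if not 2 <= self.atoms_per_residue <= 4:
            raise ValueError("atoms_per_residue must be 2..4")
        if self.topology not in ("hairpin", "helix"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 1 <= self.tail_residues < self.n_residues:
            raise ValueError("tail must be a proper N-terminal segment")


def _hairpin_positions(n: int) -> tuple[np.ndarray, np.ndarray]:
    """CA positions of an anti-parallel two-strand hairpin.

    Strand spacing 4.2 A puts cross-strand CA pairs inside the square well
    of 1.84 A united-atom carbons (2.94 < 4.2 <= 4.71 A).
    """
    s, w = 3.5, 4.2
    half = n // 2
    ca = np.zeros((n, 3))
    inward = np.zeros(n)  # +1 means the opposing strand lies at +y
    for k in range(half):
        ca[k] = (s * k, 0.0, 0.0)
        inward[k] = 1.0
    for k in range(half, n):
        ca[k] = (s * (n - 1 - k), w, 0.0)
        inward[k] = -1.0
    return ca, inward


def _helix_positions(n: int) -> tuple[np.ndarray, np.ndarray]:
    """CA positions on a compact coil with (k, k+4) square-well contacts."""
    r, dtheta, rise = 3.5, math.radians(80.0), 1.0
    ca = np.zeros((n, 3))
    outward = np.zeros((n, 3))
    for k in range(n):
        th = k * dtheta
        ca[k] = (r * math.cos(th), r * math.sin(th), rise * k)
        outward[k] = (math.cos(th), math.sin(th), 0.0)
    return ca, outward


def make_toy_native(spec: ToySpec) -> ProteinStructure:
    """Build a clash-free toy native structure with explicit bonds.

    The structure carries ``tail`` and ``core`` region annotations and an
    explicit bond list (CA backbone plus intra-residue branches); the seed
    adds a tiny symmetry-breaking jitter (0.01 A).
    """
    n = spec.n_residues
    apr = spec.atoms_per_residue
    if spec.topology == "hairpin":
        ca, inward = _hairpin_positions(n)
        cb_off = np.tile([0.0, 0.0, 1.53], (n, 1))
        n_off = np.c_[np.zeros(n), -1.45 * inward, np.zeros(n)]
        o_off = np.tile([0.0, 0.0, -1.23], (n, 1))
    else:
        ca, outward = _helix_positions(n)
        cb_off = np.tile([0.0, 0.0, 1.53], (n, 1))
        n_off = 1.45 * outward
        o_off = -1.23 * outward  # inward, toward the coil axis

    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    idx_of = {}
    serial = 0
    for k in range(n):
        names = ["CA", "CB"]
        offs = [np.zeros(3), cb_off[k]]
        if apr >= 3:
            names.append("N")
            offs.append(n_off[k])
        if apr >= 4:
            names.append("O")
            offs.append(o_off[k])
        for name, off in zip(names, offs):
            serial += 1
            xyz = ca[k] + off + rng.uniform(-0.01, 0.01, 3)
            element = name[0]
            atoms.append(
                AtomRecord(serial, name, element, k + 1, "ALA", xyz)
            )
            idx_of[(k, name)] = serial - 1
    for k in range(n):
        i_ca = idx_of[(k, "CA")]
        bonds.append((i_ca, idx_of[(k, "CB")]))
        if (k, "N") in idx_of:
            bonds.append((i_ca, idx_of[(k, "N")]))
        if (k, "O") in idx_of:
            bonds.append((i_ca, idx_of[(k, "O")]))
        if k + 1 < n:
            bonds.append((i_ca, idx_of[(k + 1, "CA")]))
    tail = RegionSpec("tail", [[1, spec.tail_residues]])
    core = RegionSpec("core", [[spec.tail_residues + 1, n]])
    structure = ProteinStructure(
        atoms, {"tail": tail, "core": core}, bonds
    )
    # feasibility self-checks: clash-free and foldable contact density
    model = build_toy_model(structure)
    if model.n_contacts < n:
        raise ValueError(
            f"infeasible toy spec: only {model.n_contacts} native contacts "
            f"for {n} residues"
        )
    return model.structure  # radii already assigned


def build_toy_model(
    structure: ProteinStructure,
    alpha: float = _DEF_ALPHA,
    lam: float = _DEF_LAMBDA,
) -> GoModel:
    """Assign united-atom radii and build the Go model of a toy structure."""
    if not structure.has_radii:
        structure = assign_radii(structure)
    return build_native_contact_map(structure, alpha, lam)


# ---------------------------------------------------------------------------
# Constraint projection shared by the ensemble generators


def _exclusion_pairs(structure: ProteinStructure, alpha: float):
    """All backbone-separated pairs with their hard-core distances."""
    res = structure.residue_numbers
    radii = structure.radii
    n = len(res)
    ii, jj = np.triu_indices(n, 1)
    keep = np.abs(res[ii] - res[jj]) >= MIN_BACKBONE_SEP
    ii, jj = ii[keep], jj[keep]
    return ii, jj, alpha * (radii[ii] + radii[jj])


def _project_constraints(
    coords: np.ndarray,
    bi: np.ndarray,
    bj: np.ndarray,
    d0: np.ndarray,
    ci: np.ndarray,
    cj: np.ndarray,
    sigma: np.ndarray,
    bond_tol: float = 0.01,
    max_iter: int = 500,
) -> np.ndarray:
    """Restore bond lengths (within the bond wells) and remove hard-core
    overlaps by iterative repulsion-only displacement; raises when the
    constraints cannot be satisfied."""
    x = coords.copy()
    tiny = np.array([0.05, 0.08, 0.06])  # deterministic separation nudge
    for _ in range(max_iter):
        disp = np.zeros_like(x)
        delta = x[bj] - x[bi]
        d = np.linalg.norm(delta, axis=1)
        coincident = d < 1e-3
        if coincident.any():
            delta[coincident] = tiny
            d[coincident] = np.linalg.norm(tiny)
        err = d - d0
        bad_b = np.abs(err) > bond_tol * d0
        if bad_b.any():
            corr = (0.5 * err[bad_b] / d[bad_b])[:, None] * delta[bad_b]
            np.add.at(disp, bi[bad_b], corr)
            np.add.at(disp, bj[bad_b], -corr)
        delta_c = x[cj] - x[ci]
        dc = np.linalg.norm(delta_c, axis=1)
        coincident = dc < 1e-3
        if coincident.any():
            delta_c[coincident] = tiny
            dc[coincident] = np.linalg.norm(tiny)
        bad_c = dc < sigma * 1.001
        if bad_c.any():
            push = (0.5 * (sigma[bad_c] * 1.02 - dc[bad_c]) / dc[bad_c])[
                :, None
            ] * delta_c[bad_c]
            np.add.at(disp, ci[bad_c], -push)
            np.add.at(disp, cj[bad_c], push)
        if not bad_b.any() and not bad_c.any():
            return x
        x += 0.7 * disp
    raise RuntimeError(
        "constraint projection failed: clashes or bond violations persist"
    )


def _chain_dihedral_axes(structure: ProteinStructure):
    """Rotatable chain bonds: (axis_atom_a, axis_atom_b, rotated atom set).

    Each consecutive CA-CA bond is a torsion axis; rotating everything
    downstream of it (including the branches of the far pivot residue)
    preserves every 1-2 and 1-3 distance exactly, because all constrained
    pairs crossing the cut have an endpoint on the axis.
    """
    res = structure.residue_numbers
    names = structure.atom_names
    ca_of = {
        int(r): i for i, (r, nm) in enumerate(zip(res, names)) if nm == "CA"
    }
    residues = sorted(ca_of)
    axes = []
    for a, b in zip(residues, residues[1:]):
        moved = [
            i
            for i, (r, nm) in enumerate(zip(res, names))
            if r > b or (r == b and nm != "CA")
        ]
        axes.append((ca_of[a], ca_of[b], np.array(moved, dtype=int)))
    return axes


def _rotate_about(
    x: np.ndarray, i: int, j: int, moved: np.ndarray, angle: float
) -> None:
    axis = x[j] - x[i]
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    x[moved] = (x[moved] - x[j]) @ R.T + x[j]


def _clash_free(x: np.ndarray, excl) -> bool:
    ci, cj, sigma = excl
    d = np.linalg.norm(x[cj] - x[ci], axis=1)
    return bool((d > sigma * 1.001).all())


def _dihedral_conformer(
    native_coords: np.ndarray,
    axes,
    sigma_rad: float,
    rng: np.random.Generator,
    excl,
    max_tries: int = 60,
) -> np.ndarray:
    """One clash-free conformer from random torsions (rejection sampled)."""
    for attempt in range(max_tries):
        x = native_coords.copy()
        scale = 1.0 / (1 + 0.15 * attempt)  # ease off if clashes persist
        for i, j, moved in axes:
            _rotate_about(x, i, j, moved, rng.normal(0.0, sigma_rad * scale))
        if _clash_free(x, excl):
            return x
    raise RuntimeError(
        "could not draw a clash-free conformer at this perturbation level"
    )


def make_conformer_ensemble(
    native: ProteinStructure,
    target_rmsd: float,
    n: int,
    seed: int = 0,
    alpha: float = _DEF_ALPHA,
) -> list[ProteinStructure]:
    """Thermally plausible conformers with a controlled mean CA RMSD.

    Conformers are drawn by correlated low-frequency backbone torsion
    moves (random rotations about every chain bond, which preserve the
    bond network exactly) with clash-free rejection sampling.  The torsion
    amplitude is calibrated on a pilot batch so that the realized
    ensemble-mean CA RMSD to the native lands within ~15% of
    *target_rmsd*.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be non-negative")
    if n < 1:
        raise ValueError("n must be positive")
    if not native.has_radii:
        native = assign_radii(native)
    if target_rmsd == 0:
        return [native.with_coords(native.coords) for _ in range(n)]
    axes = _chain_dihedral_axes(native)
    excl = _exclusion_pairs(native, alpha)
    coords0 = native.coords
    ca = native.ca_indices()
    rng = np.random.default_rng(seed)

    sigma = 0.05 * target_rmsd  # radians; refined below
    realized = None
    for _ in range(8):
        trial = [
            _dihedral_conformer(coords0, axes, sigma, rng, excl)
            for _ in range(6)
        ]
        realized = float(
            np.mean([kabsch_rmsd(t[ca], coords0[ca]) for t in trial])
        )
        if abs(realized - target_rmsd) / target_rmsd < 0.06:
            break
        sigma *= float(np.clip(target_rmsd / max(realized, 1e-9), 0.4, 2.5))
    for _ in range(8):  # batch-level refinement of the torsion amplitude
        out = []
        for _ in range(n):
            x = _dihedral_conformer(coords0, axes, sigma, rng, excl)
            out.append(native.with_coords(x))
        realized = float(np.mean(
            [kabsch_rmsd(c.coords[ca], coords0[ca]) for c in out]
        ))
        if abs(realized - target_rmsd) / target_rmsd <= 0.10:
            return out
        ratio = target_rmsd / max(realized, 1e-9)
        sigma *= float(np.clip(ratio**0.7, 0.6, 1.7))
    if abs(realized - target_rmsd) / target_rmsd <= 0.15:
        return out
    raise RuntimeError(
        f"unreachable target RMSD {target_rmsd:.2f} A under clash "
        f"constraints (realized {realized:.2f} A)"
    )


def make_detached_tail_variant(
    native: ProteinStructure,
    tail_region: RegionSpec | None = None,
    core_rmsd_target: float = 3.0,
    tail_rotation_deg: tuple[float, float] = (70.0, 140.0),
    n: int = 5,
    seed: int = 0,
    alpha: float = _DEF_ALPHA,
) -> list[ProteinStructure]:
    """Intermediate-like conformers: conserved core, detached terminal tail.

    The terminal *tail_region* (default: the structure's ``tail``
    annotation) is swung rigidly about the junction chain bond by large
    random torsions, the remaining core carries thermal torsion noise
    around *core_rmsd_target*, and clashed draws are rejected.  Each
    member gets a distinct tail placement; the tail RMSD after a core fit
    exceeds the core RMSD at least threefold.
    """
    if not native.has_radii:
        native = assign_radii(native)
    if tail_region is None:
        tail_region = native.annotations.get("tail")
        if tail_region is None:
            raise ValueError("no tail region given or annotated")
    lo, hi = native.residue_span
    tail_res = set(tail_region.residues())
    if lo not in tail_res and hi not in tail_res:
        raise ValueError("tail region must sit at a chain terminus")
    core_region = RegionSpec(
        "core", [[r, r] for r in sorted(
            set(range(lo, hi + 1)) - tail_res
        )]
    )
    excl = _exclusion_pairs(native, alpha)
    coords0 = native.coords
    res = native.residue_numbers
    all_axes = _chain_dihedral_axes(native)
    # an axis perturbs the core shape iff both pivots lie in the core
    core_axes = [
        (i, j, mv)
        for i, j, mv in all_axes
        if int(res[i]) not in tail_res and int(res[j]) not in tail_res
    ]
    junction_axes = [
        (i, j, mv)
        for i, j, mv in all_axes
        if (int(res[i]) in tail_res) != (int(res[j]) in tail_res)
    ]
    tail_idx = native.atom_indices(tail_region)
    core_ca = native.atom_indices(core_region, "CA")
    tail_ca = native.atom_indices(tail_region, "CA")
    rng = np.random.default_rng(seed)

    def draw(sigma_core: float, swing: bool) -> np.ndarray | None:
        for attempt in range(40):
            x = coords0.copy()
            scale = 1.0 / (1 + 0.1 * attempt)
            for i, j, mv in core_axes:
                _rotate_about(x, i, j, mv, rng.normal(0, sigma_core * scale))
            if swing:
                for i, j, mv in junction_axes:
                    ang = math.radians(rng.uniform(*tail_rotation_deg))
                    ang *= rng.choice([-1.0, 1.0])
                    _rotate_about(x, i, j, mv, ang)
            if _clash_free(x, excl):
                return x
        return None

    # calibrate core torsion noise against the core-fit RMSD target
    sigma_core = 0.05 * core_rmsd_target
    for _ in range(8):
        trials = [draw(sigma_core, swing=False) for _ in range(5)]
        trials = [t for t in trials if t is not None]
        if not trials:
            sigma_core *= 0.5
            continue
        realized = float(np.mean([
            superpose(t, coords0, fit_subset=core_ca).rmsd for t in trials
        ]))
        if abs(realized - core_rmsd_target) / core_rmsd_target < 0.08:
            break
        sigma_core *= float(
            np.clip(core_rmsd_target / max(realized, 1e-9), 0.4, 2.5)
        )

    members: list[np.ndarray] = []
    aligned_tails: list[np.ndarray] = []
    attempts = 0
    while len(members) < n and attempts < 60 * n:
        attempts += 1
        x = draw(sigma_core, swing=True)
        if x is None:
            continue
        sp = superpose(x, coords0, fit_subset=core_ca)
        core_rmsd = sp.rmsd
        aligned = sp.apply(x)
        tail_rmsd = float(
            np.sqrt(((aligned[tail_ca] - coords0[tail_ca]) ** 2)
                    .sum(axis=1).mean())
        )
        if not 0.4 * core_rmsd_target <= core_rmsd <= 1.6 * core_rmsd_target:
            continue
        if tail_rmsd < 3.0 * max(core_rmsd, 1e-9):
            continue
        # tail placements must differ between members (in the core frame)
        if any(
            float(np.sqrt(((aligned[tail_ca] - at) ** 2).sum(axis=1).mean()))
            < 1.0
            for at in aligned_tails
        ):
            continue
        members.append(x)
        aligned_tails.append(aligned[tail_ca])
    if len(members) < n:
        raise RuntimeError(
            f"could only build {len(members)}/{n} detached-tail conformers "
            f"under the clash constraints"
        )
    return [native.with_coords(m) for m in members]


# ---------------------------------------------------------------------------
# Lock-and-key docking pair


@dataclass
class LockKeyPair:
    """Rigid lock (cavity slab) and key (peg) with a planted optimum."""

    body_a: ProteinStructure
    body_b: ProteinStructure
    planted_rotation: np.ndarray
    planted_translation: np.ndarray
    planted_contacts: frozenset
    patch_residues_a: frozenset
    patch_residues_b: frozenset
    alpha: float = _DEF_ALPHA
    lam: float = _DEF_LAMBDA


# near-central cells first, so the cavity sits under the slab's center of
# geometry and the center-to-center docking axis points into its mouth
_FOOTPRINT_ORDER = [(2, 1), (2, 2), (3, 1), (2, 3), (3, 3), (4, 1)]


def _lock_structure(
    nx: int,
    ny: int,
    spacing: float,
    footprint: set,
    wall_height: float,
    overhang: float,
    rng: np.random.Generator,
) -> ProteinStructure:
    """Slab with an open cavity whose rim atoms overhang into it.

    The lattice spacing exceeds the maximum attractive range, so any flat
    approach earns at most one contact per key residue (lateral neighbours
    are out of reach); only the cavity interior, constricted by rim atoms
    that lean inward over the opening, offers contact-rich walls.  Cavity
    cells carry a sub-base atom, rim cells the overhang atom; every cell
    also carries a blocking atom under the interstitial site so nothing
    can embed between base atoms.
    """
    atoms = []
    serial = 0
    bonds = []
    for i in range(nx):
        for j in range(ny):
            resnum = 1 + i * ny + j
            base = np.array([spacing * i, spacing * j, 0.0])
            offsets = [("CA", np.zeros(3))]
            if (i, j) in footprint:
                offsets.append(("CB", np.array([0.0, 0.0, -1.5])))
            else:
                ortho = sorted(
                    c for c in ((i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1))
                    if c in footprint
                )
                diag = sorted(
                    c
                    for c in ((i + 1, j + 1), (i + 1, j - 1),
                              (i - 1, j + 1), (i - 1, j - 1))
                    if c in footprint
                )
                if ortho:  # rim residue: lean toward one cavity cell
                    c = ortho[0]
                    direction = np.array([c[0] - i, c[1] - j, 0.0], float)
                    offsets.append(
                        ("CB", overhang * direction
                         + np.array([0.0, 0.0, wall_height]))
                    )
                elif diag:  # corner rim: longer diagonal lean
                    c = diag[0]
                    direction = np.array(
                        [c[0] - i, c[1] - j, 0.0], float
                    ) / math.sqrt(2)
                    reach = spacing * math.sqrt(2) - (spacing - overhang)
                    offsets.append(
                        ("CB", reach * direction
                         + np.array([0.0, 0.0, wall_height]))
                    )
            offsets.append(
                ("CG", np.array([spacing / 2, spacing / 2, -2.2]))
            )
            first = serial
            for name, off in offsets:
                serial += 1
                atoms.append(
                    AtomRecord(serial, name, "C", resnum, "ALA",
                               base + off + rng.uniform(-0.05, 0.05, 3))
                )
            for k in range(first + 1, serial):
                bonds.append((first, k))
    return assign_radii(ProteinStructure(atoms, bonds=bonds))


def _key_structure(
    footprint: set,
    spacing: float,
    handle_height: float,
    lift: float,
    rng: np.random.Generator,
) -> ProteinStructure:
    """Peg matching the cavity footprint, pre-positioned above it."""
    atoms = []
    serial = 0
    for k, (i, j) in enumerate(sorted(footprint)):
        resnum = 101 + k
        base = np.array([spacing * i, spacing * j, lift])
        serial += 1
        atoms.append(
            AtomRecord(serial, "CA", "C", resnum, "ALA",
                       base + rng.uniform(-0.05, 0.05, 3))
        )
        serial += 1
        atoms.append(
            AtomRecord(serial, "CB", "C", resnum, "ALA",
                       base + np.array([0, 0, handle_height])
                       + rng.uniform(-0.05, 0.05, 3))
        )
    bonds = [(2 * k, 2 * k + 1) for k in range(len(footprint))]
    return assign_radii(ProteinStructure(atoms, bonds=bonds))


def _coarse_scan_is_argmax(
    pair: "LockKeyPair", step: float = 2.0, clash_weight: float = 10.0
) -> bool:
    """Verify by coarse 6-DOF enumeration that no pose away from the
    planted one matches its contact score."""
    A, B = pair.body_a, pair.body_b
    planted_score = len(pair.planted_contacts)
    axes = [
        Rotation.identity(),
        *(Rotation.from_euler(ax, ang, degrees=True)
          for ax in "xyz" for ang in (90, 180, 270)),
    ]
    a_coords = A.coords
    lo = a_coords.min(axis=0) - 6.0
    hi = a_coords.max(axis=0) + 6.0
    b0 = B.coords.mean(axis=0)
    t_planted = pair.planted_translation
    for rot in axes:
        R = rot.as_matrix()
        for x in np.arange(lo[0], hi[0] + step, step):
            for y in np.arange(lo[1], hi[1] + step, step):
                for z in np.arange(lo[2], hi[2] + step, step):
                    t = np.array([x, y, z]) - b0 @ R.T + b0 * 0  # place B com
                    t = np.array([x, y, z]) - (B.coords @ R.T).mean(axis=0)
                    contacts, clashes = intermolecular_contacts(
                        A, B, R, t, pair.alpha, pair.lam
                    )
                    score = len(contacts) - clash_weight * clashes
                    near_planted = (
                        np.allclose(R, pair.planted_rotation)
                        and np.linalg.norm(t - t_planted) <= 3.0
                    )
                    if score >= planted_score and not near_planted:
                        return False
    return True


def make_lock_key_pair(
    patch_size: int = 4,
    seed: int = 0,
    spacing: float = 7.0,
    wall_height: float = 3.0,
    overhang: float = 3.2,
    contact_height: float = 3.6,
    nx: int = 6,
    ny: int = 5,
    verify: bool = True,
    max_regenerate: int = 5,
) -> LockKeyPair:
    """Build complementary rigid bodies with a unique docking optimum.

    The lock is a two-layer slab with an asymmetric cavity (a polyomino
    footprint of *patch_size* cells cut out of the wall layer); the key is
    a matching peg whose insertion into the cavity realizes the maximum of
    the docking objective.  The planted pose and its residue contact list
    are returned as ground truth; when *verify* is set, a coarse exhaustive
    transform scan certifies that no other placement matches the planted
    contact count (regenerating with a fresh jitter seed on failure).
    """
    if patch_size < 3:
        raise ValueError("patch must span at least 3 residues")
    if patch_size > len(_FOOTPRINT_ORDER):
        raise ValueError(f"patch_size up to {len(_FOOTPRINT_ORDER)} supported")
    footprint = set(_FOOTPRINT_ORDER[:patch_size])
    for attempt in range(max_regenerate):
        rng = np.random.default_rng(seed + 1000 * attempt)
        body_a = _lock_structure(
            nx, ny, spacing, footprint, wall_height, overhang, rng
        )
        # key built pre-positioned above the cavity so the center-to-center
        # docking axis points into it
        lift = 14.0
        body_b = _key_structure(footprint, spacing, wall_height, lift, rng)
        planted_R = np.eye(3)
        planted_t = np.array([0.0, 0.0, contact_height - lift])
        contacts, clashes = intermolecular_contacts(
            body_a, body_b, planted_R, planted_t
        )
        if clashes or len(contacts) < patch_size + 2:
            continue
        pair = LockKeyPair(
            body_a=body_a,
            body_b=body_b,
            planted_rotation=planted_R,
            planted_translation=planted_t,
            planted_contacts=contacts,
            patch_residues_a=frozenset(a for a, _ in contacts),
            patch_residues_b=frozenset(b for _, b in contacts),
        )
        if not verify or _coarse_scan_is_argmax(pair):
            return pair
    raise RuntimeError(
        "failed to generate a lock-key pair with a unique planted optimum"
    )
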