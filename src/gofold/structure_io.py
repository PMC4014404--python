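"""Read/write single-chain protein structures and conformer ensembles.

Structures are heavy-atom only: hydrogens and waters are dropped on input,
alternate locations are resolved to the highest-occupancy conformer.  The
deposited (1-based) residue numbering is preserved everywhere so that
literature residue labels (e.g. His84 of beta-2 microglobulin) map directly
onto :class:`ProteinStructure` objects.

Van der Waals radii follow a united-atom convention: carbons with implicit
hydrogens use enlarged radii.  The shipped ``uatom19`` table puts aliphatic
CHn carbons at 1.84 A, which anchors the square-well attractive range of a
methyl-methyl pair at ``lambda * alpha * 2 * 1.84 = 4.71 A`` for the default
model parameters (alpha = 0.80, lambda = 1.6).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "RegionSpec",
    "PDBParseError",
    "load_radius_set",
    "load_b2m_regions",
    "read_pdb",
    "read_ensemble",
    "assign_radii",
    "truncate_n_terminus",
    "write_pdb",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Malformed or unreadable PDB content."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a single-chain structure."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    coordinates: np.ndarray  # (3,) in Angstrom
    vdw_radius: float | None = None  # Angstrom, None until assigned

    def __post_init__(self):
        object.__setattr__(
            self, "coordinates", np.asarray(self.coordinates, dtype=float)
        )
        if self.coordinates.shape != (3,):
            raise ValueError("coordinates must be a 3-vector")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        if self.element.upper() == "H":
            raise ValueError("hydrogens are excluded by construction")


@dataclass(frozen=True)
class RegionSpec:
    """Named set of inclusive residue-number ranges, e.g. a beta-strand."""

    name: str
    residue_ranges: tuple[tuple[int, int], ...]

    def __init__(self, name: str, residue_ranges: Iterable[Sequence[int]]):
        ranges = tuple(tuple(int(x) for x in r) for r in residue_ranges)
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"region {name!r}: range [{lo}, {hi}] inverted")
        for a, b in zip(sorted(ranges), sorted(ranges)[1:]):
            if b[0] <= a[1]:
                raise ValueError(f"region {name!r}: overlapping ranges {a} and {b}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "residue_ranges", ranges)

    def contains(self, residue_number: int) -> bool:
        return any(lo <= residue_number <= hi for lo, hi in self.residue_ranges)

    def residues(self) -> list[int]:
        out: list[int] = []
        for lo, hi in sorted(self.residue_ranges):
            out.extend(range(lo, hi + 1))
        return out

    def clipped(self, first: int, last: int) -> "RegionSpec | None":
        """Intersect with the residue span [first, last]; None if empty."""
        kept = [
            (max(lo, first), min(hi, last))
            for lo, hi in self.residue_ranges
            if hi >= first and lo <= last
        ]
        return RegionSpec(self.name, kept) if kept else None


class ProteinStructure:
    """Ordered heavy atoms of one chain plus named region annotations."""

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        annotations: Mapping[str, RegionSpec] | None = None,
        bonds: Sequence[tuple[int, int]] | None = None,
    ):
        if not atoms:
            raise ValueError("structure must contain at least one atom")
        self.atoms: list[AtomRecord] = list(atoms)
        #: explicit covalent/constraint bond list (atom index pairs); None
        #: means "infer from geometry" (real proteins). Toy structures with
        #: non-covalent pseudo-bond lengths must carry it explicitly.
        self.bonds: list[tuple[int, int]] | None = (
            [tuple(sorted(map(int, b))) for b in bonds] if bonds is not None else None
        )
        res = [a.residue_number for a in self.atoms]
        if any(b < a for a, b in zip(res, res[1:])):
            raise ValueError("residue numbers must be non-decreasing along the chain")
        self.annotations: dict[str, RegionSpec] = dict(annotations or {})
        for reg in self.annotations.values():
            span = (min(res), max(res))
            for lo, hi in reg.residue_ranges:
                if hi < span[0] or lo > span[1]:
                    raise ValueError(
                        f"region {reg.name!r} lies outside residue span {span}"
                    )

    # -- array views -------------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.array([a.residue_number for a in self.atoms], dtype=int)

    @property
    def residue_names(self) -> list[str]:
        return [a.residue_name for a in self.atoms]

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    @property
    def radii(self) -> np.ndarray:
        vals = [a.vdw_radius for a in self.atoms]
        if any(v is None for v in vals):
            raise ValueError("vdW radii not assigned; call assign_radii first")
        return np.array(vals, dtype=float)

    @property
    def has_radii(self) -> bool:
        return all(a.vdw_radius is not None for a in self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(set(a.residue_number for a in self.atoms))

    @property
    def residue_span(self) -> tuple[int, int]:
        res = self.residue_numbers
        return int(res.min()), int(res.max())

    @property
    def residue_index(self) -> dict[int, list[int]]:
        """Mapping residue_number -> atom indices."""
        out: dict[int, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_number, []).append(i)
        return out

    def atom_indices(
        self, region: RegionSpec | None = None, atom_filter: str | None = None
    ) -> np.ndarray:
        """Indices of atoms in *region* (all if None), optionally by atom name."""
        idx = []
        for i, a in enumerate(self.atoms):
            if region is not None and not region.contains(a.residue_number):
                continue
            if atom_filter is not None and a.name != atom_filter:
                continue
            idx.append(i)
        return np.array(idx, dtype=int)

    def ca_indices(self) -> np.ndarray:
        return self.atom_indices(atom_filter="CA")

    def with_coords(self, coords: np.ndarray) -> "ProteinStructure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate shape {coords.shape} incompatible with "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, coordinates=c) for a, c in zip(self.atoms, coords)]
        return ProteinStructure(atoms, self.annotations, self.bonds)

    def residue_name_of(self, residue_number: int) -> str:
        for a in self.atoms:
            if a.residue_number == residue_number:
                return a.residue_name
        raise KeyError(residue_number)


# ---------------------------------------------------------------------------
# Reading


def _validate_atom_lines(path: Path) -> None:
    """Fail early, with a line number, on unparseable ATOM coordinates."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}, line {lineno}: ATOM record too short for coordinates"
                )
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"{path}, line {lineno}: malformed coordinate field in "
                    f"ATOM record: {line.rstrip()!r}"
                ) from None


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest occupancy wins; ties broken by altloc identifier order."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    out = []
    for name, group in by_name.items():
        out.append(min(group, key=lambda a: (-a.occ, a.altloc)))
    return out


def read_pdb(path: str | Path, model_index: int = 0) -> ProteinStructure:
    """Read one model of a (possibly multi-model NMR) PDB file.

    Returns heavy atoms of the first chain only; hydrogens, waters and
    non-amino-acid heteroatoms are dropped.  ``model_index`` is 0-based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_atom_lines(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")
    if not 0 <= model_index < len(st):
        raise IndexError(
            f"model_index {model_index} out of range: file has {len(st)} model(s)"
        )
    model = st[model_index]
    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for residue in chain:
            if residue.name in _WATER_NAMES:
                continue
            info = gemmi.find_tabulated_residue(residue.name)
            if info is not None and not info.is_amino_acid():
                continue
            for atom in sorted(
                _resolve_altlocs(residue), key=lambda a: a.serial
            ):
                if atom.element.is_hydrogen:
                    continue
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        element=atom.element.name.upper(),
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        coordinates=np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z]
                        ),
                    )
                )
        if atoms:
            break  # single-chain contract: first chain with amino acids
    if not atoms:
        raise PDBParseError(f"{path}: no amino-acid heavy atoms found")
    return ProteinStructure(atoms)


def read_ensemble(path: str | Path) -> list[ProteinStructure]:
    """Read every model of a multi-model PDB file as a conformer ensemble."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    return [read_pdb(path, model_index=i) for i in range(len(st))]


# ---------------------------------------------------------------------------
# Radii


def load_radius_set(name_or_path: str | Path = "uatom19") -> dict:
    """Load a radius table, either shipped by name or from a JSON path."""
    p = Path(name_or_path)
    if p.suffix == ".json" and p.exists():
        return json.loads(p.read_text())
    ref = resources.files("gofold.data").joinpath(f"{name_or_path}.json")
    try:
        return json.loads(ref.read_text())
    except FileNotFoundError:
        raise FileNotFoundError(
            f"unknown radius set {name_or_path!r}"
        ) from None


def load_b2m_regions() -> dict:
    """Shipped region constants for human beta-2 microglobulin.

    Returns a dict with ``wt_strands`` / ``dn6_strands`` (RegionSpec per
    beta-strand, deposited numbering), the ``core`` region (residues
    21-94) and the 21-residue ``hydrophobic_core`` list of
    (residue_number, residue_name) pairs.
    """
    raw = json.loads(
        resources.files("gofold.data").joinpath("b2m_regions.json").read_text()
    )
    return {
        "wt_strands": {
            k: RegionSpec(k, v) for k, v in raw["wt_strands"].items()
        },
        "dn6_strands": {
            k: RegionSpec(k, v) for k, v in raw["dn6_strands"].items()
        },
        "core": RegionSpec("core", raw["core"]),
        "hydrophobic_core": [
            (int(r), str(n)) for r, n in raw["hydrophobic_core_residues"]
        ],
    }


def _radius_for(residue_name: str, atom_name: str, element: str, table: dict):
    element = element.upper()
    if element == "C":
        cr = table["carbon_radii"]
        bare = table.get("bare_carbons", {})
        if atom_name in bare.get("*", []) or atom_name in bare.get(
            residue_name, []
        ):
            return cr["bare"]
        if atom_name in table.get("aromatic_ch_carbons", {}).get(
            residue_name, []
        ):
            return cr["aromatic_ch"]
        return cr["aliphatic_ch"]
    return table["element_defaults"].get(element)


def assign_radii(
    structure: ProteinStructure,
    radius_set: str | Path | Mapping = "uatom19",
) -> ProteinStructure:
    """Return a copy of *structure* with united-atom vdW radii assigned.

    Idempotent: reassigning with the same table reproduces the same radii.
    """
    table = (
        dict(radius_set)
        if isinstance(radius_set, Mapping)
        else load_radius_set(radius_set)
    )
    atoms = []
    unresolved = []
    for a in structure.atoms:
        r = _radius_for(a.residue_name, a.name, a.element, table)
        if r is None:
            unresolved.append(f"{a.residue_name}{a.residue_number}:{a.name}")
            continue
        atoms.append(replace(a, vdw_radius=float(r)))
    if unresolved:
        raise ValueError(
            "radius set cannot resolve atoms: " + ", ".join(unresolved)
        )
    return ProteinStructure(atoms, structure.annotations, structure.bonds)


# ---------------------------------------------------------------------------
# Editing and writing


def truncate_n_terminus(
    structure: ProteinStructure, first_kept_residue: int
) -> ProteinStructure:
    """Drop all residues numbered below *first_kept_residue*.

    Mirrors N-terminally truncated variants such as DN6 beta-2 microglobulin
    (full-length minus the first six residues).  Annotations are re-clipped
    to the remaining span.
    """
    lo, hi = structure.residue_span
    if not lo <= first_kept_residue <= hi:
        raise ValueError(
            f"first_kept_residue {first_kept_residue} outside chain span "
            f"[{lo}, {hi}]"
        )
    kept_idx = [
        i for i, a in enumerate(structure.atoms)
        if a.residue_number >= first_kept_residue
    ]
    atoms = [structure.atoms[i] for i in kept_idx]
    kept_res = {a.residue_number for a in atoms}
    if len(kept_res) < 2:
        raise ValueError("truncation would leave fewer than 2 residues")
    annotations = {}
    for name, reg in structure.annotations.items():
        clipped = reg.clipped(first_kept_residue, hi)
        if clipped is not None:
            annotations[name] = clipped
    bonds = None
    if structure.bonds is not None:
        remap = {old: new for new, old in enumerate(kept_idx)}
        bonds = [
            (remap[i], remap[j])
            for i, j in structure.bonds
            if i in remap and j in remap
        ]
    return ProteinStructure(atoms, annotations, bonds)


def write_pdb(
    structure_or_ensemble: ProteinStructure | Sequence[ProteinStructure],
    path: str | Path,
) -> None:
    """Write a structure, or an ensemble as MODEL/ENDMDL blocks.

    Round-trip safe at PDB fixed-width precision (0.001 A).
    """
    if isinstance(structure_or_ensemble, ProteinStructure):
        ensemble = [structure_or_ensemble]
    else:
        ensemble = list(structure_or_ensemble)
        if not ensemble:
            raise ValueError("empty ensemble")
    for s in ensemble:
        if s.residue_span[1] > 9999:
            raise ValueError(
                "residue number exceeds 9999: PDB fixed-width overflow"
            )
        if len(s) > 99999:
            raise ValueError("atom count exceeds 99999: PDB fixed-width overflow")
    st = gemmi.Structure()
    st.name = "gofold"
    for m, s in enumerate(ensemble, start=1):
        model = gemmi.Model(m)
        chain = gemmi.Chain("A")
        cur_res = None
        for a in s.atoms:
            if cur_res is None or cur_res.seqid.num != a.residue_number:
                cur_res = gemmi.Residue()
                cur_res.name = a.residue_name
                cur_res.seqid = gemmi.SeqId(a.residue_number, " ")
                chain.add_residue(cur_res)
                cur_res = chain[-1]
            atom = gemmi.Atom()
            atom.name = a.name
            atom.serial = a.serial
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.coordinates)
            atom.occ = 1.0
            cur_res.add_atom(atom)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))
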