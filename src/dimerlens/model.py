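"""Coordinate models, file I/O and crystal-symmetry expansion.

A :class:`StructureModel` is a flat list of atoms plus optional crystal
metadata (unit cell, space group, symmetry operators).  Reading goes
through gemmi, so both PDB and mmCIF are supported; symmetry operators come
from the space-group symbol via gemmi's tables, or from explicit operator
lists supplied by a generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    chain_id: str
    residue_index: int
    residue_type: str   # 3-letter residue name
    atom_name: str
    element: str
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_water: bool = False


@dataclass
class SymmetryOp:
    """Rotation (fractional basis) and fractional translation."""

    rot: np.ndarray   # 3x3
    tran: np.ndarray  # 3

    def apply_frac(self, frac_xyz: np.ndarray) -> np.ndarray:
        return frac_xyz @ self.rot.T + self.tran

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rot, np.eye(3)) and np.allclose(self.tran, 0)


@dataclass
class StructureModel:
    atoms: list[Atom]
    coords: np.ndarray                     # (n, 3) Angstrom
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    symmetry_ops: list[SymmetryOp] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise StructureError("coords shape does not match atom count")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    # -- selections --------------------------------------------------------

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def mask(
        self,
        chain_id: str | None = None,
        atom_names: Iterable[str] | None = None,
        residue_range: tuple[int, int] | None = None,
        heavy_only: bool = False,
        exclude_water: bool = False,
    ) -> np.ndarray:
        names = {n.upper() for n in atom_names} if atom_names is not None else None
        out = np.zeros(len(self.atoms), dtype=bool)
        for i, a in enumerate(self.atoms):
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if names is not None and a.atom_name.upper() not in names:
                continue
            if residue_range is not None and not (
                residue_range[0] <= a.residue_index <= residue_range[1]
            ):
                continue
            if heavy_only and a.element.upper() == "H":
                continue
            if exclude_water and a.is_water:
                continue
            out[i] = True
        return out

    def subset(self, mask: np.ndarray) -> "StructureModel":
        idx = np.flatnonzero(mask)
        return StructureModel(
            [self.atoms[i] for i in idx],
            self.coords[idx],
            cell=self.cell,
            space_group=self.space_group,
            symmetry_ops=list(self.symmetry_ops),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        return StructureModel(
            list(self.atoms),
            self.coords @ np.asarray(rotation, float).T + np.asarray(translation, float),
            cell=self.cell,
            space_group=self.space_group,
            symmetry_ops=list(self.symmetry_ops),
        )

    def with_chain_ids(self, mapping: dict[str, str]) -> "StructureModel":
        atoms = [
            replace(a, chain_id=mapping.get(a.chain_id, a.chain_id)) for a in self.atoms
        ]
        return StructureModel(atoms, self.coords.copy(), self.cell,
                              self.space_group, list(self.symmetry_ops))

    # -- crystal helpers ----------------------------------------------------

    def unit_cell(self) -> gemmi.UnitCell:
        if self.cell is None:
            raise StructureError("model has no unit cell")
        return gemmi.UnitCell(*self.cell)


def space_group_operators(symbol: str) -> list[SymmetryOp]:
    """Symmetry operators for a Hermann-Mauguin space-group symbol."""
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise StructureError(
            f"unknown space group symbol {symbol!r}; use a Hermann-Mauguin "
            "symbol recognised by the crystallographic tables, e.g. 'P 1', "
            "'P 21 21 21', 'P 31 2 1', 'C 2 2 21'"
        )
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append(SymmetryOp(rot, tran))
    return ops


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper()
    if el and el != "X":
        return el
    name = atom.name.strip()
    return name[:1].upper() if name else "C"


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer;
    waters are kept but flagged.  The format is inferred from the file
    unless ``fmt`` ("pdb" or "cif") is given.
    """
    path = Path(path)
    if fmt is None:
        st = gemmi.read_structure(str(path))
    else:
        fmt_map = {"pdb": gemmi.CoorFormat.Pdb, "cif": gemmi.CoorFormat.Mmcif,
                   "mmcif": gemmi.CoorFormat.Mmcif}
        if fmt.lower() not in fmt_map:
            raise StructureError(f"unsupported format {fmt!r}; use 'pdb' or 'cif'")
        st = gemmi.read_structure(str(path), format=fmt_map[fmt.lower()])
    st.setup_entities()

    atoms: list[Atom] = []
    coords: list[list[float]] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            # resolve altlocs: keep highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    Atom(
                        chain.name,
                        residue.seqid.num,
                        residue.name.strip().upper(),
                        atom.name.strip(),
                        _element_of(atom),
                        occupancy=atom.occ,
                        b_factor=atom.b_iso,
                        is_water=residue.name.strip().upper() in WATER_NAMES,
                    )
                )
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])

    cell = None
    space_group = None
    ops: list[SymmetryOp] = []
    if st.cell and st.cell.a > 1.0:  # gemmi uses a 1 A dummy cell when absent
        cell = (st.cell.a, st.cell.b, st.cell.c,
                st.cell.alpha, st.cell.beta, st.cell.gamma)
        if st.spacegroup_hm:
            space_group = st.spacegroup_hm
            ops = space_group_operators(space_group)
    return StructureModel(atoms, np.array(coords, float).reshape(-1, 3),
                          cell=cell, space_group=space_group, symmetry_ops=ops)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model in PDB format (CRYST1 record when a cell exists)."""
    lines: list[str] = []
    if model.cell is not None:
        a, b, c, al, be, ga = model.cell
        sg = (model.space_group or "P 1")[:11]
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} {sg:<11s}"
        )
    serial = 0
    for atom, (x, y, z) in zip(model.atoms, model.coords):
        serial += 1
        record = "HETATM" if atom.is_water else "ATOM  "
        name = atom.atom_name
        # PDB columns: 4-char atom name field, element-justified
        name_field = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
        lines.append(
            f"{record}{serial:5d} {name_field}{'':1s}{atom.residue_type:<3s} "
            f"{atom.chain_id[:1]}{atom.residue_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Symmetry expansion
# ---------------------------------------------------------------------------

def build_dimer_from_asu(
    model: StructureModel,
    contact_distance: float = 5.0,
    neighbor_cells: int = 1,
) -> StructureModel:
    """Reconstruct the crystallographic dimer from a single-chain ASU.

    Applies every symmetry operator over a ``(2*neighbor_cells+1)**3``
    block of neighboring unit cells, counts heavy-atom contacts (pairs
    closer than ``contact_distance``) between the original chain and each
    symmetry mate, and returns the original plus the most-contacting mate
    relabeled as chains A and B.
    """
    if model.cell is None or not model.symmetry_ops:
        raise StructureError("need a unit cell and symmetry operators to expand")
    cell = model.unit_cell()

    heavy = model.mask(heavy_only=True, exclude_water=True)
    sub = model.subset(heavy)
    frac = np.array([list(cell.fractionalize(gemmi.Position(*p))) for p in sub.coords])
    tree = cKDTree(sub.coords)

    shifts = range(-neighbor_cells, neighbor_cells + 1)
    best: tuple[int, np.ndarray] | None = None
    for op in model.symmetry_ops:
        base = op.apply_frac(frac)
        for dx in shifts:
            for dy in shifts:
                for dz in shifts:
                    if op.is_identity and dx == dy == dz == 0:
                        continue
                    f = base + np.array([dx, dy, dz], float)
                    cart = np.array(
                        [list(cell.orthogonalize(gemmi.Fractional(*p))) for p in f]
                    )
                    # reject self-images (operator acts as identity here)
                    if np.allclose(cart, sub.coords, atol=1e-6):
                        continue
                    n_contacts = sum(
                        len(hits) for hits in tree.query_ball_point(cart, contact_distance)
                    )
                    if n_contacts and (best is None or n_contacts > best[0]):
                        best = (n_contacts, cart)
    if best is None:
        raise StructureError(
            "monomeric packing: no symmetry mate within contact distance"
        )

    _, mate_coords = best
    a_atoms = [replace(a, chain_id="A") for a in sub.atoms]
    b_atoms = [replace(a, chain_id="B") for a in sub.atoms]
    return StructureModel(
        a_atoms + b_atoms,
        np.vstack([sub.coords, mate_coords]),
        cell=model.cell,
        space_group=model.space_group,
    )
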