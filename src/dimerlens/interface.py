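"""Dimer-interface geometry.

Interchain backbone hydrogen bonds, Shrake-Rupley solvent-accessible
surface area, buried interface area (half the SASA lost on complexation,
the PISA convention), least-squares rigid-body superposition, and the
beta-pairing register map with its integer shift statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._refdata import VDW_RADII, VDW_RADII_PROVENANCE
from .model import StructureModel, StructureError

#: geometric H-bond defaults.  Crystal structures at moderate resolution
#: carry no hydrogens, so the default criterion is donor-acceptor distance
#: N...O <= 3.5 A with the C-O...N angle in [90, 180] deg; when amide
#: hydrogens are present the N-H...O angle must additionally be >= 120 deg.
DEFAULT_HBOND_DMAX = 3.5
DEFAULT_HBOND_ANGLE_MIN = 120.0
DEFAULT_CON_ANGLE_RANGE = (90.0, 180.0)

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SASA_POINTS = 960


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, int, str]     # (chain, residue, atom)
    acceptor: tuple[str, int, str]
    distance_no: float              # Angstrom, N...O
    angle: float                    # deg; N-H...O if H present else C-O...N


@dataclass
class InterfaceReport:
    hbonds: list[HBond]
    buried_area: float                       # A^2
    register_map: list[tuple[int, int]]      # (res chain A, res chain B)
    radius_set: str = VDW_RADII_PROVENANCE
    probe_radius: float = DEFAULT_PROBE_RADIUS

    def to_text(self) -> str:
        lines = [
            f"# vdW radii: {self.radius_set}; probe {self.probe_radius:.2f} A",
            f"buried interface area: {self.buried_area:.1f} A^2",
            f"backbone H-bonds ({len(self.hbonds)}):",
        ]
        for hb in self.hbonds:
            d_c, d_r, d_a = hb.donor
            a_c, a_r, a_a = hb.acceptor
            lines.append(
                f"  {d_c}/{d_r}/{d_a} -> {a_c}/{a_r}/{a_a}"
                f"  d(N..O)={hb.distance_no:.2f} A  angle={hb.angle:.1f} deg"
            )
        lines.append(
            "register map: " + ", ".join(f"({i},{j})" for i, j in self.register_map)
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Backbone hydrogen bonds
# ---------------------------------------------------------------------------

def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def backbone_hbonds(
    dimer: StructureModel,
    d_max: float = DEFAULT_HBOND_DMAX,
    angle_min: float = DEFAULT_HBOND_ANGLE_MIN,
    con_angle_range: tuple[float, float] = DEFAULT_CON_ANGLE_RANGE,
) -> list[HBond]:
    """Interchain backbone amide-to-carbonyl hydrogen bonds.

    A donor backbone N of one chain is paired with an acceptor backbone O
    of another chain when N...O <= ``d_max``.  With an amide hydrogen
    present the N-H...O angle must be >= ``angle_min``; without hydrogens
    the C-O...N angle must fall inside ``con_angle_range``.  Each donor
    reports at most one bond (the shortest qualifying N...O).
    """
    chains = dimer.chains
    if len(chains) < 2:
        raise StructureError("need >= 2 chains for interchain hydrogen bonds")
    if d_max <= 0:
        return []

    # index backbone atoms per (chain, residue)
    n_atoms: dict[tuple[str, int], int] = {}
    h_atoms: dict[tuple[str, int], int] = {}
    o_atoms: dict[tuple[str, int], int] = {}
    c_atoms: dict[tuple[str, int], int] = {}
    for i, a in enumerate(dimer.atoms):
        if a.is_water:
            continue
        key = (a.chain_id, a.residue_index)
        name = a.atom_name.upper()
        if name == "N":
            n_atoms[key] = i
        elif name in ("H", "HN"):
            h_atoms[key] = i
        elif name == "O":
            o_atoms[key] = i
        elif name == "C":
            c_atoms[key] = i

    o_keys = list(o_atoms)
    if not o_keys or not n_atoms:
        return []
    o_tree = cKDTree(dimer.coords[[o_atoms[k] for k in o_keys]])

    bonds: list[HBond] = []
    for nkey, ni in sorted(n_atoms.items()):
        npos = dimer.coords[ni]
        candidates = []
        for oi in o_tree.query_ball_point(npos, d_max):
            okey = o_keys[oi]
            if okey[0] == nkey[0]:
                continue  # interfacial bonds only
            opos = dimer.coords[o_atoms[okey]]
            dist = float(np.linalg.norm(npos - opos))
            if nkey in h_atoms:
                ang = _angle(npos, dimer.coords[h_atoms[nkey]], opos)
                if ang < angle_min:
                    continue
            else:
                ci = c_atoms.get(okey)
                if ci is None:
                    continue
                ang = _angle(dimer.coords[ci], opos, npos)
                if not (con_angle_range[0] <= ang <= con_angle_range[1]):
                    continue
            candidates.append((dist, okey, ang))
        if candidates:
            dist, okey, ang = min(candidates)
            bonds.append(
                HBond((nkey[0], nkey[1], "N"), (okey[0], okey[1], "O"), dist, ang)
            )
    return bonds


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_radii(model: StructureModel, radii: Mapping[str, float] | None = None) -> np.ndarray:
    table = radii or VDW_RADII
    out = np.empty(len(model.atoms))
    for i, a in enumerate(model.atoms):
        el = a.element.upper()
        if el not in table:
            raise StructureError(
                f"unknown element {el!r} for atom {a.chain_id}/{a.residue_index}/{a.atom_name}"
            )
        out[i] = table[el]
    return out


def sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
    radii: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    Each atom's accessible sphere (vdW radius + probe) is sampled on a
    deterministic golden-spiral point set; points inside any neighbour's
    accessible sphere are occluded.  The per-atom area is the exposed
    fraction times the sphere area.
    """
    if n_points < 64:
        raise ValueError("n_points must be >= 64 for a usable quadrature")
    r = atom_radii(model, radii) + probe
    coords = model.coords
    n = len(model.atoms)
    unit = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    out = np.zeros(n)
    max_reach = 2.0 * r.max()
    for i in range(n):
        pts = coords[i] + r[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], max_reach):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > r[j] ** 2
            if not exposed.any():
                break
        out[i] = 4.0 * math.pi * r[i] ** 2 * exposed.sum() / n_points
    return out


def interface_area(
    dimer: StructureModel,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
    radii: Mapping[str, float] | None = None,
) -> float:
    """Buried interface area of a two-chain complex (A^2).

    ``(SASA_A + SASA_B - SASA_AB) / 2`` over non-water atoms — half the
    total surface buried on complexation, the convention of interface
    servers such as PISA.
    """
    dry = dimer.subset(dimer.mask(exclude_water=True))
    chains = dry.chains
    if len(chains) != 2:
        raise StructureError(f"interface_area needs exactly 2 chains, got {chains}")
    a = dry.subset(dry.mask(chain_id=chains[0]))
    b = dry.subset(dry.mask(chain_id=chains[1]))
    area_a = sasa(a, probe, n_points, radii).sum()
    area_b = sasa(b, probe, n_points, radii).sum()
    area_ab = sasa(dry, probe, n_points, radii).sum()
    return max(0.0, (area_a + area_b - area_ab) / 2.0)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass
class Superposition:
    rmsd: float
    rotation: np.ndarray      # 3x3, applied to mobile
    translation: np.ndarray   # 3
    n_atoms: int
    selection: str = ""


def _pair_selections(
    mobile: StructureModel,
    target: StructureModel,
    atom_names: Sequence[str],
    residue_range: tuple[int, int] | None,
) -> tuple[np.ndarray, np.ndarray]:
    def index(m: StructureModel) -> dict[tuple[int, str], int]:
        out = {}
        for i, a in enumerate(m.atoms):
            if a.is_water or a.atom_name.upper() not in {n.upper() for n in atom_names}:
                continue
            if residue_range and not (residue_range[0] <= a.residue_index <= residue_range[1]):
                continue
            out[(a.residue_index, a.atom_name.upper())] = i
        return out

    im, it = index(mobile), index(target)
    shared = sorted(set(im) & set(it))
    only_m = sorted(set(im) - set(it))
    only_t = sorted(set(it) - set(im))
    if len(shared) < 3:
        msg = f"need >= 3 paired atoms, found {len(shared)}"
        if only_m or only_t:
            msg += f"; unpaired mobile {only_m[:5]}, unpaired target {only_t[:5]}"
        raise StructureError(msg)
    return (
        mobile.coords[[im[k] for k in shared]],
        target.coords[[it[k] for k in shared]],
    )


def superpose(
    mobile: StructureModel,
    target: StructureModel,
    atom_names: Sequence[str] = ("CA",),
    residue_range: tuple[int, int] | None = (6, 68),
) -> Superposition:
    """Optimal rigid-body superposition of ``mobile`` onto ``target``.

    Atoms are paired by (residue index, atom name) over the selection;
    the rotation is the Kabsch SVD solution with reflection correction.
    The default selection (Calpha of residues 6-68) matches chemokine
    models whose flexible N-terminal residues are unmodelled.
    """
    x, y = _pair_selections(mobile, target, atom_names, residue_range)
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    u, _, vt = np.linalg.svd(x0.T @ y0)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    rot = (u @ correction @ vt).T
    trans = yc - rot @ xc
    moved = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    sel = f"{'+'.join(atom_names)}"
    if residue_range:
        sel += f" {residue_range[0]}-{residue_range[1]}"
    return Superposition(rmsd, rot, trans, len(x), sel)


# ---------------------------------------------------------------------------
# Beta-pairing register
# ---------------------------------------------------------------------------

def register_map(
    dimer: StructureModel,
    hbonds: list[HBond] | None = None,
    **hbond_kwargs,
) -> list[tuple[int, int]]:
    """Interchain backbone pairings as (residue in chain A, residue in B).

    Reduces the interchain H-bond list to residue pairs: a bond donated by
    chain A residue i to chain B residue j, or by B residue j to A residue
    i, both map to the tuple ``(i, j)``.  Pairs are deduplicated and
    sorted by the chain-A residue.
    """
    if hbonds is None:
        hbonds = backbone_hbonds(dimer, **hbond_kwargs)
    chains = dimer.chains
    if not hbonds:
        return []
    first = chains[0]
    pairs = set()
    for hb in hbonds:
        if hb.donor[0] == first:
            pairs.add((hb.donor[1], hb.acceptor[1]))
        else:
            pairs.add((hb.acceptor[1], hb.donor[1]))
    return sorted(pairs)


def register_shift(
    map_a: Sequence[tuple[int, int]],
    map_b: Sequence[tuple[int, int]],
    window: tuple[int, int] = (5, 15),
) -> int:
    """Integer register offset between two dimer pairing maps.

    Each pairing (i, j) has center (i + j) / 2; the offset is the median
    difference of centers, map B minus map A, rounded to the nearest
    integer.  Positive means the pairing center of B sits toward the
    C-terminus relative to A.  Both maps are restricted to ``window``
    (default the N-terminal interface, residues 5-15).
    """
    def centers(m: Sequence[tuple[int, int]]) -> list[float]:
        return [
            (i + j) / 2.0 for i, j in m
            if window[0] <= i <= window[1] and window[0] <= j <= window[1]
        ]

    ca, cb = centers(map_a), centers(map_b)
    if not ca or not cb:
        raise StructureError(
            f"no pairings inside the residue window {window} in one of the maps"
        )
    return round(median(cb) - median(ca))
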