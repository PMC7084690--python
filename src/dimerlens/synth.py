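"""Synthetic ground-truth generators.

Every analysis stage in this package gets a generator that produces inputs
with known truth: shift tables with a designed secondary-structure
pattern, mono-exponential relaxation decays on the standard delay grids,
idealized antiparallel beta-strand dimers with a controllable pairing
register, and pseudo-atom sphere fixtures for analytic surface-area
oracles.

All generators are pure functions of their arguments and seed: the same
call produces byte-identical output.  Truth objects are returned next to
each dataset so tests never re-derive ground truth from generator
internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._refdata import (
    R1_DELAYS_S,
    R2_DELAYS_S,
    RANDOM_COIL_CA_CB,
    ccl5_12aaa14_seq,
    ccl5_topology,
)
from .model import Atom, StructureModel, SymmetryOp
from .relax import DecaySeries
from .shifts import COIL, HELIX, STRAND, ShiftEntry, ShiftTable

#: class centers (ppm) of the smoothed CA-CB index per secondary-structure
#: class — synthetic conventions mirroring typical secondary-shift
#: magnitudes, split evenly between the CA and CB deviations.
INDEX_CENTERS = {"H": +3.0, "E": -3.0, "C": 0.0}

_LABEL_OF = {"H": HELIX, "E": STRAND, "C": COIL}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


# ---------------------------------------------------------------------------
# Shift tables
# ---------------------------------------------------------------------------

def gen_shift_table(
    topology: str | None = None,
    sequence: str | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    include_amide: bool = True,
) -> tuple[ShiftTable, dict[int, str]]:
    """Shift table with a designed secondary-structure pattern.

    ``topology`` is a per-residue string over {H, E, C}; the default is
    the chemokine fold layout (three strands 24-28/39-43/46-51 and a
    C-terminal helix 56-66 over 68 residues).  The CA-CB index is drawn
    around +3 ppm (helix), -3 ppm (strand) or 0 (coil), split evenly
    between CA and CB, plus independent Gaussian noise of ``noise_sd`` on
    each carbon.  Returns the table and the truth labels.
    """
    if topology is None:
        topology = ccl5_topology()
    if sequence is None:
        sequence = ccl5_12aaa14_seq(with_met0=False)[: len(topology)]
    if len(sequence) < len(topology):
        raise ValueError("sequence shorter than topology")
    bad = set(topology) - set("HEC")
    if bad:
        raise ValueError(f"topology must use H/E/C, found {sorted(bad)}")

    rng = np.random.default_rng(seed)
    entries: list[ShiftEntry] = []
    truth: dict[int, str] = {}
    for i, (ss, aa) in enumerate(zip(topology, sequence), start=1):
        center = INDEX_CENTERS[ss]
        truth[i] = _LABEL_OF[ss]
        rc = RANDOM_COIL_CA_CB[aa]
        d_ca = center / 2.0 + rng.normal(0.0, noise_sd)
        entries.append(ShiftEntry(i, aa, "CA", rc["CA"] + d_ca))
        if aa != "G":
            d_cb = -center / 2.0 + rng.normal(0.0, noise_sd)
            entries.append(ShiftEntry(i, aa, "CB", rc["CB"] + d_cb))
        if include_amide:
            entries.append(ShiftEntry(i, aa, "H", 8.3 + rng.normal(0.0, 0.02)))
            entries.append(ShiftEntry(i, aa, "N", 119.0 + rng.normal(0.0, 0.2)))
    return ShiftTable(entries), truth


def perturb_shift_table(
    table: ShiftTable,
    perturbations: Mapping[int, tuple[float, float]],
) -> ShiftTable:
    """Copy of a shift table with designed amide perturbations.

    ``perturbations`` maps residue -> (dH, dN) in ppm, added to the H and
    N entries; carbons are untouched.  Useful for building CSP test pairs
    with known combined shifts.
    """
    entries = []
    for e in table.entries:
        dh, dn = perturbations.get(e.residue_index, (0.0, 0.0))
        if e.atom == "H" and dh:
            e = ShiftEntry(e.residue_index, e.residue_type, e.atom, e.shift + dh)
        elif e.atom == "N" and dn:
            e = ShiftEntry(e.residue_index, e.residue_type, e.atom, e.shift + dn)
        entries.append(e)
    return ShiftTable(entries)


# ---------------------------------------------------------------------------
# Relaxation decays
# ---------------------------------------------------------------------------

def gen_decays(
    rates: Mapping[int, float],
    kind: str = "R2",
    noise_frac: float = 0.0,
    amplitude: float = 100.0,
    delays_s: Sequence[float] | None = None,
    seed: int = 0,
) -> list[DecaySeries]:
    """Mono-exponential decay curves with multiplicative Gaussian noise.

    ``I(t) = I0 exp(-R t) (1 + eps)`` with ``eps ~ N(0, noise_frac)``.
    Default delay grids are the standard longitudinal (R1) and transverse
    (R2) series of the CCL5 measurements.
    """
    if any(r <= 0 for r in rates.values()):
        raise ValueError("rates must be positive")
    if delays_s is None:
        delays_s = R1_DELAYS_S if kind.upper() == "R1" else R2_DELAYS_S
    t = np.asarray(delays_s, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for res in sorted(rates):
        clean = amplitude * np.exp(-rates[res] * t)
        noisy = clean * (1.0 + rng.normal(0.0, noise_frac, size=t.shape)) \
            if noise_frac > 0 else clean
        out.append(DecaySeries(res, t.copy(), noisy, kind=kind.upper()))
    return out


# ---------------------------------------------------------------------------
# Idealized antiparallel beta dimers
# ---------------------------------------------------------------------------

#: flat-sheet template constants (Angstrom): residue rise along the strand,
#: donor-acceptor N...O gap across the interface, carbonyl C=O length, and
#: in-plane offsets of backbone atoms from the Calpha x-position.
STRAND_RISE = 3.4
NO_GAP = 2.9
CO_LENGTH = 1.23
NO_X_OFFSET = 0.8
FACE_Y = 1.0


@dataclass
class BetaDimer:
    """An idealized two-chain antiparallel beta pairing with known truth."""

    dimer: StructureModel
    truth_pairs: list[tuple[int, int]]
    pairing_sum: int                 # i + j of every facing pair
    asu: StructureModel = field(repr=False, default=None)  # chain A + operator


def gen_beta_dimer(
    n_residues: int = 17,
    register_offset: int = 0,
    hbond_positions: Sequence[int] | None = None,
    with_hydrogens: bool = False,
) -> BetaDimer:
    """Two-chain idealized antiparallel beta-strand dimer.

    Chain A runs along +x; chain B is its exact two-fold image (180 deg
    about z), so residue i of A faces residue ``c - i`` of B where the
    pairing sum ``c = n_residues + 1 + 2 * register_offset``.  Residues in
    ``hbond_positions`` (chain-A numbering; the set must be symmetric
    under ``i -> c - i``) point their amide N and carbonyl O across the
    interface at N...O = 2.9 A, producing two hydrogen bonds per facing
    pair; all other residues point away.  The default positions form an
    alternating ladder around the pairing center, as in a real
    antiparallel sheet.

    Returns the dimer, the truth register map, and a single-chain ASU
    model carrying the two-fold as an explicit symmetry operator (for
    symmetry-expansion round trips).  Use an odd ``n_residues`` so the
    pairing sum stays even and the two-fold maps the position set onto
    itself.
    """
    if n_residues < 4:
        raise ValueError("need >= 4 residues per strand")
    c = n_residues + 1 + 2 * register_offset
    if hbond_positions is None:
        center = c // 2
        hbond_positions = [
            i for i in range(1, n_residues + 1)
            if 1 <= c - i <= n_residues
            # alternate positions when the pairing sum is even (odd sums
            # cannot alternate symmetrically under i -> c - i)
            and (c % 2 == 1 or (i - center) % 2 == 0)
        ]
    pos_set = set(hbond_positions)
    if any(not (1 <= i <= n_residues) for i in pos_set):
        raise ValueError("hbond positions outside the strand")
    if {c - i for i in pos_set if 1 <= c - i <= n_residues} - pos_set:
        raise ValueError("hbond position set must be symmetric under i -> c - i")

    def strand_atoms() -> tuple[list[Atom], np.ndarray]:
        atoms: list[Atom] = []
        xyz: list[tuple[float, float, float]] = []

        def add(res: int, name: str, element: str, x: float, y: float) -> None:
            atoms.append(Atom("A", res, "GLY", name, element))
            xyz.append((x, y, 0.0))

        for i in range(1, n_residues + 1):
            x0 = STRAND_RISE * i
            facing = i in pos_set
            sign = 1.0 if facing else -1.0
            add(i, "N", "N", x0 - NO_X_OFFSET, sign * FACE_Y)
            if with_hydrogens:
                add(i, "H", "H", x0 - NO_X_OFFSET, sign * (FACE_Y + 1.0))
            add(i, "CA", "C", x0, 0.5 * sign)
            add(i, "C", "C", x0 + NO_X_OFFSET, sign * (FACE_Y - CO_LENGTH))
            add(i, "O", "O", x0 + NO_X_OFFSET, sign * FACE_Y)
        return atoms, np.array(xyz, dtype=float)

    a_atoms, a_xyz = strand_atoms()

    # two-fold axis parallel to z through (cx, cy): maps A onto B so that
    # A_i faces B_{c-i} across an N...O gap of NO_GAP.
    cx = STRAND_RISE * c / 2.0
    cy = (2.0 * FACE_Y + NO_GAP) / 2.0
    rot = np.diag([-1.0, -1.0, 1.0])
    tran_cart = np.array([2.0 * cx, 2.0 * cy, 0.0])
    b_xyz = a_xyz @ rot.T + tran_cart
    b_atoms = [Atom("B", a.residue_index, a.residue_type, a.atom_name, a.element)
               for a in a_atoms]

    dimer = StructureModel(a_atoms + b_atoms, np.vstack([a_xyz, b_xyz]))
    truth = sorted((i, c - i) for i in pos_set if 1 <= c - i <= n_residues)

    # single-chain ASU in a box cell with the explicit two-fold operator
    cell = (
        max(200.0, 2 * cx + 20.0),
        max(100.0, 2 * cy + 20.0),
        50.0, 90.0, 90.0, 90.0,
    )
    a_len, b_len, _ = cell[0], cell[1], cell[2]
    ops = [
        SymmetryOp(np.eye(3), np.zeros(3)),
        SymmetryOp(rot.copy(), np.array([2.0 * cx / a_len, 2.0 * cy / b_len, 0.0])),
    ]
    asu = StructureModel(list(a_atoms), a_xyz.copy(), cell=cell,
                         space_group="P 1", symmetry_ops=ops)
    return BetaDimer(dimer, truth, c, asu)


# ---------------------------------------------------------------------------
# Sphere fixtures
# ---------------------------------------------------------------------------

def gen_sphere_fixture(
    radii: Sequence[float],
    centers: Sequence[Sequence[float]],
) -> tuple[StructureModel, dict[str, float]]:
    """Pseudo-atom spheres for analytic surface-area tests.

    Each sphere becomes one atom with a synthetic element symbol carrying
    its radius; returns the model and the matching radius table to pass to
    the SASA routines.
    """
    if len(radii) != len(centers):
        raise ValueError("radii and centers differ in length")
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    atoms = []
    table: dict[str, float] = {}
    for k, r in enumerate(radii):
        el = f"Z{k}"
        table[el] = float(r)
        chain = "A" if k < len(radii) / 2 or len(radii) == 1 else "B"
        atoms.append(Atom(chain, k + 1, "SPH", "X", el))
    coords = np.asarray(centers, dtype=float).reshape(len(radii), 3)
    return StructureModel(atoms, coords), table


def sphere_cap_buried_area(r1: float, r2: float, d: float, probe: float) -> float:
    """Analytic buried area of two intersecting accessible spheres.

    For accessible radii ``R1 = r1 + probe`` and ``R2 = r2 + probe`` at
    center distance ``d``, each sphere loses a spherical cap; the
    function returns half the total lost area, matching the
    interface-area convention.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 0.0
    # cap heights from the standard two-sphere intersection geometry
    h1 = (R2 - (d - R1)) * (R2 + d - R1) / (2 * d) if d > abs(R1 - R2) else 2 * R1
    h2 = (R1 - (d - R2)) * (R1 + d - R2) / (2 * d) if d > abs(R1 - R2) else 2 * R2
    cap1 = 2 * math.pi * R1 * min(h1, 2 * R1)
    cap2 = 2 * math.pi * R2 * min(h2, 2 * R2)
    return (cap1 + cap2) / 2.0
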