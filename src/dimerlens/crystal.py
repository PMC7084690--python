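"""Crystal-content arithmetic: Matthews coefficient and solvent fraction.

V_M = V_cell / (Z * M_chain) with Z = (symmetry operators) x (chains per
asymmetric unit); the solvent fraction follows from the standard protein
partial specific volume, 1 / (0.74 cm^3/g * rho) ~= 1.230 A^3/Da of
ordered protein per Dalton:

    f_solvent = 1 - 1.230 / V_M
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi

from ._refdata import RESIDUE_MASS_AVG, WATER_MASS_AVG
from .model import StructureError, space_group_operators

PROTEIN_VOLUME_PER_DALTON = 1.230  # A^3/Da


@dataclass
class CrystalContent:
    matthews_vm: float       # A^3/Da
    solvent_fraction: float  # 0..1
    z_molecules: int
    chain_mass: float        # Da
    cell_volume: float       # A^3


def chain_mass_average(sequence: str) -> float:
    """Average-isotopic mass (Da) of a peptide chain from its 1-letter sequence.

    Residue masses are monomer masses minus one water per peptide bond;
    one water is added back for the free termini.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    total = WATER_MASS_AVG
    for aa in seq:
        try:
            total += RESIDUE_MASS_AVG[aa]
        except KeyError:
            raise ValueError(f"unknown residue code {aa!r}") from None
    return total


def crystal_content(
    cell: tuple[float, float, float, float, float, float],
    space_group: str,
    sequence: str,
    z_per_asu: int = 1,
) -> CrystalContent:
    """Matthews coefficient and solvent content of a crystal form.

    ``cell`` is (a, b, c, alpha, beta, gamma) in Angstrom/degrees; the
    cell volume uses the general triclinic formula; Z is the number of
    space-group operators times ``z_per_asu`` chains.
    """
    if z_per_asu < 1:
        raise ValueError("z_per_asu must be >= 1")
    volume = gemmi.UnitCell(*cell).volume
    n_ops = len(space_group_operators(space_group))
    z = n_ops * z_per_asu
    mass = chain_mass_average(sequence)
    vm = volume / (z * mass)
    if vm <= PROTEIN_VOLUME_PER_DALTON:
        raise StructureError(
            f"impossible packing: V_M = {vm:.3f} A^3/Da <= {PROTEIN_VOLUME_PER_DALTON}"
        )
    solvent = 1.0 - PROTEIN_VOLUME_PER_DALTON / vm
    return CrystalContent(vm, solvent, z, mass, volume)
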