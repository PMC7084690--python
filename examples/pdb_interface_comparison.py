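"""Interface comparison on deposited crystal structures.

Usage:  python pdb_interface_comparison.py MUTANT.pdb [WILDTYPE.pdb]

Point this at locally downloaded coordinate files (e.g. PDB entries 6LOG
for the CCL5-12AAA14 crystal and 1EQT for the wild-type CCL5 dimer).
A single-chain asymmetric unit is expanded to the crystallographic dimer
before analysis.  With two files it also superposes the monomers (Calpha
of residues 6-68) and reports the N-terminal pairing register shift.
"""

import sys

import dimerlens as dl


def load_dimer(path: str) -> dl.StructureModel:
    model = dl.read_structure(path)
    dry = model.subset(model.mask(exclude_water=True))
    if len(dry.chains) < 2:
        print(f"{path}: single chain in ASU; expanding by crystal symmetry")
        return dl.build_dimer_from_asu(model)
    first_two = dry.chains[:2]
    keep = dry.mask(chain_id=first_two[0]) | dry.mask(chain_id=first_two[1])
    return dry.subset(keep)


if len(sys.argv) < 2:
    sys.exit(__doc__)

dimer_a = load_dimer(sys.argv[1])
area_a = dl.interface_area(dimer_a)
map_a = dl.register_map(dimer_a)
print(f"{sys.argv[1]}: buried interface {area_a:.0f} A^2, pairing {map_a}")

if len(sys.argv) > 2:
    dimer_b = load_dimer(sys.argv[2])
    area_b = dl.interface_area(dimer_b)
    map_b = dl.register_map(dimer_b)
    print(f"{sys.argv[2]}: buried interface {area_b:.0f} A^2, pairing {map_b}")
    mono_a = dimer_a.subset(dimer_a.mask(chain_id=dimer_a.chains[0]))
    mono_b = dimer_b.subset(dimer_b.mask(chain_id=dimer_b.chains[0]))
    sup = dl.superpose(mono_a, mono_b)  # Calpha 6-68 by default
    print(f"monomer superposition RMSD ({sup.selection}): {sup.rmsd:.3f} A")
    print(f"register shift: {dl.register_shift(map_a, map_b)} residue(s)")
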