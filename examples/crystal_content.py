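"""Matthews coefficient and solvent content of a crystal form.

Uses the trigonal cell of the CCL5-12AAA14 crystal (a = b = 48.3 A,
c = 60.4 A, space group P3(1)21) with one 69-residue chain per
asymmetric unit.
"""

import dimerlens as dl
from dimerlens._refdata import ccl5_12aaa14_seq

seq = ccl5_12aaa14_seq(with_met0=True)
cc = dl.crystal_content((48.3, 48.3, 60.4, 90.0, 90.0, 120.0),
                        "P 31 2 1", seq, z_per_asu=1)
print(f"chain mass: {cc.chain_mass:.1f} Da ({len(seq)} residues)")
print(f"cell volume: {cc.cell_volume:.0f} A^3, Z = {cc.z_molecules}")
print(f"V_M = {cc.matthews_vm:.2f} A^3/Da")
print(f"solvent content = {100 * cc.solvent_fraction:.1f}%")
# V_M near 2.6 A^3/Da is typical protein packing (~50% solvent) and is the
# classic sanity check that one molecule per asymmetric unit is right.
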