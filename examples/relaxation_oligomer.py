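"""15N relaxation: decay fitting, tumbling time, oligomeric state.

Simulates 40 residues relaxing at dimer-regime rates (R1 = 1.26 1/s,
R2 = 11.47 1/s) with 2% noise on the standard delay grids, fits the
rates back, converts the R2/R1 ratio to a rotational correlation time at
a 600 MHz field, and classifies the oligomeric state.
"""

import numpy as np

import dimerlens as dl

residues = range(1, 41)
r1_series = dl.gen_decays({i: 1.26 for i in residues}, kind="R1",
                          noise_frac=0.02, seed=11)
r2_series = dl.gen_decays({i: 11.47 for i in residues}, kind="R2",
                          noise_frac=0.02, seed=12)

r1 = np.mean([f.rate for f in dl.fit_rates(r1_series) if f.ok])
r2 = np.mean([f.rate for f in dl.fit_rates(r2_series) if f.ok])
print(f"fitted means: R1 = {r1:.3f} 1/s, R2 = {r2:.3f} 1/s")

nu_n = dl.nitrogen_larmor_mhz(600.0)
est = dl.tau_c_from_ratio(r1, r2, nu_n)
call = dl.classify_oligomer(est)
print(f"R2/R1 = {est.r2_over_r1:.2f} -> tau_c = {est.tau_c_ns:.2f} ns "
      f"({est.formula_name})")
print(f"oligomeric state: {call.state}  [{call.basis}]")
# ~9 ns tumbling at this field is the dimer regime for an 8 kDa chemokine;
# a monomer would tumble near 4 ns (e.g. R1 = 2.26, R2 = 6.08).
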