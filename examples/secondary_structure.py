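"""Secondary-structure prediction from CA/CB chemical shifts.

Generates a synthetic shift table with the chemokine fold layout (three
beta strands at residues 24-28/39-43/46-51 and a C-terminal helix at
56-66) plus 1 ppm of noise, then recovers the fold from the smoothed
(d_dCA - d_dCB) index.
"""

import dimerlens as dl

table, truth = dl.gen_shift_table(noise_sd=1.0, seed=7)
profile = dl.predict_secondary_structure(table)

print(profile.to_dataframe().head(10).to_string(index=False))
frac = dl.recovery_fraction(truth, profile.labels)
print(f"\nreference set: {profile.reference_provenance}")
print(f"structured residues recovered: {100 * frac:.1f}%")
# The index is positive in helices and negative in strands; residues whose
# smoothed index stays within the +/-0.7 ppm deadband are called coil.
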