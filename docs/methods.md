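# Methods

This note documents the models behind each analysis, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the package's known limitations.

## Secondary-shift indexing

Backbone ¹³Cα and ¹³Cβ shifts deviate from their random-coil values in
opposite directions in helices and strands, so the per-residue index

    idx_i = (δ_obs,Cα − δ_rc,Cα) − (δ_obs,Cβ − δ_rc,Cβ)

is positive in α-helix and negative in β-strand. The index is smoothed
with a three-residue running mean, Δδᵢ = (Δδᵢ₋₁ + Δδᵢ + Δδᵢ₊₁)/3, and the
sign of the smoothed value calls the element.

Conventions and defaults:

* **Random-coil reference.** The shipped default is the Wishart/Sykes
  GGXGG peptide compilation (DSS-referenced); its provenance string is
  embedded in every profile and output header, and a user table can be
  supplied (`residue_type, atom, shift_ppm`). Absolute label positions
  depend on the reference set, which is why it is always recorded.
* **Chain termini and assignment gaps.** Real spectra lose residues to
  exchange broadening. The smoothing window averages over the members
  that exist instead of dropping the residue, so coverage is preserved;
  a residue with no own value stays undefined. Terminal residues are
  therefore two-point means — users comparing against plots made with a
  different end convention should note this.
* **Coil deadband, 0.7 ppm (configurable).** The sign rule alone
  over-calls structure on noisy data: typical Cα/Cβ measurement noise plus
  reference mismatch produces smoothed excursions of a few tenths of a
  ppm in genuine coil. 0.7 ppm is roughly a quarter of the typical
  structured-class amplitude (±3 ppm) and leaves the calls of genuinely
  structured runs untouched.
* **Glycine** has no Cβ; its ΔδCβ is taken as 0 so the index reduces to
  ΔδCα. The same fallback applies to a non-Gly residue whose Cβ is
  unassigned.
* Shifts outside [0, 250] ppm are rejected as a likely column mix-up.

## CSP mapping

For each residue present in both states, the signed amide differences
Δδ_H and Δδ_N (state A − state B) are kept for diagnostics and combined
as

    Δδ_NH = √((Δδ_H² + (Δδ_N/5)²) / 2)

The 1/5 factor puts the ¹⁵N scale on the ¹H scale before averaging.
Tiers count thresholds *strictly* exceeded; threshold sets are chosen per
experiment (mutation-scale: 0.25/0.5/1.0 ppm; ligand-titration scale:
0.05/0.1 ppm). Residues visible in only one state are reported as
unmatched, never dropped silently — a vanished peak is itself a result.

## ¹⁵N relaxation

Decays are fit per residue to I(t) = I₀·exp(−R·t) by nonlinear least
squares, initialized from a log-linear regression. The default residual
weighting is *relative* (σ ∝ intensity): peak-intensity errors in decay
series grow with the signal, and over the large dynamic range of a fast
transverse decay unweighted fitting mis-states the parameter uncertainty
(uniform weighting is available). Standard errors come from the fit's
curvature, scaled by the reduced χ²; non-convergent or negative-rate fits
are flagged and excluded from batch summaries rather than raised.
File delays are read in ms (the acquisition convention) and converted to
seconds; rates are always s⁻¹.

Protein-level averages use a trimmed mean (10 % per side) after excluding
residues with NOE < 0.6, which marks flexible tails whose rates do not
report overall tumbling. Both knobs are configurable; published averaged
values rarely state their exclusions, so ours are explicit.

The rotational correlation time uses the isotropic rigid-rotor
approximation

    τc ≈ √(6·R₂/R₁ − 7) / (4π·ν_N)

valid for ω_N·τc ≳ 1 when internal motion and exchange are negligible; the
formula name travels with every estimate so an alternative estimator can
be substituted and audited. The expression under the root must be
positive — small ratios mean sub-nanosecond tumbling where this inversion
is invalid, and the package raises (or returns an indeterminate call)
instead of extrapolating.

Oligomeric state is a deterministic interval lookup on τc. Defaults:
[3, 6.5) ns → monomer, [6.5, 10.5] ns → dimer, anything else →
higher-order/indeterminate. The anchors are the well-known regimes of an
~8 kDa chemokine (monomer ≈ 4 ns at 298 K; dimer ≈ 8–9 ns); the interval
*edges* are our choice, stated as defaults and user-overridable, because
published anchors do not define boundaries.

## Dimer-interface geometry

* **Symmetry expansion.** A single-chain asymmetric unit is expanded by
  applying every space-group operator (from the Hermann–Mauguin symbol
  via gemmi's tables, or explicit operators) over a 3×3×3 block of
  neighboring cells — contacts across one cell edge are possible, farther
  is not. The mate with the most heavy-atom contacts under 5 Å becomes
  chain B; no contacting mate means genuinely monomeric packing.
* **Backbone hydrogen bonds.** Crystal structures at moderate resolution
  carry no hydrogens, so the default criterion is geometric: donor
  N···acceptor O ≤ 3.5 Å with the C–O···N angle in [90°, 180°]; when an
  amide H is present the N–H···O angle must be ≥ 120°. Each donor
  reports at most its shortest qualifying bond. Only interchain bonds
  are considered. All cutoffs are configurable.
* **SASA.** Shrake–Rupley quadrature on a deterministic golden-spiral
  point set (default 960 points/atom, probe 1.4 Å) with the Bondi (1964)
  vdW radii; the radius-set provenance is embedded in reports. The
  quadrature error on a lone sphere is zero by construction (all points
  exposed) and total areas change < 0.5 % on doubling the point count.
* **Interface area** = (SASA_A + SASA_B − SASA_AB)/2 over non-water atoms
  — half the surface buried on complexation, the convention of interface
  servers. Comparisons with server values should allow ~15 %: point
  counts, radius sets and probe handling differ between implementations.
* **Superposition** pairs atoms by (residue, atom name) and solves the
  rotation by the Kabsch SVD construction with reflection correction.
  The default selection is Cα of residues 6–68, matching chemokine models
  whose first five residues are unmodelled; the selection used is always
  recorded in the result.
* **Register map and shift.** Interchain backbone H-bonds reduce to
  residue pairs (i of chain A, j of chain B). Each pair has center
  (i+j)/2 — for an antiparallel pairing the center is the invariant of
  the ladder — and the register shift between two dimers is the median
  difference of centers, rounded to the nearest integer, restricted to a
  residue window (default 5–15, the N-terminal interface of the CC-type
  chemokine dimer). Positive = the pairing center of the second dimer
  sits toward the C-terminus. The median makes the statistic robust to
  flank bonds.

## Crystal content

Cell volume from the general triclinic formula; Z = (space-group
operators) × (chains per ASU); chain mass from average isotopic residue
masses (plus one water for the termini) — the leading Met of recombinant
constructs is part of the sequence input, not an option flag. Then
V_M = V/(Z·m) and solvent fraction 1 − 1.230/V_M, using the standard
protein packing density of 1.230 Å³/Da. For the trigonal chemokine cell
shipped in the examples this yields V_M = 2.60 Å³/Da and 52.7 % solvent;
program suites that use a slightly different mass model print values a
point or two higher.

## Synthetic generators

All generators are pure functions of their arguments and seed.

* **Shift tables**: the CA−CB index is drawn around class centers of
  +3 ppm (helix), −3 ppm (strand), 0 (coil) — synthetic conventions
  mirroring typical secondary-shift magnitudes, split evenly between Cα
  and Cβ — plus independent Gaussian noise per carbon, on top of the
  shipped random-coil table. The default topology is the chemokine fold
  (strands 24–28, 39–43, 46–51; helix 56–66 over 68 residues). What this
  does *not* emulate: reference-set mismatch, residue-type-dependent
  shift dispersion, or missing assignments; recovery rates on synthetic
  tables are therefore upper bounds for real data.
* **Decays**: I₀·exp(−R·t) with multiplicative Gaussian noise on the
  standard longitudinal (5–1000 ms) and transverse (0–237.44 ms) delay
  grids. Real decays add exchange contributions and baseline artifacts
  that are out of scope.
* **β dimers**: a flat antiparallel two-strand template (3.4 Å rise,
  N···O 2.9 Å across the interface) in which chain B is the exact
  two-fold image of chain A, with the pairing register and the set of
  H-bonded positions designable; truth pairings are returned next to the
  model, and a single-chain version carries the generating operator for
  symmetry-expansion round trips. The template is idealized — no pleat,
  no side chains, no twist — because the quantities under test (bond
  counts, register arithmetic, area bookkeeping) depend on topology, not
  on fine geometry.
* **Spheres**: pseudo-atoms with arbitrary radii for the analytic SASA
  and buried-area oracles (isolated-sphere and two-sphere spherical-cap
  closed forms).

## Problem sizes

The shipped tests and the acceptance script use 68-residue shift tables,
17-residue strand dimers, and 200–500 simulated decays per condition —
sizes at which every check runs in seconds while the Monte-Carlo
statistics (bias below 1 %, 2·se coverage above 90 %) are stable across
seeds.

## Known limitations

* No model-free (Lipari–Szabo) analysis, anisotropic diffusion, or
  exchange decomposition; τc is the isotropic ratio estimate only.
* The oligomer call is a τc interval lookup; it cannot distinguish a
  tight dimer from a fast monomer–dimer equilibrium averaging to the same
  apparent τc.
* H-bond detection is purely geometric; bifurcated bonds report only the
  shortest acceptor per donor.
* Buried areas on real structures depend on the radius set and point
  density; values are comparable between runs of this package, and to
  other programs only within the tolerance noted above.
* Validation against deposited crystal structures requires the user to
  supply the coordinate files (see `examples/pdb_interface_comparison.py`);
  nothing is downloaded.
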