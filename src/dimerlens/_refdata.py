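"""Reference data shipped with dimerlens.

Every table here carries a provenance string that downstream code embeds in
its output headers, so a result can always be audited against the reference
set that produced it.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Random-coil 13C chemical shifts (ppm, DSS-referenced).
#
# Values from the Wishart & Sykes random-coil compilation commonly used for
# secondary-shift indexing (GGXGG peptides, 25 degC, pH 5).  Users may load
# their own table; the provenance string travels with every profile.
# ---------------------------------------------------------------------------

RANDOM_COIL_PROVENANCE = "Wishart1995-GGXGG-DSS"

# residue 1-letter -> {"CA": ppm, "CB": ppm}; Gly has no CB.
RANDOM_COIL_CA_CB: dict[str, dict[str, float]] = {
    "A": {"CA": 52.5, "CB": 19.1},
    "R": {"CA": 56.0, "CB": 30.9},
    "N": {"CA": 53.1, "CB": 38.9},
    "D": {"CA": 54.2, "CB": 41.1},
    "C": {"CA": 58.2, "CB": 28.0},
    "Q": {"CA": 55.7, "CB": 29.4},
    "E": {"CA": 56.6, "CB": 29.9},
    "G": {"CA": 45.1},
    "H": {"CA": 55.0, "CB": 29.0},
    "I": {"CA": 61.1, "CB": 38.8},
    "L": {"CA": 55.1, "CB": 42.4},
    "K": {"CA": 56.2, "CB": 33.1},
    "M": {"CA": 55.4, "CB": 32.9},
    "F": {"CA": 57.7, "CB": 39.6},
    "P": {"CA": 63.3, "CB": 31.7},
    "S": {"CA": 58.3, "CB": 63.8},
    "T": {"CA": 61.8, "CB": 69.8},
    "W": {"CA": 57.5, "CB": 29.6},
    "Y": {"CA": 57.9, "CB": 38.8},
    "V": {"CA": 62.2, "CB": 32.9},
}

# ---------------------------------------------------------------------------
# Van der Waals radii (Angstrom), Bondi (1964) set.
# ---------------------------------------------------------------------------

VDW_RADII_PROVENANCE = "Bondi1964"

VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

# ---------------------------------------------------------------------------
# Average (isotope-abundance weighted) amino-acid residue masses, Da.
# Residue mass = free amino acid minus one water (peptide-bond convention).
# ---------------------------------------------------------------------------

RESIDUE_MASS_AVG: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

WATER_MASS_AVG = 18.0153

# ---------------------------------------------------------------------------
# Relaxation delay grids (seconds).  These are the longitudinal (R1) and
# transverse (R2) delay series used for the CCL5 measurements this package
# was built around; they are the default grids of the decay simulator.
# ---------------------------------------------------------------------------

R1_DELAYS_S: tuple[float, ...] = (
    0.005, 0.010, 0.020, 0.040, 0.080, 0.150, 0.300, 0.600, 0.800, 1.000,
)

R2_DELAYS_S: tuple[float, ...] = (
    0.0, 0.01696, 0.03392, 0.05088, 0.06784, 0.0848,
    0.10176, 0.11872, 0.13568, 0.16960, 0.20352, 0.23744,
)

# ---------------------------------------------------------------------------
# Sequences.  Mature human CCL5 (residues 1-68, UniProt P13501 numbering of
# the secreted protein).  The recombinant constructs carry an extra starting
# Met (M0).  The 12AAA14 variant replaces F12 and Y14 by Ala.
# ---------------------------------------------------------------------------

CCL5_MATURE_SEQ = (
    "SPYSSDTTPCCFAYIARPLPRAHIKEYFYTSGKCSNPAVVFVTRKNRQVCANPEKKWVREYINSLEMS"
)


def ccl5_12aaa14_seq(with_met0: bool = True) -> str:
    """Sequence of the CCL5-12AAA14 double mutant (F12A, Y14A).

    With ``with_met0`` the construct's leading Met (M0) is included,
    matching the recombinant protein used for crystallization.
    """
    s = list(CCL5_MATURE_SEQ)
    assert s[11] == "F" and s[13] == "Y"
    s[11] = "A"
    s[13] = "A"
    seq = "".join(s)
    return ("M" + seq) if with_met0 else seq


# Secondary-structure layout of the CCL5 fold in one-letter DSSP-like codes
# (C coil, E strand, H helix), used by the synthetic shift generator:
# N-terminal extended region, three antiparallel beta strands
# (24-28, 39-43, 46-51) and the C-terminal helix (56-66), 68 residues.
def ccl5_topology(n_residues: int = 68) -> str:
    topo = ["C"] * n_residues
    for lo, hi in ((24, 28), (39, 43), (46, 51)):
        for i in range(lo, hi + 1):
            topo[i - 1] = "E"
    for i in range(56, 67):
        topo[i - 1] = "H"
    return "".join(topo[:n_residues])


# Gyromagnetic-ratio scale factor between 1H and 15N Larmor frequencies.
N15_TO_H1_FREQ_RATIO = 0.101329118
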