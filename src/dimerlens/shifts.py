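"""Chemical-shift arithmetic.

Two analyses live here:

* **Secondary-shift indexing** — the deviation of observed 13Ca/13Cb shifts
  from random-coil reference values reports backbone secondary structure.
  The per-residue index is ``(d_dCA - d_dCB)`` where ``d_d = d_obs - d_rc``;
  a three-residue running mean smooths it, and the sign calls the element
  (positive: helix, negative: strand), with a configurable deadband for the
  coil call.

* **Chemical-shift-perturbation (CSP) mapping** — amide 1H/15N shift changes
  between two states, combined per residue as

      d_dNH = sqrt((d_dH**2 + (d_dN / 5)**2) / 2)

  and binned into ordinal tiers against user thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._refdata import RANDOM_COIL_CA_CB, RANDOM_COIL_PROVENANCE

BACKBONE_ATOMS = ("H", "N", "CA", "CB")

HELIX, STRAND, COIL, UNDEFINED = "helix", "strand", "coil", "undefined"

#: default deadband (ppm) on the smoothed index inside which residues are
#: called coil rather than helix/strand; a zero deadband over-calls
#: structure on noisy data.
DEFAULT_DEADBAND = 0.7


class ShiftTableError(ValueError):
    """Malformed or inconsistent chemical-shift input."""


@dataclass(frozen=True)
class ShiftEntry:
    residue_index: int
    residue_type: str  # 1-letter code
    atom: str          # one of BACKBONE_ATOMS
    shift: float       # ppm


@dataclass
class ShiftTable:
    """Per-residue, per-atom backbone chemical shifts for one protein state."""

    entries: list[ShiftEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for e in self.entries:
            if e.residue_index <= 0:
                raise ShiftTableError(
                    f"residue_index must be positive, got {e.residue_index}"
                )
            if e.atom not in BACKBONE_ATOMS:
                raise ShiftTableError(f"unsupported atom {e.atom!r}")
            if e.residue_type == "G" and e.atom == "CB":
                raise ShiftTableError(
                    f"Gly residue {e.residue_index} cannot carry a CB shift"
                )
            key = (e.residue_index, e.atom)
            if key in seen:
                raise ShiftTableError(f"duplicate entry for residue {key[0]} atom {key[1]}")
            seen.add(key)

    # -- access helpers ---------------------------------------------------

    def residues(self) -> list[int]:
        return sorted({e.residue_index for e in self.entries})

    def residue_type(self, residue_index: int) -> str | None:
        for e in self.entries:
            if e.residue_index == residue_index:
                return e.residue_type
        return None

    def get(self, residue_index: int, atom: str) -> float | None:
        for e in self.entries:
            if e.residue_index == residue_index and e.atom == atom:
                return e.shift
        return None

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ShiftTable":
        required = {"residue_index", "residue_type", "atom", "shift_ppm"}
        missing = required - set(df.columns)
        if missing:
            raise ShiftTableError(f"missing columns: {sorted(missing)}")
        entries = [
            ShiftEntry(int(r.residue_index), str(r.residue_type).strip().upper(),
                       str(r.atom).strip().upper(), float(r.shift_ppm))
            for r in df.itertuples()
        ]
        return cls(entries)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ShiftTable":
        """Read a delimited shift table (comma or tab, sniffed)."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        df.columns = [c.strip() for c in df.columns]
        return cls.from_dataframe(df)

    @classmethod
    def read_nmrstar(cls, path: str | Path) -> "ShiftTable":
        """Read the chemical-shift loop of an NMR-STAR v3 file.

        Only the four needed columns are used (sequence code, residue,
        atom, value); other loops and save frames are ignored.
        """
        text = Path(path).read_text()
        return cls(_parse_star_shift_loop(text))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.residue_index, e.residue_type, e.atom, e.shift) for e in self.entries],
            columns=["residue_index", "residue_type", "atom", "shift_ppm"],
        )


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _parse_star_shift_loop(text: str) -> list[ShiftEntry]:
    # Accepts both Atom_chem_shift.* (v3) tag sets; columns located by tag.
    lines = text.splitlines()
    entries: list[ShiftEntry] = []
    i = 0
    while i < len(lines):
        if lines[i].strip() == "loop_":
            tags: list[str] = []
            j = i + 1
            while j < len(lines) and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            lowered = [t.lower() for t in tags]
            if any("atom_chem_shift" in t for t in lowered):
                def col(*names: str) -> int:
                    for n in names:
                        for k, t in enumerate(lowered):
                            if t.endswith(n):
                                return k
                    raise ShiftTableError(f"NMR-STAR shift loop lacks {names[0]}")

                c_seq = col(".seq_id", ".comp_index_id")
                c_res = col(".comp_id")
                c_atom = col(".atom_id")
                c_val = col(".val", ".chem_shift_val")
                while j < len(lines):
                    row = lines[j].strip()
                    j += 1
                    if row in ("stop_", "") or row.startswith(("_", "#")):
                        if row == "stop_":
                            break
                        continue
                    parts = row.split()
                    if len(parts) <= max(c_seq, c_res, c_atom, c_val):
                        continue
                    atom = parts[c_atom].upper()
                    if atom not in BACKBONE_ATOMS:
                        continue
                    res3 = parts[c_res].upper()
                    res1 = _THREE_TO_ONE.get(res3, res3 if len(res3) == 1 else "?")
                    if res1 == "?":
                        raise ShiftTableError(f"unknown residue type {res3!r}")
                    entries.append(
                        ShiftEntry(int(parts[c_seq]), res1, atom, float(parts[c_val]))
                    )
            i = j
        else:
            i += 1
    if not entries:
        raise ShiftTableError("no backbone shifts found in NMR-STAR input")
    return entries


@dataclass
class RandomCoilTable:
    """Random-coil 13CA/13CB reference shifts with named provenance."""

    values: Mapping[str, Mapping[str, float]]
    provenance: str

    def __post_init__(self) -> None:
        for aa in _THREE_TO_ONE.values():
            if aa not in self.values or "CA" not in self.values[aa]:
                raise ShiftTableError(f"random-coil table lacks CA for {aa}")
            if aa != "G" and "CB" not in self.values[aa]:
                raise ShiftTableError(f"random-coil table lacks CB for {aa}")

    @classmethod
    def default(cls) -> "RandomCoilTable":
        return cls(RANDOM_COIL_CA_CB, RANDOM_COIL_PROVENANCE)

    @classmethod
    def read_csv(cls, path: str | Path, provenance: str | None = None) -> "RandomCoilTable":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        values: dict[str, dict[str, float]] = {}
        for r in df.itertuples():
            aa = str(r.residue_type).strip().upper()
            values.setdefault(aa, {})[str(r.atom).strip().upper()] = float(r.shift_ppm)
        return cls(values, provenance or str(path))

    def get(self, residue_type: str, atom: str) -> float:
        try:
            return self.values[residue_type][atom]
        except KeyError:
            raise ShiftTableError(
                f"no random-coil {atom} reference for residue type {residue_type!r}"
            ) from None


# ---------------------------------------------------------------------------
# Secondary-shift index
# ---------------------------------------------------------------------------

def secondary_shifts(
    shifts: ShiftTable, reference: RandomCoilTable | None = None
) -> dict[int, tuple[float, float]]:
    """Per-residue secondary shifts ``(d_dCA, d_dCB)`` in ppm.

    ``d_d = d_observed - d_random_coil`` for CA and CB.  Gly, which has no
    CB, contributes ``d_dCB = 0`` so the CA-CB index reduces to d_dCA.
    Residues without a CA shift are omitted (callers treat them as
    undefined).
    """
    reference = reference or RandomCoilTable.default()
    out: dict[int, tuple[float, float]] = {}
    for res in shifts.residues():
        rtype = shifts.residue_type(res)
        assert rtype is not None
        if rtype not in _THREE_TO_ONE.values():
            raise ShiftTableError(f"unknown residue type {rtype!r} at residue {res}")
        ca = shifts.get(res, "CA")
        if ca is None:
            continue
        _check_ppm(ca, res, "CA")
        d_ca = ca - reference.get(rtype, "CA")
        if rtype == "G":
            d_cb = 0.0
        else:
            cb = shifts.get(res, "CB")
            if cb is None:
                d_cb = 0.0
            else:
                _check_ppm(cb, res, "CB")
                d_cb = cb - reference.get(rtype, "CB")
        out[res] = (d_ca, d_cb)
    return out


def _check_ppm(value: float, res: int, atom: str) -> None:
    if not (0.0 <= value <= 250.0):
        raise ShiftTableError(
            f"{atom} shift {value} ppm at residue {res} is outside [0, 250]; "
            "check for a column mix-up"
        )


def raw_index(deltas: Mapping[int, tuple[float, float]]) -> dict[int, float]:
    """The CA-CB index ``d_dCA - d_dCB`` per residue."""
    return {res: d[0] - d[1] for res, d in deltas.items()}


def smooth_index(raw: Mapping[int, float]) -> dict[int, float]:
    """Three-residue running mean of the index.

    Interior residues take ``(x[i-1] + x[i] + x[i+1]) / 3``.  At chain
    termini and next to assignment gaps the mean runs over the available
    window members, so no residue with an own value is dropped.
    """
    out: dict[int, float] = {}
    for res, val in raw.items():
        members = [val]
        for nb in (res - 1, res + 1):
            if nb in raw:
                members.append(raw[nb])
        out[res] = sum(members) / len(members)
    return out


def classify_secondary(
    smoothed: Mapping[int, float], deadband: float = DEFAULT_DEADBAND
) -> dict[int, str]:
    """Sign-rule secondary-structure call with a coil deadband.

    ``helix`` where the smoothed index exceeds ``+deadband``, ``strand``
    below ``-deadband``, ``coil`` in between.
    """
    if deadband < 0:
        raise ValueError("deadband must be >= 0")
    labels: dict[int, str] = {}
    for res, val in smoothed.items():
        if val > deadband:
            labels[res] = HELIX
        elif val < -deadband:
            labels[res] = STRAND
        else:
            labels[res] = COIL
    return labels


@dataclass
class SecondaryShiftProfile:
    """Raw and smoothed CA-CB index with secondary-structure labels."""

    raw: dict[int, float]
    smoothed: dict[int, float]
    labels: dict[int, str]
    deadband: float
    reference_provenance: str

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (res, self.raw[res], self.smoothed[res], self.labels[res])
            for res in sorted(self.raw)
        ]
        return pd.DataFrame(
            rows, columns=["residue_index", "raw_index_ppm", "smoothed_index_ppm", "label"]
        )


def predict_secondary_structure(
    shifts: ShiftTable,
    reference: RandomCoilTable | None = None,
    deadband: float = DEFAULT_DEADBAND,
) -> SecondaryShiftProfile:
    """Full pipeline: secondary shifts -> index -> smoothing -> labels."""
    reference = reference or RandomCoilTable.default()
    deltas = secondary_shifts(shifts, reference)
    raw = raw_index(deltas)
    smoothed = smooth_index(raw)
    labels = classify_secondary(smoothed, deadband)
    return SecondaryShiftProfile(raw, smoothed, labels, deadband, reference.provenance)


# ---------------------------------------------------------------------------
# Chemical-shift perturbation
# ---------------------------------------------------------------------------

@dataclass
class CspProfile:
    """Combined amide perturbations between two states.

    ``delta_h``/``delta_n`` keep the signed differences (state A minus
    state B) for diagnostics; ``delta_nh`` is the non-negative combined
    value.  ``unmatched`` lists residues present in only one state.
    """

    delta_h: dict[int, float]
    delta_n: dict[int, float]
    delta_nh: dict[int, float]
    tiers: dict[int, int] = field(default_factory=dict)
    thresholds: tuple[float, ...] = ()
    unmatched_a: tuple[int, ...] = ()
    unmatched_b: tuple[int, ...] = ()

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for res in sorted(self.delta_nh):
            rows.append(
                (res, self.delta_h[res], self.delta_n[res], self.delta_nh[res],
                 self.tiers.get(res, 0))
            )
        return pd.DataFrame(
            rows,
            columns=["residue_index", "delta_H_ppm", "delta_N_ppm", "delta_NH_ppm", "tier"],
        )


def combined_shift(delta_h: float, delta_n: float) -> float:
    """The weighted combined amide perturbation.

    ``sqrt((d_dH^2 + (d_dN/5)^2) / 2)`` — the 15N difference is scaled by
    1/5 to put it on the 1H shift scale before averaging.
    """
    return math.sqrt((delta_h ** 2 + (delta_n / 5.0) ** 2) / 2.0)


def csp(state_a: ShiftTable, state_b: ShiftTable) -> CspProfile:
    """Amide CSP between two states over their shared residues.

    Residues present in only one state (lost or unassigned peaks) are
    reported in ``unmatched_a``/``unmatched_b``, never silently dropped.
    """
    def amide_residues(t: ShiftTable) -> set[int]:
        return {
            r for r in t.residues()
            if t.get(r, "H") is not None and t.get(r, "N") is not None
        }

    res_a, res_b = amide_residues(state_a), amide_residues(state_b)
    shared = sorted(res_a & res_b)
    if not shared:
        raise ShiftTableError("the two states share no residues with H and N shifts")

    dh: dict[int, float] = {}
    dn: dict[int, float] = {}
    dnh: dict[int, float] = {}
    for res in shared:
        h_a, h_b = state_a.get(res, "H"), state_b.get(res, "H")
        n_a, n_b = state_a.get(res, "N"), state_b.get(res, "N")
        assert None not in (h_a, h_b, n_a, n_b)
        dh[res] = h_a - h_b
        dn[res] = n_a - n_b
        dnh[res] = combined_shift(dh[res], dn[res])
    return CspProfile(
        dh, dn, dnh,
        unmatched_a=tuple(sorted(res_a - res_b)),
        unmatched_b=tuple(sorted(res_b - res_a)),
    )


def tier_csp(profile: CspProfile, thresholds: Sequence[float]) -> CspProfile:
    """Bin combined perturbations into ordinal tiers.

    Tier k = number of thresholds strictly exceeded; thresholds must be
    positive and strictly ascending.  Typical sets: ``(0.25, 0.5, 1.0)``
    ppm for a mutation, ``(0.05, 0.1)`` ppm for a ligand titration.
    """
    th = tuple(float(t) for t in thresholds)
    if not th or any(t <= 0 for t in th) or any(b <= a for a, b in zip(th, th[1:])):
        raise ValueError(f"thresholds must be positive and strictly ascending, got {th}")
    tiers = {
        res: sum(1 for t in th if val > t) for res, val in profile.delta_nh.items()
    }
    profile.tiers = tiers
    profile.thresholds = th
    return profile


def recovery_fraction(
    truth: Mapping[int, str], labels: Mapping[int, str], structured_only: bool = True
) -> float:
    """Fraction of (structured) residues whose label matches the truth."""
    keys: Iterable[int] = (
        [r for r, t in truth.items() if t in (HELIX, STRAND)]
        if structured_only else truth.keys()
    )
    keys = [r for r in keys if r in labels]
    if not keys:
        return float("nan")
    return sum(1 for r in keys if labels[r] == truth[r]) / len(keys)
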