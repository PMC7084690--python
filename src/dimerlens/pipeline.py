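"""End-to-end orchestration of the NMR and structure analysis stages.

A :class:`RunConfig` collects every tunable with its documented default
and serializes to a flat ``key = value`` text file that is archived next
to the outputs; every machine-readable output embeds the config hash and
package version, so a results directory is self-describing.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import pandas as pd

from . import __version__
from ._refdata import RANDOM_COIL_PROVENANCE, VDW_RADII_PROVENANCE
from .interface import (
    DEFAULT_HBOND_ANGLE_MIN,
    DEFAULT_HBOND_DMAX,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_SASA_POINTS,
    backbone_hbonds,
    interface_area,
    register_map,
    register_shift,
    superpose,
)
from .model import StructureModel, build_dimer_from_asu, read_structure, write_pdb
from .relax import (
    RelaxationRates,
    average_rates,
    classify_oligomer,
    fit_rates,
    read_decays,
    read_noe_table,
    tau_c_from_ratio,
)
from .shifts import DEFAULT_DEADBAND, RandomCoilTable, ShiftTable, csp, predict_secondary_structure, tier_csp

log = logging.getLogger("dimerlens")

EXIT_OK, EXIT_BAD_INPUT, EXIT_STAGE_FAILURE = 0, 2, 3


@dataclass
class RunConfig:
    """All inputs and tunables of a pipeline run."""

    # inputs
    shifts_path: str | None = None
    shifts_reference_path: str | None = None   # second state for CSP
    r1_decays_path: str | None = None
    r2_decays_path: str | None = None
    noe_path: str | None = None
    structure_path: str | None = None
    structure_reference_path: str | None = None
    random_coil_path: str | None = None
    out_dir: str = "dimerlens_out"

    # shift analysis
    deadband: float = DEFAULT_DEADBAND
    csp_thresholds: tuple[float, ...] = (0.25, 0.5, 1.0)

    # relaxation
    field_mhz: float = 600.13          # 1H frequency of the spectrometer
    noe_cutoff: float = 0.6
    trim_fraction: float = 0.1

    # structure
    build_dimer: bool = False
    hbond_dmax: float = DEFAULT_HBOND_DMAX
    hbond_angle_min: float = DEFAULT_HBOND_ANGLE_MIN
    probe_radius: float = DEFAULT_PROBE_RADIUS
    sasa_points: int = DEFAULT_SASA_POINTS
    superpose_atoms: tuple[str, ...] = ("CA",)
    superpose_range: tuple[int, int] = (6, 68)
    register_window: tuple[int, int] = (5, 15)

    seed: int = 0

    # -- serialization ------------------------------------------------------

    def to_text(self) -> str:
        lines = [f"# dimerlens {__version__} run configuration"]
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        types = {f.name: f for f in fields(cls)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cls(), key)
            if raw == "None":
                kwargs[key] = None
            elif isinstance(default, bool):
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(default, int) and not isinstance(default, bool):
                kwargs[key] = int(raw)
            elif isinstance(default, float):
                kwargs[key] = float(raw)
            elif isinstance(default, tuple):
                parts = [p for p in raw.split(",") if p]
                elem = type(default[0]) if default else float
                kwargs[key] = tuple(elem(p) for p in parts)
            else:
                kwargs[key] = raw
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha1(self.to_text().encode()).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (
        f"# dimerlens {__version__}  config {config.digest()}\n"
        f"# random-coil reference: {RANDOM_COIL_PROVENANCE}; "
        f"vdW radii: {VDW_RADII_PROVENANCE}\n"
    )


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.5f")


@dataclass
class ReportBundle:
    out_dir: Path
    summary: dict[str, object] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def exit_code(self) -> int:
        return EXIT_STAGE_FAILURE if self.errors else EXIT_OK


def _finish(bundle: ReportBundle, config: RunConfig) -> ReportBundle:
    lines = [_header(config).rstrip()]
    for key, val in bundle.summary.items():
        lines.append(f"{key}: {val}")
    for stage, err in bundle.errors.items():
        lines.append(f"ERROR[{stage}]: {err}")
    (bundle.out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    (bundle.out_dir / "config.txt").write_text(config.to_text())
    return bundle


def run_nmr_pipeline(config: RunConfig) -> ReportBundle:
    """Secondary-structure, CSP, and relaxation stages.

    Stages are independent: an error in one is recorded and the others
    still run.  Missing optional inputs (decays, NOE, second shift table)
    simply skip their stage with a warning.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out)

    reference = (
        RandomCoilTable.read_csv(config.random_coil_path)
        if config.random_coil_path else RandomCoilTable.default()
    )

    table = None
    if config.shifts_path:
        try:
            table = ShiftTable.read_csv(config.shifts_path)
            profile = predict_secondary_structure(table, reference, config.deadband)
            _write_table(profile.to_dataframe(), out / "ss.tsv", config)
            counts = pd.Series(list(profile.labels.values())).value_counts().to_dict()
            bundle.summary["secondary_structure"] = counts
        except Exception as exc:  # noqa: BLE001 - stage isolation by contract
            log.error("secondary-structure stage failed: %s", exc)
            bundle.errors["secondary_structure"] = str(exc)
    else:
        log.warning("no shift table given; skipping shift analyses")

    if table is not None and config.shifts_reference_path:
        try:
            other = ShiftTable.read_csv(config.shifts_reference_path)
            profile = tier_csp(csp(table, other), config.csp_thresholds)
            _write_table(profile.to_dataframe(), out / "csp.tsv", config)
            top = max(profile.tiers.values(), default=0)
            bundle.summary["csp_max_tier"] = top
            bundle.summary["csp_unmatched"] = {
                "a_only": list(profile.unmatched_a), "b_only": list(profile.unmatched_b)
            }
        except Exception as exc:  # noqa: BLE001
            log.error("CSP stage failed: %s", exc)
            bundle.errors["csp"] = str(exc)

    rates = RelaxationRates()
    try:
        if config.r1_decays_path:
            for f in fit_rates(read_decays(config.r1_decays_path, "R1")):
                if f.ok:
                    rates.r1[f.residue_index] = (f.rate, f.rate_se)
        if config.r2_decays_path:
            for f in fit_rates(read_decays(config.r2_decays_path, "R2")):
                if f.ok:
                    rates.r2[f.residue_index] = (f.rate, f.rate_se)
        if config.noe_path:
            rates.noe = read_noe_table(config.noe_path)
    except Exception as exc:  # noqa: BLE001
        log.error("relaxation stage failed: %s", exc)
        bundle.errors["relaxation"] = str(exc)

    if rates.r1 or rates.r2:
        _write_table(rates.to_dataframe(), out / "rates.tsv", config)
        means = average_rates(rates, config.noe_cutoff, config.trim_fraction)
        bundle.summary["mean_rates"] = {
            k: (round(v, 3) if v == v else None) for k, v in means.items()
        }
        if rates.r1 and rates.r2 and means["R1"] > 0 and means["R2"] > 0:
            nu_n = config.field_mhz * 0.101329118
            try:
                est = tau_c_from_ratio(means["R1"], means["R2"], nu_n)
                call = classify_oligomer(est)
                tumbling = pd.DataFrame(
                    [(est.tau_c_ns, est.r2_over_r1, est.nitrogen_larmor_mhz,
                      est.formula_name, call.state)],
                    columns=["tau_c_ns", "R2_over_R1", "nuN_MHz", "formula", "state"],
                )
                _write_table(tumbling, out / "tumbling.tsv", config)
                bundle.summary["tau_c_ns"] = round(est.tau_c_ns, 2)
                bundle.summary["oligomeric_state"] = call.state
                bundle.summary["oligomer_basis"] = call.basis
            except Exception as exc:  # noqa: BLE001
                log.error("tumbling stage failed: %s", exc)
                bundle.errors["tumbling"] = str(exc)
    else:
        log.warning("no decay data; relaxation stages skipped")

    return _finish(bundle, config)


def run_structure_pipeline(config: RunConfig) -> ReportBundle:
    """Dimer-interface stage: H-bonds, buried area, register, superposition."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out)
    if not config.structure_path:
        bundle.errors["structure"] = "no structure file given"
        return _finish(bundle, config)

    try:
        model = read_structure(config.structure_path)
        model = _as_dimer(model, config)
    except Exception as exc:  # noqa: BLE001
        bundle.errors["structure"] = str(exc)
        return _finish(bundle, config)

    try:
        report = analyze_interface(model, config)
        (out / "interface.txt").write_text(_header(config) + report.to_text() + "\n")
        rows = [
            (hb.donor[0], hb.donor[1], hb.acceptor[0], hb.acceptor[1],
             hb.distance_no, hb.angle) for hb in report.hbonds
        ]
        _write_table(
            pd.DataFrame(rows, columns=[
                "donor_chain", "donor_res", "acceptor_chain", "acceptor_res",
                "dist_NO_A", "angle_deg"]),
            out / "interface.tsv", config,
        )
        bundle.summary["buried_area_A2"] = round(report.buried_area, 1)
        bundle.summary["n_interchain_hbonds"] = len(report.hbonds)
        bundle.summary["register_map"] = report.register_map
    except Exception as exc:  # noqa: BLE001
        bundle.errors["interface"] = str(exc)

    if config.structure_reference_path:
        try:
            other = read_structure(config.structure_reference_path)
            other = _as_dimer(other, config)
            sup = superpose(
                model.subset(model.mask(chain_id=model.chains[0])),
                other.subset(other.mask(chain_id=other.chains[0])),
                atom_names=config.superpose_atoms,
                residue_range=config.superpose_range,
            )
            bundle.summary["monomer_rmsd_A"] = round(sup.rmsd, 3)
            bundle.summary["rmsd_selection"] = sup.selection
            mono = model.subset(model.mask(chain_id=model.chains[0]))
            write_pdb(mono.transformed(sup.rotation, sup.translation),
                      out / "superposed.pdb")
            map_b = register_map(
                other, d_max=config.hbond_dmax, angle_min=config.hbond_angle_min
            )
            offset = register_shift(
                bundle.summary.get("register_map", []), map_b, config.register_window
            )
            bundle.summary["register_shift"] = offset
        except Exception as exc:  # noqa: BLE001
            bundle.errors["comparison"] = str(exc)

    return _finish(bundle, config)


def _as_dimer(model: StructureModel, config: RunConfig) -> StructureModel:
    chains = model.subset(model.mask(exclude_water=True)).chains
    if len(chains) >= 2:
        return model
    if config.build_dimer or model.symmetry_ops:
        if model.cell is None or not model.symmetry_ops:
            raise ValueError(
                "single-chain input: need crystal symmetry (cell + space group) "
                "or a two-chain file"
            )
        return build_dimer_from_asu(model)
    raise ValueError("single-chain input without symmetry; need two chains")


def analyze_interface(dimer: StructureModel, config: RunConfig | None = None):
    """Interface report (H-bonds, buried area, register map) for a dimer."""
    from .interface import InterfaceReport

    config = config or RunConfig()
    hbonds = backbone_hbonds(
        dimer, d_max=config.hbond_dmax, angle_min=config.hbond_angle_min
    )
    area = interface_area(dimer, config.probe_radius, config.sasa_points)
    reg = register_map(dimer, hbonds=hbonds)
    return InterfaceReport(hbonds, area, reg, probe_radius=config.probe_radius)


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
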