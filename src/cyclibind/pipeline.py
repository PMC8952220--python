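"""End-to-end orchestration: configuration, stage runners and report writers.

Each runner takes a validated :class:`RunConfig` plus input paths, executes
the corresponding analysis stage, and returns the report table(s) along
with a machine-readable dictionary (full precision, config hash and input
checksums embedded for traceability). The thin command-line layer in
:mod:`cyclibind.cli` wraps these runners.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import io as cio
from .chem import Constants, SolutionSpec
from .kinetics import ZeroOrderKinetics
from .sorption import WeberMorris, compute_sorption_series, equilibrium_thermo
from .spectra import (
    band_shift_report,
    default_assignments,
    detect_peaks,
    load_assignments,
    preprocess_spectrum,
)
from .stoichiometry import (
    BindingMeasurement,
    audit_binding_table,
    fit_calibration,
    stoichiometry_table,
)
from .reference import MIXTURE_PROTEIN_MOLARITY, reference_binding_table

__all__ = [
    "RunConfig",
    "analyze_ph_series",
    "run_kinetics",
    "run_stoichiometry",
    "run_spectra",
    "run_audit",
]


class SolutionConfig(BaseModel):
    protein_stock_mg_ml: float = 1.0
    protein_volume_ml: float = 2.0
    ligand_volume_ml: float = 1.0
    temperature_c: float = 22.0
    initial_ph: float = 7.14

    def to_solution(self) -> SolutionSpec:
        return SolutionSpec.from_mixing(
            protein_stock_mg_ml=self.protein_stock_mg_ml,
            protein_volume_ml=self.protein_volume_ml,
            ligand_volume_ml=self.ligand_volume_ml,
            temperature_c=self.temperature_c,
            initial_ph=self.initial_ph,
        )


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    solution: SolutionConfig = Field(default_factory=SolutionConfig)
    pkw: float = 14.00
    min_points_per_segment: int = 2
    alpha: float = 0.05
    equilibrium_time: float | None = None
    dilution_factor: float = 30.0
    protein_mixture_molarity: float = MIXTURE_PROTEIN_MOLARITY
    pairing_tolerance: float = 8.0
    min_prominence: float = 0.05
    smooth_window: int = 7
    baseline_order: int = 3
    technique: str = "FTIR"
    assignments_file: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def constants(self) -> Constants:
        return Constants(pKw=self.pkw)

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def analyze_ph_series(series, config: RunConfig) -> dict:
    """Full kinetic + sorption + thermodynamic analysis of one pH series."""
    constants = config.constants()
    kin = ZeroOrderKinetics(series, config.min_points_per_segment, config.alpha).fit()
    sorption = compute_sorption_series(series, constants)
    wm = WeberMorris(sorption, segmentation=kin).fit()
    thermo = equilibrium_thermo(series, constants, config.equilibrium_time)
    return {
        "label": series.label,
        "mechanism": kin.mechanism,
        "sorption_class": kin.classify(),
        "breakpoint_min": kin.breakpoint,
        "k0_step1": kin.k0_step1,
        "k0_step2": kin.k0_step2,
        "A": wm.A,
        "K_ip": wm.K_ip,
        "q_eq_mg_kg": thermo.q_eq,
        "Ce_mg_L": thermo.Ce,
        "K_D": thermo.K_D,
        "dG_kJ": thermo.dG_kJ,
        "dG_kcal": thermo.dG_kcal,
    }


def _report_round(df: pd.DataFrame, spec: dict[str, int | str]) -> pd.DataFrame:
    """Round report columns the way the field reports them (2 d.p. for dG and
    counts of bound molecules, 3 s.f. for rate constants)."""
    out = df.copy()
    for col, rule in spec.items():
        if col not in out.columns:
            continue
        if rule == "2dp":
            out[col] = out[col].map(
                lambda v: np.nan if pd.isna(v) else round(float(v), 2))
        elif rule == "3sf":
            out[col] = out[col].map(
                lambda v: np.nan if pd.isna(v) else float(f"{float(v):.3g}"))
    return out


def run_kinetics(config: RunConfig, series_files: list[str | Path],
                 out_dir: str | Path | None = None) -> tuple[pd.DataFrame, dict]:
    """Analyze pH series files into a kinetics/thermodynamics report.

    Per-file parse errors are collected into the payload's ``errors`` list;
    the run continues for the remaining files.
    """
    solution = config.solution.to_solution()
    rows, errors, checksums = [], [], {}
    for path in series_files:
        try:
            series = cio.read_ph_series(path, solution)
        except cio.ParseError as exc:
            errors.append(str(exc))
            continue
        checksums[str(path)] = cio.sha256_file(path)
        rows.append(analyze_ph_series(series, config))
    columns = ["label", "mechanism", "sorption_class", "breakpoint_min",
               "k0_step1", "k0_step2", "A", "K_ip", "q_eq_mg_kg", "Ce_mg_L",
               "K_D", "dG_kJ", "dG_kcal"]
    table = pd.DataFrame(rows, columns=columns)
    payload = {
        "config_sha256": config.config_hash(),
        "inputs_sha256": checksums,
        "errors": errors,
        "rows": rows,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pretty = _report_round(table, {"dG_kJ": "2dp", "dG_kcal": "2dp",
                                       "k0_step1": "3sf", "k0_step2": "3sf",
                                       "A": "3sf", "K_ip": "3sf", "K_D": "3sf"})
        cio.write_tsv(pretty, out_dir / "kinetics_report.tsv")
        cio.write_json(payload, out_dir / "kinetics_report.json")
    return table, payload


def run_stoichiometry(config: RunConfig, calib_file: str | Path,
                      measure_file: str | Path,
                      out_dir: str | Path | None = None) -> tuple[pd.DataFrame, dict]:
    """Fit calibration curves, invert the measurements, assemble the binding table."""
    calib = cio.read_calibration_table(calib_file)
    meas = cio.read_measurement_table(measure_file)
    curves = {}
    for analyte, grp in calib.groupby("analyte"):
        curves[str(analyte)] = fit_calibration(
            grp["conc_M"].to_numpy(float), grp["peak_area"].to_numpy(float),
            analyte=str(analyte))
    measurements = []
    for i, row in meas.iterrows():
        ratio = float(row["molar_ratio"])
        c0 = (float(row["c0_M"]) if "c0_M" in meas.columns and pd.notna(row.get("c0_M"))
              else ratio * config.protein_mixture_molarity)
        dilution = (float(row["dilution"]) if "dilution" in meas.columns
                    and pd.notna(row.get("dilution")) else config.dilution_factor)
        measurements.append(BindingMeasurement(
            analyte=str(row["analyte"]),
            molar_ratio=ratio,
            peak_area=float(row["peak_area"]),
            c0=c0,
            dilution_factor=dilution,
            replicate=int(row["replicate"]) if "replicate" in meas.columns
            and pd.notna(row.get("replicate")) else int(i),
        ))
    table = stoichiometry_table(measurements, curves)
    audit = audit_binding_table(
        table[table["error"] == ""][["analyte", "molar_ratio",
                                     "bound_percent", "n_bound"]])
    payload = {
        "config_sha256": config.config_hash(),
        "inputs_sha256": {str(calib_file): cio.sha256_file(calib_file),
                          str(measure_file): cio.sha256_file(measure_file)},
        "curves": {name: {"slope": c.slope, "intercept": c.intercept,
                          "r_squared": c.r_squared, "equation": c.equation()}
                   for name, c in curves.items()},
        "rows": table.to_dict(orient="records"),
        "audit": audit.to_dict(orient="records"),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pretty = _report_round(table, {"bound_percent": "2dp", "n_bound": "2dp",
                                       "sd_percent": "2dp", "sd_n_bound": "2dp"})
        cio.write_tsv(pretty, out_dir / "stoichiometry_report.tsv")
        cio.write_json(payload, out_dir / "stoichiometry_report.json")
    return table, payload


def run_spectra(config: RunConfig, control_file: str | Path,
                complex_files: list[str | Path],
                out_dir: str | Path | None = None) -> tuple[list, dict]:
    """Band-shift reports of each complex spectrum against the control.

    Complex spectra on a different wavenumber grid are linearly interpolated
    onto the control grid with a named warning.
    """
    control = cio.read_spectrum(control_file, technique=config.technique)
    assignments = (load_assignments(config.assignments_file)
                   if config.assignments_file else default_assignments(config.technique))
    control_peaks = detect_peaks(
        preprocess_spectrum(control, config.smooth_window, config.baseline_order),
        config.min_prominence)
    reports, checksums = [], {str(control_file): cio.sha256_file(control_file)}
    for path in complex_files:
        spec = cio.read_spectrum(path, technique=config.technique)
        checksums[str(path)] = cio.sha256_file(path)
        if (len(spec) != len(control)
                or not np.allclose(spec.wavenumbers, control.wavenumbers)):
            warnings.warn(
                f"{path}: wavenumber grid differs from control; resampling by "
                "linear interpolation", stacklevel=2)
            asc = np.argsort(spec.wavenumbers)
            resampled = np.interp(control.wavenumbers,
                                  spec.wavenumbers[asc], spec.intensities[asc])
            spec = type(spec)(wavenumbers=control.wavenumbers.copy(),
                              intensities=resampled, technique=spec.technique,
                              resolution=spec.resolution, label=spec.label)
        peaks = detect_peaks(
            preprocess_spectrum(spec, config.smooth_window, config.baseline_order),
            config.min_prominence)
        reports.append(band_shift_report(control_peaks, peaks, assignments,
                                         config.pairing_tolerance, label=spec.label))
    payload = {
        "config_sha256": config.config_hash(),
        "inputs_sha256": checksums,
        "reports": [r.to_dict() for r in reports],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cio.write_json(payload, out_dir / "band_shift_reports.json")
        (out_dir / "band_shift_reports.txt").write_text(
            "\n\n".join(r.summary() for r in reports) + "\n")
    return reports, payload


def run_audit(table: pd.DataFrame | None = None,
              out_dir: str | Path | None = None) -> pd.DataFrame:
    """Consistency audit of a reported binding table (default: the built-in
    reference table)."""
    if table is None:
        table = reference_binding_table()
    audit = audit_binding_table(table[["analyte", "molar_ratio",
                                       "bound_percent", "n_bound"]])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cio.write_tsv(audit, out_dir / "binding_table_audit.tsv")
    return audit
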