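"""Plain-text table readers/writers and provenance checksums.

All tabular I/O is delimited text; reports are written with fixed float
formatting so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import SolutionSpec
from .kinetics import PHTimeSeries
from .spectra import Spectrum

__all__ = [
    "ParseError",
    "read_table",
    "read_ph_series",
    "read_spectrum",
    "read_calibration_table",
    "read_measurement_table",
    "write_tsv",
    "write_json",
    "sha256_file",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed into the expected shape."""


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a delimited text table, sniffing the delimiter; '#' comments allowed."""
    try:
        return pd.read_csv(path, sep=None, engine="python", comment="#", **kwargs)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise ParseError(f"{path}: {exc}") from exc


def read_ph_series(path: str | Path, solution: SolutionSpec,
                   label: str | None = None) -> PHTimeSeries:
    """Read a two-column (time_min, pH) table into a PHTimeSeries."""
    df = read_table(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (time_min, pH)")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    ph = df.iloc[:, 1].to_numpy(dtype=float)
    try:
        return PHTimeSeries(times=times, pH=ph, solution=solution,
                            label=label if label is not None else Path(path).stem)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_spectrum(path: str | Path, technique: str = "FTIR",
                  resolution: float = 8.0, label: str | None = None) -> Spectrum:
    """Read a two-column (wavenumber_cm1, intensity) table (either direction)."""
    df = read_table(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (wavenumber_cm1, intensity)")
    try:
        return Spectrum(
            wavenumbers=df.iloc[:, 0].to_numpy(dtype=float),
            intensities=df.iloc[:, 1].to_numpy(dtype=float),
            technique=technique,
            resolution=resolution,
            label=label if label is not None else Path(path).stem,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_calibration_table(path: str | Path) -> pd.DataFrame:
    """Columns: analyte, conc_M, peak_area."""
    df = read_table(path)
    missing = {"analyte", "conc_M", "peak_area"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    """Columns: analyte, molar_ratio, peak_area [, c0_M, dilution, replicate]."""
    df = read_table(path)
    missing = {"analyte", "molar_ratio", "peak_area"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def _format_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return "nan"
        return format(float(v), ".6g")
    return str(v)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with fixed 6-significant-digit float format."""
    formatted = df.map(_format_value)
    formatted.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON dump (sorted keys, full precision)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
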