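"""MS-calibration stoichiometry: how many ligand molecules bind per protein.

A linear calibration curve (SIM peak area vs concentration) is fitted per
analyte, inverted to recover the unbound ligand concentration in the
supernatant of a protein-ligand mixture, and combined with the initial
ligand concentration into the bound percentage and the number of bound
molecules per protein:

    bound%  = 100 * (c0 - c_free) / c0
    n_bound = bound% / 100 * r        (r = initial ligand:protein molar ratio)

``audit_binding_table`` checks a reported binding table against the exact
identity n_bound = r * bound% / 100 and flags rows where the two reported
columns are mutually inconsistent (including the case where they are
consistent only when transposed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import CyclitolSpec
from .kinetics import DegenerateFitError, _ols_line

__all__ = [
    "CalibrationCurve",
    "CalibrationModel",
    "BindingMeasurement",
    "BindingResult",
    "fit_calibration",
    "invert_calibration",
    "bound_fraction",
    "bound_molecules",
    "stoichiometry_table",
    "audit_binding_table",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted linear MS response curve: area = slope * conc + intercept."""

    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]
    analyte: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise DegenerateFitError("a calibration curve with zero slope is invalid")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.conc_range[0] > self.conc_range[1]:
            raise ValueError("conc_range must be ordered")

    def predict(self, conc: float | np.ndarray) -> float | np.ndarray:
        return self.slope * conc + self.intercept

    def equation(self) -> str:
        return (f"y = {self.slope:.3g}x + {self.intercept:.6g} "
                f"(R^2 = {self.r_squared:.4f})")


class CalibrationModel:
    """Linear calibration of instrument response on concentration (OLS)."""

    def __init__(self, concs, areas, analyte: str = ""):
        self.concs = np.asarray(concs, dtype=float)
        self.areas = np.asarray(areas, dtype=float)
        self.analyte = analyte
        if self.concs.shape != self.areas.shape or self.concs.ndim != 1:
            raise ValueError("concs and areas must be 1-D arrays of equal length")
        if len(np.unique(self.concs)) < 3:
            raise DegenerateFitError("calibration needs >= 3 distinct concentrations")
        if np.ptp(self.areas) == 0:
            raise DegenerateFitError(
                "constant instrument response; calibration slope would be zero")

    def fit(self) -> CalibrationCurve:
        intercept, slope, sse = _ols_line(self.concs, self.areas)
        sst = float(np.sum((self.areas - self.areas.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        return CalibrationCurve(
            slope=slope,
            intercept=intercept,
            r_squared=max(0.0, min(1.0, r2)),
            conc_range=(float(self.concs.min()), float(self.concs.max())),
            analyte=self.analyte,
        )


def fit_calibration(concs, areas, analyte: str = "") -> CalibrationCurve:
    """OLS calibration fit (wrapper around CalibrationModel)."""
    return CalibrationModel(concs, areas, analyte).fit()


def invert_calibration(area: float, curve: CalibrationCurve,
                       dilution_factor: float = 1.0) -> float:
    """Back-calculate the pre-dilution concentration (mol/L) from a peak area.

    A below-blank response (area < intercept) clips to 0 mol/L with a
    warning; a back-calculated value outside the calibration range also
    warns but is returned as-is.
    """
    if not np.isfinite(area):
        raise ValueError("area must be finite")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    diluted = (area - curve.intercept) / curve.slope
    if diluted < 0:
        warnings.warn(
            f"response below blank for {curve.analyte or 'analyte'}; "
            "clipping concentration to 0",
            stacklevel=2,
        )
        return 0.0
    lo, hi = curve.conc_range
    if diluted > 0 and not lo <= diluted <= hi:
        warnings.warn(
            f"back-calculated concentration {diluted:.3g} M outside the "
            f"calibration range [{lo:.3g}, {hi:.3g}] M",
            stacklevel=2,
        )
    return dilution_factor * diluted


def bound_fraction(c0: float, c_free: float) -> float:
    """Percentage of the ligand bound: 100 * (c0 - c_free) / c0, clipped to [0, 100]."""
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    if c_free < 0:
        raise ValueError("c_free must be non-negative")
    pct = 100.0 * (c0 - c_free) / c0
    if pct < 0:
        warnings.warn("bound fraction below 0% (free exceeds initial); clipping", stacklevel=2)
        return 0.0
    return pct


def bound_molecules(bound_percent: float, molar_ratio: float) -> float:
    """Bound ligand molecules per protein: bound%/100 * molar ratio."""
    if molar_ratio <= 0:
        raise ValueError("molar_ratio must be positive")
    if not 0 <= bound_percent <= 100:
        raise ValueError("bound_percent must lie in [0, 100]")
    return bound_percent / 100.0 * molar_ratio


@dataclass(frozen=True)
class BindingMeasurement:
    """One supernatant measurement of a protein:ligand mixture.

    ``molar_ratio`` r is the initial ligand:protein ratio; ``c0`` the initial
    ligand concentration in the (pre-centrifugation) mixture, mol/L.
    """

    analyte: str
    molar_ratio: float
    peak_area: float
    c0: float
    dilution_factor: float = 30.0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.molar_ratio <= 0:
            raise ValueError("molar_ratio must be positive")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class BindingResult:
    """Binding outcome for one analyte at one molar ratio (replicate means)."""

    analyte: str
    molar_ratio: float
    c_free: float
    bound_percent: float
    n_bound: float
    sd_percent: float = 0.0
    sd_n_bound: float = 0.0
    n_replicates: int = 1


def _process_one(m: BindingMeasurement, curve: CalibrationCurve) -> tuple[float, float, float]:
    c_free = invert_calibration(m.peak_area, curve, m.dilution_factor)
    if c_free > m.c0:
        warnings.warn(
            f"free concentration {c_free:.3g} M exceeds initial {m.c0:.3g} M "
            f"for {m.analyte} 1:{m.molar_ratio:g}; bound fraction clipped to 0%",
            stacklevel=3,
        )
        c_free = min(c_free, m.c0)
    pct = bound_fraction(m.c0, c_free)
    return c_free, pct, bound_molecules(pct, m.molar_ratio)


def stoichiometry_table(measurements: list[BindingMeasurement],
                        curves: dict[str, CalibrationCurve]) -> pd.DataFrame:
    """Assemble the per-(analyte, ratio) binding table.

    Replicates sharing (analyte, molar_ratio) are processed independently
    through the whole pipeline and summarised as mean +- SD. Rows whose
    analyte has no calibration curve are reported with a row-level error;
    the remaining rows proceed.
    """
    rows = []
    by_key: dict[tuple[str, float], list[BindingMeasurement]] = {}
    for m in measurements:
        by_key.setdefault((m.analyte, m.molar_ratio), []).append(m)
    for (analyte, ratio), group in by_key.items():
        if analyte not in curves:
            rows.append({
                "analyte": analyte, "molar_ratio": ratio, "c_free": np.nan,
                "bound_percent": np.nan, "n_bound": np.nan, "sd_percent": np.nan,
                "sd_n_bound": np.nan, "n_replicates": len(group),
                "error": "no calibration curve for analyte",
            })
            continue
        curve = curves[analyte]
        results = np.array([_process_one(m, curve) for m in group])
        c_free, pct, nb = results.T
        sd = (lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        rows.append({
            "analyte": analyte, "molar_ratio": ratio,
            "c_free": float(c_free.mean()),
            "bound_percent": float(pct.mean()), "n_bound": float(nb.mean()),
            "sd_percent": sd(pct), "sd_n_bound": sd(nb),
            "n_replicates": len(group), "error": "",
        })
    columns = ["analyte", "molar_ratio", "c_free", "bound_percent", "n_bound",
               "sd_percent", "sd_n_bound", "n_replicates", "error"]
    return pd.DataFrame(rows, columns=columns)


def audit_binding_table(table: pd.DataFrame, tol: float = 0.01) -> pd.DataFrame:
    """Audit a reported binding table for internal consistency.

    For each row the identity ``n_bound = molar_ratio * bound_percent / 100``
    is checked to the reporting precision (``tol``, default one unit in the
    second decimal place). Rows failing it but satisfying the identity with
    the two reported columns swapped are flagged ``"transposed"``; anything
    else failing is ``"inconsistent"``.

    Expects columns ``analyte``, ``molar_ratio``, ``bound_percent``,
    ``n_bound``; returns the table with ``n_bound_recomputed`` and
    ``status`` columns appended.
    """
    out = table.copy()
    recomputed = out["molar_ratio"] * out["bound_percent"] / 100.0
    status = []
    for rec, ratio, pct, nb in zip(recomputed, out["molar_ratio"],
                                   out["bound_percent"], out["n_bound"]):
        if abs(rec - nb) <= tol:
            status.append("consistent")
        elif abs(ratio * nb / 100.0 - pct) <= tol:
            status.append("transposed")
        else:
            status.append("inconsistent")
    out["n_bound_recomputed"] = recomputed
    out["status"] = status
    return out
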