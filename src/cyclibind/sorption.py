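"""Sorption quantity, intraparticle-diffusion model and binding thermodynamics.

The pH trajectory of a protein-cyclitol mixture is converted into a sorbed
quantity q_t — the change in hydroxide availability per gram of protein:

    q_t = ([OH-]_0 - [OH-]_t) * M_OH * V / m          (mg OH- per g protein)

with [OH-] = 10**(pH - pKw) mol/L, V the mixture volume and m the protein
mass. This is the only dimensionally consistent reading of "change in the
number of hydroxyl groups on the protein (mg/g)"; q may be negative when the
pH rebounds above its initial value.

The intraparticle-diffusion (Weber-Morris) model is then

    q_t = A + K_ip * sqrt(t)

where A (mg/g) reflects external-surface / boundary-layer sorption and K_ip
((mg/g)/min^0.5) is the intraparticle diffusion rate constant. The headline
(A, K_ip) pair comes from the full-series fit; per-segment fits are emitted
as diagnostics when a kinetic segmentation is supplied.

At equilibrium (by default the last observation) the distribution constant

    K_D = q_eq / Ce

is formed with q_eq in mg/kg (note: the sorption equation uses mg/g, the
distribution equation mg/kg — both unit conventions are honoured literally,
so q_eq = 1000 * q_t(eq)) and Ce the equilibrium hydroxide concentration in
solution (mg/L). K_D is then treated as a bare number in

    dG_bind = -R * T * ln(K_D).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .chem import Constants, DEFAULT_CONSTANTS, SolutionSpec, hydroxide_conc, kj_to_kcal
from .kinetics import (
    InsufficientDataError,
    KineticModelResult,
    PHTimeSeries,
    _ols_line,
)

__all__ = [
    "SorptionSeries",
    "WeberMorrisFit",
    "WeberMorris",
    "ThermoResult",
    "compute_sorption_series",
    "ph_from_sorption",
    "fit_weber_morris",
    "distribution_constant",
    "gibbs_free_energy",
    "equilibrium_thermo",
]


@dataclass
class SorptionSeries:
    """q_t trajectory derived from a pH time series (q in mg/g)."""

    times: np.ndarray
    q: np.ndarray
    solution: SolutionSpec
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.times.shape != self.q.shape or self.times.ndim != 1:
            raise ValueError("times and q must be 1-D arrays of equal length")

    @property
    def sqrt_times(self) -> np.ndarray:
        return np.sqrt(self.times)

    def __len__(self) -> int:
        return len(self.times)


def compute_sorption_series(series: PHTimeSeries,
                            constants: Constants = DEFAULT_CONSTANTS) -> SorptionSeries:
    """Map a pH trajectory to the sorbed hydroxide quantity q_t (mg/g)."""
    sol = series.solution
    if sol.protein_mass <= 0:
        raise ValueError("solution.protein_mass must be positive")
    oh0 = hydroxide_conc(sol.initial_pH, constants.pKw)
    oh_t = np.array([hydroxide_conc(p, constants.pKw) for p in series.pH])
    # mol/L * g/mol * 1000 -> mg/L; * V(L) -> mg; / m(g) -> mg/g
    # with V in mL and m in mg the litre/gram factors cancel to *1000:
    q = (oh0 - oh_t) * constants.M_OH * sol.total_volume * 1000.0 / sol.protein_mass
    return SorptionSeries(times=series.times.copy(), q=q, solution=sol, label=series.label)


def ph_from_sorption(sorption: SorptionSeries,
                     constants: Constants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Invert the q_t map back to the pH trajectory (exact inverse)."""
    sol = sorption.solution
    oh0 = hydroxide_conc(sol.initial_pH, constants.pKw)
    oh_t = oh0 - sorption.q * sol.protein_mass / (constants.M_OH * sol.total_volume * 1000.0)
    if np.any(oh_t <= 0):
        raise ValueError("sorption values exceed the available hydroxide pool")
    return constants.pKw + np.log10(oh_t)


@dataclass
class WeberMorrisFit:
    """Intraparticle-diffusion fit. ``headline`` is the full-series (A, K_ip);
    ``segments`` holds per-segment (A, K_ip, sse) diagnostics when a kinetic
    segmentation was supplied."""

    A: float
    K_ip: float
    sse: float
    n_points: int
    segments: list[tuple[float, float, float]]
    n_segments: int
    label: str = ""

    @property
    def headline(self) -> tuple[float, float]:
        return (self.A, self.K_ip)

    def predict(self, times: np.ndarray) -> np.ndarray:
        return self.A + self.K_ip * np.sqrt(np.asarray(times, dtype=float))

    def summary(self) -> str:
        lines = [
            f"Weber-Morris intraparticle-diffusion fit"
            + (f" for {self.label}" if self.label else ""),
            f"  A    = {self.A:.4g} mg/g (boundary-layer intercept)",
            f"  K_ip = {self.K_ip:.4g} (mg/g)/min^0.5",
            f"  sse  = {self.sse:.3g} (n = {self.n_points})",
        ]
        for i, (a, k, sse) in enumerate(self.segments, start=1):
            lines.append(f"  segment {i}: A = {a:.4g}, K_ip = {k:.4g}, sse = {sse:.3g}")
        return "\n".join(lines)

    def plot(self, sorption: SorptionSeries, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(sorption.sqrt_times, sorption.q, "o", label="data")
        st = np.linspace(sorption.sqrt_times.min(), sorption.sqrt_times.max(), 50)
        ax.plot(st, self.A + self.K_ip * st, "-", label="fit")
        ax.set_xlabel(r"$\sqrt{t}$ (min$^{0.5}$)")
        ax.set_ylabel(r"$q_t$ (mg/g)")
        ax.legend()
        return ax


class WeberMorris:
    """Weber-Morris model of a sorption series: OLS of q on sqrt(t)."""

    def __init__(self, sorption: SorptionSeries,
                 segmentation: KineticModelResult | None = None):
        if len(sorption) < 3:
            raise InsufficientDataError("Weber-Morris fit needs at least 3 points")
        self.sorption = sorption
        self.segmentation = segmentation

    def fit(self) -> WeberMorrisFit:
        st = self.sorption.sqrt_times
        q = self.sorption.q
        A, K_ip, sse = _ols_line(st, q)
        seg_fits: list[tuple[float, float, float]] = []
        if self.segmentation is not None and self.segmentation.breakpoint is not None:
            left = self.sorption.times <= self.segmentation.breakpoint
            for mask in (left, ~left):
                if mask.sum() >= 2 and np.ptp(st[mask]) > 0:
                    seg_fits.append(_ols_line(st[mask], q[mask]))
        return WeberMorrisFit(
            A=A,
            K_ip=K_ip,
            sse=sse,
            n_points=len(q),
            segments=seg_fits,
            n_segments=max(1, len(seg_fits)),
            label=self.sorption.label,
        )


def fit_weber_morris(sorption: SorptionSeries,
                     segmentation: KineticModelResult | None = None) -> WeberMorrisFit:
    """Convenience wrapper around the WeberMorris model class."""
    return WeberMorris(sorption, segmentation).fit()


def distribution_constant(q_eq: float, Ce: float) -> float:
    """Distribution constant K_D = q_eq / Ce (q_eq in mg/kg, Ce in mg/L).

    The ratio is treated as dimensionless downstream.
    """
    if Ce <= 0:
        raise ValueError("Ce must be positive")
    if q_eq < 0:
        raise ValueError("q_eq must be non-negative")
    return q_eq / Ce


def gibbs_free_energy(K_D: float, T: float,
                      constants: Constants = DEFAULT_CONSTANTS) -> tuple[float, float]:
    """Gibbs free energy of sorption: dG = -R*T*ln(K_D), in (kJ/mol, kcal/mol)."""
    if K_D <= 0:
        raise ValueError("K_D must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    dg_kj = -constants.R * T * math.log(K_D) / 1000.0
    return dg_kj, kj_to_kcal(dg_kj)


@dataclass
class ThermoResult:
    """Equilibrium sorption thermodynamics.

    ``q_eq`` in mg/kg, ``Ce`` in mg/L, ``K_D`` dimensionless; dG in kJ/mol
    and kcal/mol (NaN with ``defined = False`` when no net sorption
    occurred, i.e. q_eq <= 0).
    """

    q_eq: float
    Ce: float
    K_D: float
    dG_kJ: float
    dG_kcal: float
    T: float
    eq_time: float
    defined: bool = True
    label: str = ""

    def summary(self) -> str:
        return "\n".join([
            f"Sorption thermodynamics{' for ' + self.label if self.label else ''} "
            f"(equilibrium at t = {self.eq_time:g} min, T = {self.T:.2f} K)",
            f"  q_eq = {self.q_eq:.4g} mg/kg",
            f"  Ce   = {self.Ce:.4g} mg/L",
            f"  K_D  = {self.K_D:.4g}",
            f"  dG   = {self.dG_kJ:.2f} kJ/mol = {self.dG_kcal:.2f} kcal/mol"
            + ("" if self.defined else "  (undefined: no net sorption)"),
        ])


def equilibrium_thermo(series: PHTimeSeries,
                       constants: Constants = DEFAULT_CONSTANTS,
                       eq_time: float | None = None) -> ThermoResult:
    """K_D and dG from a pH trajectory at its equilibrium point.

    ``eq_time`` defaults to the last observation. A negative equilibrium q
    (pH rebound above the initial value) is clipped to zero with a warning,
    leaving dG undefined.
    """
    sorption = compute_sorption_series(series, constants)
    if eq_time is None:
        idx = len(series) - 1
    else:
        matches = np.flatnonzero(np.isclose(series.times, eq_time))
        if matches.size == 0:
            raise ValueError(f"eq_time {eq_time} is not an observation time")
        idx = int(matches[0])
    q_eq_mg_g = float(sorption.q[idx])
    if q_eq_mg_g < 0:
        warnings.warn(
            "negative equilibrium sorption (pH above initial value); "
            "clipping q_eq to 0, dG undefined",
            stacklevel=2,
        )
        q_eq_mg_g = 0.0
    q_eq = q_eq_mg_g * 1000.0  # mg/g -> mg/kg
    oh_eq = hydroxide_conc(float(series.pH[idx]), constants.pKw)
    Ce = oh_eq * constants.M_OH * 1000.0  # mol/L * g/mol * 1000 -> mg/L
    K_D = distribution_constant(q_eq, Ce)
    if K_D > 0:
        dg_kj, dg_kcal = gibbs_free_energy(K_D, series.solution.temperature, constants)
        defined = True
    else:
        dg_kj = dg_kcal = float("nan")
        defined = False
    return ThermoResult(
        q_eq=q_eq,
        Ce=Ce,
        K_D=K_D,
        dG_kJ=dg_kj,
        dG_kcal=dg_kcal,
        T=series.solution.temperature,
        eq_time=float(series.times[idx]),
        defined=defined,
        label=series.label,
    )
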