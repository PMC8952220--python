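"""Seeded generators of synthetic study inputs.

Every downstream stage of the pipeline can be exercised without instrument
data: piecewise-linear pH decays on the study sampling grid, binding
experiments pushed through a known calibration curve and binding rule, and
Gaussian-peak spectra on a fingerprint-window grid. All generators are pure
functions of (params, seed) — same seed, bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chem import SolutionSpec, study_solution
from .kinetics import PHTimeSeries
from .reference import MIXTURE_PROTEIN_MOLARITY, RECONSTRUCTION_PARAMS, STUDY_TIME_GRID
from .spectra import Spectrum
from .stoichiometry import BindingMeasurement, CalibrationCurve

__all__ = [
    "KineticSimParams",
    "BindingSimParams",
    "SpectrumSimParams",
    "generate_ph_series",
    "generate_binding_experiment",
    "generate_spectrum",
    "reconstruction_params",
]

#: pH floor applied by the kinetic generator.
PH_FLOOR = 1.0


@dataclass(frozen=True)
class KineticSimParams:
    """Piecewise zero-order pH decay parameters.

    ``breakpoint`` is the knee time in minutes (None = single regime). The
    mean trajectory is continuous: slope ``k0_step1`` before the knee,
    ``k0_step2`` after. Gaussian noise of sd ``noise_sd`` is added
    independently per sample; default 0.01 pH units, a realistic pH-meter
    precision.
    """

    seed: int
    initial_pH: float = 7.14
    breakpoint: float | None = 30.0
    k0_step1: float = 0.031
    k0_step2: float = 5.7e-5
    noise_sd: float = 0.01
    times: Sequence[float] = STUDY_TIME_GRID

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


def mean_ph_trajectory(p: KineticSimParams, times: np.ndarray) -> np.ndarray:
    """Noise-free piecewise-linear mean pH at the given times."""
    t = np.asarray(times, dtype=float)
    if p.breakpoint is None:
        ph = p.initial_pH - p.k0_step1 * t
    else:
        before = np.minimum(t, p.breakpoint)
        after = np.maximum(t - p.breakpoint, 0.0)
        ph = p.initial_pH - p.k0_step1 * before - p.k0_step2 * after
    return ph


def generate_ph_series(p: KineticSimParams,
                       solution: SolutionSpec | None = None,
                       label: str = "") -> PHTimeSeries:
    """Simulate a pH trajectory (piecewise-linear mean + Gaussian noise).

    pH values are floored at 1.0 with a warning if the parameters drive the
    trajectory below the floor.
    """
    rng = np.random.default_rng(p.seed)
    t = np.asarray(p.times, dtype=float)
    ph = mean_ph_trajectory(p, t)
    if p.noise_sd > 0:
        ph = ph + rng.normal(0.0, p.noise_sd, size=len(t))
    if np.any(ph < PH_FLOOR):
        warnings.warn("simulated pH fell below the floor of 1.0; flooring", stacklevel=2)
        ph = np.maximum(ph, PH_FLOOR)
    return PHTimeSeries(times=t, pH=ph,
                        solution=solution if solution is not None else study_solution(),
                        label=label)


def reconstruction_params(analyte: str, seed: int, noise_sd: float = 0.01) -> KineticSimParams:
    """KineticSimParams reconstructing the reported regime of a study cyclitol."""
    try:
        ref = RECONSTRUCTION_PARAMS[analyte]
    except KeyError:
        raise KeyError(
            f"no reconstruction for {analyte!r}; known: {sorted(RECONSTRUCTION_PARAMS)}"
        ) from None
    return KineticSimParams(
        seed=seed,
        initial_pH=ref["initial_pH"],
        breakpoint=ref["breakpoint"],
        k0_step1=ref["k0_step1"],
        k0_step2=ref["k0_step2"],
        noise_sd=noise_sd,
    )


@dataclass(frozen=True)
class BindingSimParams:
    """Forward model of the binding/calibration experiment.

    ``n_bound_rule`` maps a molar ratio r to the true number of bound
    molecules per protein (must not exceed r). The free concentration at
    each ratio is diluted, pushed through the truth calibration curve, and
    perturbed by multiplicative Gaussian noise (default 2% relative, typical
    of SIM peak-area repeatability). Calibration data are generated over
    the 1e-6 to 1e-5 M range.
    """

    seed: int
    curve: CalibrationCurve
    n_bound_rule: Callable[[float], float]
    ratios: Sequence[float] = (2.0, 5.0, 7.0, 10.0)
    protein_molarity: float = MIXTURE_PROTEIN_MOLARITY
    dilution: float = 30.0
    area_noise_rel: float = 0.02
    n_replicates: int = 3
    n_calibration_levels: int = 10
    calibration_range: tuple[float, float] = (1e-6, 1e-5)

    def __post_init__(self) -> None:
        if self.area_noise_rel < 0:
            raise ValueError("area_noise_rel must be non-negative")
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")


def generate_binding_experiment(
    p: BindingSimParams,
) -> tuple[list[BindingMeasurement], np.ndarray, np.ndarray]:
    """Simulate supernatant measurements plus calibration data.

    Returns (measurements, calib_concs, calib_areas). Raises if the binding
    rule tries to bind more ligand than supplied at any ratio.
    """
    rng = np.random.default_rng(p.seed)
    for r in p.ratios:
        if p.n_bound_rule(r) > r + 1e-12:
            raise ValueError(f"n_bound_rule({r}) exceeds the supplied ratio {r}")

    lo, hi = p.calibration_range
    calib_concs = np.linspace(lo, hi, p.n_calibration_levels)
    calib_areas = np.asarray(p.curve.predict(calib_concs), dtype=float)
    if p.area_noise_rel > 0:
        calib_areas = calib_areas * (
            1.0 + rng.normal(0.0, p.area_noise_rel, size=len(calib_areas))
        )

    measurements: list[BindingMeasurement] = []
    for r in p.ratios:
        c0 = r * p.protein_molarity
        c_free = c0 * (1.0 - p.n_bound_rule(r) / r)
        area_true = float(p.curve.predict(c_free / p.dilution))
        for rep in range(p.n_replicates):
            area = area_true
            if p.area_noise_rel > 0:
                area *= 1.0 + rng.normal(0.0, p.area_noise_rel)
            measurements.append(BindingMeasurement(
                analyte=p.curve.analyte or "analyte",
                molar_ratio=float(r),
                peak_area=area,
                c0=c0,
                dilution_factor=p.dilution,
                replicate=rep,
            ))
    return measurements, calib_concs, calib_areas


@dataclass(frozen=True)
class SpectrumSimParams:
    """Sum-of-Gaussians spectrum on a regular wavenumber grid.

    ``peaks`` is a sequence of (center cm^-1, height, sigma cm^-1);
    ``baseline`` holds polynomial coefficients (constant first) evaluated on
    the grid scaled to [-1, 1].
    """

    seed: int
    peaks: Sequence[tuple[float, float, float]] = ()
    baseline: Sequence[float] = (0.0,)
    noise_sd: float = 0.0
    grid_start: float = 1700.0
    grid_stop: float = 900.0
    grid_step: float = 2.0
    technique: str = "FTIR"
    resolution: float = 8.0

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if any(width <= 0 for _, _, width in self.peaks):
            raise ValueError("peak widths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_spectrum(p: SpectrumSimParams, label: str = "") -> Spectrum:
    """Simulate a spectrum: Gaussian peaks + polynomial baseline + noise."""
    rng = np.random.default_rng(p.seed)
    lo, hi = sorted((p.grid_start, p.grid_stop))
    w = np.arange(lo, hi + p.grid_step / 2, p.grid_step)
    if p.grid_start > p.grid_stop:
        w = w[::-1]
    x = (w - w.mean()) / (np.ptp(w) / 2 if np.ptp(w) > 0 else 1.0)
    y = np.polynomial.polynomial.polyval(x, np.asarray(p.baseline, dtype=float))
    for center, height, sigma in p.peaks:
        y = y + height * np.exp(-0.5 * ((w - center) / sigma) ** 2)
    if p.noise_sd > 0:
        y = y + rng.normal(0.0, p.noise_sd, size=len(w))
    return Spectrum(wavenumbers=w, intensities=y, technique=p.technique,
                    resolution=p.resolution, label=label)
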