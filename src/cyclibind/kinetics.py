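"""Zero-order pH kinetics of protein-ligand sorption.

The sorption of a cyclitol onto a protein acidifies the mixture; within each
sorption regime the pH trajectory is well described by a zero-order law

    pH(t) = pH0 - k0 * t

with ``k0`` (min^-1) the rate constant of that regime (positive while the
pH falls). Many trajectories show two regimes — a rapid initial sorption
step followed by a much slower gradual step — so the model supports an
unknown changepoint between two zero-order segments.

Changepoint estimation
----------------------
Candidate breakpoints are restricted to the observation times (the sampling
grids in these experiments are short, eight points, so a continuous
breakpoint parameter is over-parameterised). Each candidate is scored by the
SSE of the *continuous* segmented (hinge) regression

    pH(t) = b0 + b1*t + b2*max(t - tau, 0),

because the pH trajectory is physically continuous; this makes the knee
identifiable even though the knee observation lies on both segments' lines.
The best two-segment model is compared with the single straight line by an
F-test (default alpha = 0.05). Per-segment rate constants are then reported
from unconstrained per-segment least squares, the breakpoint observation
closing the first segment (the rapid step includes its last sample).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chem import SolutionSpec

__all__ = [
    "PHTimeSeries",
    "SegmentFit",
    "KineticModelResult",
    "ZeroOrderKinetics",
    "fit_zero_order_segment",
    "detect_breakpoint",
    "classify_sorption_mechanism",
    "DegenerateFitError",
    "InsufficientDataError",
]


class DegenerateFitError(ValueError):
    """Raised when a least-squares fit is requested on degenerate data."""


class InsufficientDataError(ValueError):
    """Raised when too few observations are available for the requested model."""


@dataclass
class PHTimeSeries:
    """A measured pH trajectory of a protein-ligand mixture.

    ``times`` in minutes (strictly increasing, >= 0), one pH per time,
    at least three observations. ``solution`` carries the mixture
    composition, temperature and the initial (pre-addition) pH.
    """

    times: np.ndarray
    pH: np.ndarray
    solution: SolutionSpec
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pH = np.asarray(self.pH, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.pH.shape:
            raise ValueError("times and pH must be 1-D arrays of equal length")
        if len(self.times) < 3:
            raise ValueError("a pH time series needs at least 3 observations")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.pH))):
            raise ValueError("times and pH must be finite")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.pH <= 0) | (self.pH >= 14)):
            raise ValueError("pH values must lie in (0, 14)")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SegmentFit:
    """Least-squares zero-order fit over one time segment.

    ``k0`` is minus the fitted slope, so a falling pH gives k0 > 0; a pH
    rebound gives k0 < 0. ``intercept`` is the fitted pH at t = 0.
    """

    t_start: float
    t_end: float
    k0: float
    intercept: float
    sse: float
    n_points: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.intercept - self.k0 * np.asarray(t, dtype=float)


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares of y on t. Returns (intercept, slope, sse)."""
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(beta[0]), float(beta[1]), float(r @ r)


def _hinge_sse(t: np.ndarray, y: np.ndarray, tau: float) -> float:
    """SSE of the continuous two-segment (hinge) fit with knot at tau."""
    X = np.column_stack([np.ones_like(t), t, np.maximum(t - tau, 0.0)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def fit_zero_order_segment(times: np.ndarray, pH: np.ndarray) -> SegmentFit:
    """Fit ``pH = intercept - k0 * t`` by ordinary least squares."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(pH, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and pH must be 1-D arrays of equal length")
    if len(t) < 2:
        raise DegenerateFitError("need at least 2 points for a segment fit")
    if np.ptp(t) == 0:
        raise DegenerateFitError("all times identical; slope is undefined")
    intercept, slope, sse = _ols_line(t, y)
    return SegmentFit(
        t_start=float(t.min()),
        t_end=float(t.max()),
        k0=-slope,
        intercept=intercept,
        sse=sse,
        n_points=len(t),
    )


@dataclass
class KineticModelResult:
    """Fitted zero-order kinetic model: one or two contiguous segments.

    ``mechanism`` is "two-step" iff a breakpoint is present iff there are
    exactly two segments. ``model_selection_stat`` is the F statistic of
    the two-segment (continuous hinge) fit against the single line;
    ``bic_one`` / ``bic_two`` are reported as diagnostics.
    """

    segments: list[SegmentFit]
    breakpoint: float | None
    mechanism: str
    model_selection_stat: float
    f_pvalue: float
    sse_one: float
    sse_two: float
    bic_one: float
    bic_two: float
    label: str = ""

    @property
    def k0_step1(self) -> float:
        return self.segments[0].k0

    @property
    def k0_step2(self) -> float | None:
        return self.segments[1].k0 if len(self.segments) == 2 else None

    def classify(self) -> str:
        return classify_sorption_mechanism(self)

    def summary(self) -> str:
        lines = [
            f"Zero-order kinetic model{' for ' + self.label if self.label else ''}",
            f"  mechanism       : {self.mechanism} ({self.classify()})",
            f"  breakpoint      : "
            + (f"{self.breakpoint:g} min" if self.breakpoint is not None else "none"),
            f"  F statistic     : {self.model_selection_stat:.4g}"
            f"  (p = {self.f_pvalue:.4g})",
            f"  BIC one/two-seg : {self.bic_one:.4g} / {self.bic_two:.4g}",
        ]
        for i, seg in enumerate(self.segments, start=1):
            lines.append(
                f"  step {i}: t in [{seg.t_start:g}, {seg.t_end:g}] min, "
                f"k0 = {seg.k0:.4g} min^-1, intercept = {seg.intercept:.4f}, "
                f"sse = {seg.sse:.3g} (n = {seg.n_points})"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot of the fitted segments (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for seg in self.segments:
            tt = np.linspace(seg.t_start, seg.t_end, 50)
            ax.plot(tt, seg.predict(tt), "-")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("pH")
        return ax


def _bic(n: int, sse: float, k: int) -> float:
    # Gaussian log-likelihood BIC; guard the perfect-fit case.
    sse = max(sse, 1e-300)
    return n * math.log(sse / n) + k * math.log(n)


class ZeroOrderKinetics:
    """Zero-order kinetic model of a pH trajectory with optional changepoint.

    Parameters
    ----------
    series : PHTimeSeries
        The measured trajectory.
    min_points_per_segment : int
        Minimum observations per segment (>= 2). Candidate breakpoints are
        observation times leaving at least this many points on each side,
        the breakpoint observation counted in the first segment.
    alpha : float
        Significance level of the F-test for preferring two segments.
    """

    def __init__(self, series: PHTimeSeries, min_points_per_segment: int = 2,
                 alpha: float = 0.05):
        if min_points_per_segment < 2:
            raise ValueError("min_points_per_segment must be >= 2")
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.series = series
        self.min_points_per_segment = min_points_per_segment
        self.alpha = alpha

    def candidate_breakpoints(self) -> np.ndarray:
        t = self.series.times
        n = len(t)
        m = self.min_points_per_segment
        if n < 2 * m:
            return np.empty(0)
        return t[m - 1: n - m]

    def fit(self) -> KineticModelResult:
        t = self.series.times
        y = self.series.pH
        n = len(t)
        one = fit_zero_order_segment(t, y)
        sse_one = one.sse

        candidates = self.candidate_breakpoints()
        if candidates.size == 0:
            if n < 2 * self.min_points_per_segment:
                raise InsufficientDataError(
                    f"need at least {2 * self.min_points_per_segment} observations "
                    f"for breakpoint detection, got {n}"
                )
        sse_two_by_tau = np.array([_hinge_sse(t, y, tau) for tau in candidates])
        # minimal SSE; on exact ties prefer the latest breakpoint (the rapid
        # step extends through the last observation consistent with it)
        best = sse_two_by_tau.min()
        tol = 1e-12 * (1.0 + best)
        best_idx = int(np.flatnonzero(sse_two_by_tau <= best + tol)[-1])
        tau = float(candidates[best_idx])
        sse_two = float(sse_two_by_tau[best_idx])

        # F-test: hinge model spends 2 extra parameters (slope change + knot)
        df_num, df_den = 2, n - 4
        gain = sse_one - sse_two
        if df_den <= 0 or gain <= 0:
            f_stat, pval = 0.0, 1.0
        elif sse_two == 0.0:
            f_stat, pval = math.inf, 0.0
        else:
            f_stat = (gain / df_num) / (sse_two / df_den)
            pval = float(stats.f.sf(f_stat, df_num, df_den))

        two_step = pval < self.alpha
        if two_step:
            left = t <= tau
            segments = [
                fit_zero_order_segment(t[left], y[left]),
                fit_zero_order_segment(t[~left], y[~left]),
            ]
            breakpoint_ = tau
            mechanism = "two-step"
        else:
            segments = [one]
            breakpoint_ = None
            mechanism = "one-step"

        return KineticModelResult(
            segments=segments,
            breakpoint=breakpoint_,
            mechanism=mechanism,
            model_selection_stat=f_stat,
            f_pvalue=pval,
            sse_one=sse_one,
            sse_two=sse_two,
            bic_one=_bic(n, sse_one, 2),
            bic_two=_bic(n, sse_two, 4),
            label=self.series.label,
        )


def detect_breakpoint(series: PHTimeSeries, min_points_per_segment: int = 2,
                      alpha: float = 0.05) -> KineticModelResult:
    """Fit the kinetic model with changepoint detection (see ZeroOrderKinetics)."""
    return ZeroOrderKinetics(series, min_points_per_segment, alpha).fit()


def classify_sorption_mechanism(result: KineticModelResult) -> str:
    """Classify the sorption regime of a fitted kinetic model.

    Returns one of:

    - ``"rapid-equilibrium"`` — a single segment: rapid sorption followed by
      immediate establishment of equilibrium;
    - ``"rapid-then-gradual"`` — two segments, both acidifying (k0 >= 0 in
      the second step);
    - ``"rebound"`` — two segments with a pH *increase* in the second step
      (negative second-step rate constant).
    """
    if len(result.segments) == 1:
        return "rapid-equilibrium"
    if result.segments[1].k0 < 0:
        return "rebound"
    return "rapid-then-gradual"
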