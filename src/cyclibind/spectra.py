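"""FTIR/Raman band-shift analysis of protein-ligand complexes.

Vibrational spectra of a protein control and of protein-ligand complexes are
smoothed, baseline-corrected, and reduced to peak lists; control and complex
peaks are paired (greedy nearest-neighbour within a tolerance, by default
the instrument resolution), and the paired/unpaired peaks are reported as
shifted, new and lost bands, each annotated with the spectral-window
assignment it falls in (amide A/I/II/III backbone bands and the side-chain
bands of the default table).

Peak *positions* only are compared; intensities between separately acquired
spectra are deliberately not compared (the acquisitions are not
quantitative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "Spectrum",
    "Peak",
    "BandAssignment",
    "BandShift",
    "BandShiftReport",
    "preprocess_spectrum",
    "detect_peaks",
    "band_shift_report",
    "default_assignments",
    "load_assignments",
    "save_assignments",
]


@dataclass
class Spectrum:
    """A vibrational spectrum: strictly monotone wavenumber grid + intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    technique: str = "FTIR"
    resolution: float = 8.0
    label: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape or self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.wavenumbers))
                and np.all(np.isfinite(self.intensities))):
            raise ValueError("wavenumbers and intensities must be finite")
        d = np.diff(self.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumbers must be strictly monotone")
        if self.technique not in ("FTIR", "Raman"):
            raise ValueError("technique must be 'FTIR' or 'Raman'")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def ascending(self) -> bool:
        return bool(self.wavenumbers[1] > self.wavenumbers[0])

    def __len__(self) -> int:
        return len(self.wavenumbers)


@dataclass(frozen=True)
class Peak:
    position: float  # cm^-1
    height: float
    prominence: float


@dataclass(frozen=True)
class BandAssignment:
    """A named spectral window [low, high] cm^-1 with its vibration."""

    window: tuple[float, float]
    name: str
    vibration: str = ""

    def __post_init__(self) -> None:
        if self.window[0] > self.window[1]:
            raise ValueError("assignment window must be ordered (low, high)")

    def contains(self, position: float) -> bool:
        return self.window[0] <= position <= self.window[1]


@dataclass(frozen=True)
class BandShift:
    control_position: float
    complex_position: float
    delta: float  # complex - control, cm^-1
    assignment: str
    sub_resolution: bool = False


@dataclass
class BandShiftReport:
    """Band-level comparison of a complex spectrum against the control."""

    shifted: list[BandShift]
    unchanged: list[BandShift]
    new_bands: list[tuple[float, str]]
    lost_bands: list[tuple[float, str]]
    tolerance: float
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "tolerance_cm1": self.tolerance,
            "shifted": [
                {"control": s.control_position, "complex": s.complex_position,
                 "delta": s.delta, "assignment": s.assignment,
                 "sub_resolution": s.sub_resolution}
                for s in self.shifted
            ],
            "unchanged": [
                {"position": s.control_position, "assignment": s.assignment}
                for s in self.unchanged
            ],
            "new_bands": [{"position": p, "assignment": a} for p, a in self.new_bands],
            "lost_bands": [{"position": p, "assignment": a} for p, a in self.lost_bands],
        }

    def summary(self) -> str:
        lines = [f"Band-shift report{' for ' + self.label if self.label else ''} "
                 f"(pairing tolerance {self.tolerance:g} cm^-1)"]
        for s in self.shifted:
            tag = " [sub-resolution]" if s.sub_resolution else ""
            lines.append(f"  shifted: {s.control_position:.1f} -> "
                         f"{s.complex_position:.1f} cm^-1 "
                         f"(delta {s.delta:+.1f}) {s.assignment}{tag}")
        for p, a in self.new_bands:
            lines.append(f"  new band: {p:.1f} cm^-1 ({a})")
        for p, a in self.lost_bands:
            lines.append(f"  lost band: {p:.1f} cm^-1 ({a})")
        if len(lines) == 1:
            lines.append("  no band changes")
        return "\n".join(lines)


def preprocess_spectrum(s: Spectrum, smooth_window: int = 7,
                        baseline_order: int = 3, max_iter: int = 100) -> Spectrum:
    """Savitzky-Golay smoothing followed by iterative polynomial baseline removal.

    The baseline is estimated by repeatedly fitting a polynomial of degree
    ``baseline_order`` and clipping the working signal to the fit from above
    (modified-polyfit scheme); the wavenumber grid is unchanged.
    """
    if smooth_window < 3 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 3")
    if smooth_window > len(s):
        raise ValueError("smooth_window larger than the spectrum")
    if baseline_order > 5:
        raise ValueError("baseline_order must be <= 5")
    order = np.argsort(s.wavenumbers)
    w = s.wavenumbers[order]
    y = s.intensities[order]
    y = savgol_filter(y, smooth_window, polyorder=min(3, smooth_window - 1))
    # scale wavenumbers to [-1, 1] for a well-conditioned polynomial fit
    span = np.ptp(w)
    x = (w - w.mean()) / (span / 2 if span > 0 else 1.0)
    work = y.copy()
    baseline = np.zeros_like(y)
    for _ in range(max_iter):
        coeffs = np.polynomial.polynomial.polyfit(x, work, baseline_order)
        baseline = np.polynomial.polynomial.polyval(x, coeffs)
        clipped = np.minimum(work, baseline)
        if np.allclose(clipped, work, rtol=0, atol=1e-12 * (1 + np.abs(work).max())):
            break
        work = clipped
    corrected = y - baseline
    inverse = np.argsort(order)
    return Spectrum(
        wavenumbers=s.wavenumbers.copy(),
        intensities=corrected[inverse],
        technique=s.technique,
        resolution=s.resolution,
        label=s.label,
    )


def detect_peaks(s: Spectrum, min_prominence: float) -> list[Peak]:
    """Local maxima with prominence >= min_prominence, positions refined by
    parabolic interpolation over the three points at each maximum; sorted by
    descending wavenumber."""
    order = np.argsort(s.wavenumbers)
    w = s.wavenumbers[order]
    y = s.intensities[order]
    idx, props = find_peaks(y, prominence=min_prominence)
    peaks = []
    for i, prom in zip(idx, props["prominences"]):
        pos, height = float(w[i]), float(y[i])
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom < 0:
                delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
                pos = float(w[i] + delta * (w[i + 1] - w[i - 1]) / 2.0)
                height = float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta)
        peaks.append(Peak(position=pos, height=height, prominence=float(prom)))
    return sorted(peaks, key=lambda p: -p.position)


def _assign(position: float, assignments: list[BandAssignment]) -> str:
    for a in assignments:
        if a.contains(position):
            return a.name
    return "unassigned"


def _check_overlaps(assignments: list[BandAssignment]) -> None:
    spans = sorted((a.window, a.name) for a in assignments)
    for (w1, n1), (w2, n2) in zip(spans, spans[1:]):
        if w2[0] < w1[1]:
            warnings.warn(
                f"assignment windows overlap ({n1} {w1} / {n2} {w2}); "
                "first match in table order wins",
                stacklevel=3,
            )
            return


def band_shift_report(control: list[Peak], complex_: list[Peak],
                      assignments: list[BandAssignment] | None = None,
                      tolerance: float = 8.0, label: str = "") -> BandShiftReport:
    """Pair control vs complex peaks and report shifts, new and lost bands.

    Greedy nearest-neighbour pairing: candidate pairs within ``tolerance``
    are taken closest-first, each peak used at most once. Paired peaks with
    a non-zero position difference are "shifted" (flagged sub-resolution
    when |delta| < tolerance, i.e. below the pairing resolution), unpaired
    complex peaks are new bands, unpaired control peaks are lost bands.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if assignments is None:
        assignments = default_assignments("FTIR")
    _check_overlaps(assignments)

    candidates = sorted(
        ((abs(c.position - x.position), i, j)
         for i, c in enumerate(control)
         for j, x in enumerate(complex_)
         if abs(c.position - x.position) <= tolerance),
        key=lambda t: (t[0], control[t[1]].position, complex_[t[2]].position),
    )
    used_c: set[int] = set()
    used_x: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_c or j in used_x:
            continue
        used_c.add(i)
        used_x.add(j)
        pairs.append((i, j))

    shifted, unchanged = [], []
    for i, j in sorted(pairs, key=lambda p: -control[p[0]].position):
        delta = complex_[j].position - control[i].position
        entry = BandShift(
            control_position=control[i].position,
            complex_position=complex_[j].position,
            delta=delta,
            assignment=_assign(control[i].position, assignments),
            sub_resolution=0 < abs(delta) < tolerance,
        )
        (shifted if delta != 0 else unchanged).append(entry)
    new_bands = [(x.position, _assign(x.position, assignments))
                 for j, x in enumerate(complex_) if j not in used_x]
    lost_bands = [(c.position, _assign(c.position, assignments))
                  for i, c in enumerate(control) if i not in used_c]
    return BandShiftReport(
        shifted=shifted,
        unchanged=unchanged,
        new_bands=sorted(new_bands, key=lambda t: -t[0]),
        lost_bands=sorted(lost_bands, key=lambda t: -t[0]),
        tolerance=tolerance,
        label=label,
    )


# Default band table. Side-chain windows precede the broad amide windows so
# that a narrow side-chain feature inside an amide region is named for the
# side chain (first match wins).
_FTIR_ASSIGNMENTS = [
    BandAssignment((1485.0, 1495.0), "phenylalanine ring", "C-C ring stretch"),
    BandAssignment((1440.0, 1460.0), "histidine/CH", "CH3 bend + C-N stretch"),
    BandAssignment((1385.0, 1412.0), "COO- symmetric", "Asp/Glu COO- sym stretch"),
    BandAssignment((1115.0, 1130.0), "Asp/Glu C-O", "C-O stretch"),
    BandAssignment((1080.0, 1095.0), "histidine C-N", "C-N stretch + C-H bend"),
    BandAssignment((1055.0, 1070.0), "threonine C-O", "C-O stretch"),
    BandAssignment((1030.0, 1050.0), "C-O/O-H", "C-O and O-H stretch"),
    BandAssignment((993.0, 1005.0), "phenylalanine ring breathing", "C-C sym stretch"),
    BandAssignment((965.0, 980.0), "serine C-O", "C-O stretch"),
    BandAssignment((3200.0, 3400.0), "amide A", "N-H stretch"),
    BandAssignment((1600.0, 1700.0), "amide I", "C=O stretch (backbone)"),
    BandAssignment((1500.0, 1600.0), "amide II", "N-H bend + C-N stretch"),
    BandAssignment((1200.0, 1350.0), "amide III", "C-N stretch + N-H bend"),
]

_RAMAN_ASSIGNMENTS = [
    BandAssignment((1598.0, 1610.0), "tyrosine ring", "ring stretch, H-bond acceptor"),
    BandAssignment((1560.0, 1575.0), "COO- asymmetric", "Asp/Glu COO- asym stretch"),
    BandAssignment((1500.0, 1515.0), "tryptophan indole", "C-N stretch + C-H/N-H bend"),
    BandAssignment((1445.0, 1460.0), "CH2 scissor", "CH2 scissoring"),
    BandAssignment((1408.0, 1418.0), "glycine C-N", "C-N stretch"),
    BandAssignment((1340.0, 1356.0), "tryptophan C-H", "C-H bend"),
    BandAssignment((1303.0, 1312.0), "alpha-helix", "amide III alpha-helical"),
    BandAssignment((1240.0, 1315.0), "amide III", "C-N stretch + N-H bend"),
    BandAssignment((1228.0, 1239.0), "tyrosine C-O", "C-O + C-C stretch"),
    BandAssignment((1170.0, 1185.0), "tyrosine C-H/O-H", "exocyclic C-H, O-H bend"),
    BandAssignment((1090.0, 1105.0), "histidine C-N", "C-N stretch + C-H bend"),
    BandAssignment((1040.0, 1052.0), "C-O stretch", "cyclitol C-O"),
    BandAssignment((983.0, 990.0), "serine C-O", "C-O stretch"),
    BandAssignment((1600.0, 1700.0), "amide I", "C=O stretch (backbone)"),
    BandAssignment((1500.0, 1600.0), "amide II", "N-H bend + C-N stretch"),
]


def default_assignments(technique: str = "FTIR") -> list[BandAssignment]:
    """The built-in band-assignment table for a technique."""
    if technique == "FTIR":
        return list(_FTIR_ASSIGNMENTS)
    if technique == "Raman":
        return list(_RAMAN_ASSIGNMENTS)
    raise ValueError("technique must be 'FTIR' or 'Raman'")


def load_assignments(path: str | Path) -> list[BandAssignment]:
    """Read an assignment table from a tab-delimited file
    (columns: low_cm1, high_cm1, name, vibration)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        lo, hi, name, *rest = line.split("\t")
        out.append(BandAssignment((float(lo), float(hi)), name,
                                  rest[0] if rest else ""))
    return out


def save_assignments(assignments: list[BandAssignment], path: str | Path) -> None:
    lines = ["# low_cm1\thigh_cm1\tname\tvibration"]
    for a in assignments:
        lines.append(f"{a.window[0]:g}\t{a.window[1]:g}\t{a.name}\t{a.vibration}")
    Path(path).write_text("\n".join(lines) + "\n")
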