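"""Physical-chemistry bookkeeping for protein-cyclitol experiments.

Molar masses from molecular formulas, concentration and unit conversions,
pH <-> hydroxide-ion concentration, mixing (dilution) arithmetic, and the
shared physical constants used by the kinetic and thermodynamic stages.

All computations are carried in full precision; rounding to the precision
conventional in reports (2 d.p. for mg/mL and kcal/mol) happens only in the
reporting layer.
"""

from __future__ import annotations

import configparser
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "ATOMIC_WEIGHTS",
    "Constants",
    "DEFAULT_CONSTANTS",
    "CyclitolSpec",
    "SolutionSpec",
    "formula_mass",
    "molar_to_mass_conc",
    "hydroxide_conc",
    "hydrogen_conc",
    "kj_to_kcal",
    "mixture_conc",
    "load_cyclitol_registry",
    "study_solution",
    "BSA_MOLAR_MASS",
]

#: IUPAC 2021 standard atomic weights (abridged), g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Na": 22.990,
    "K": 39.098,
    "Cl": 35.45,
}

#: Molar mass of bovine serum albumin, g/mol (monomer, ~66.4 kDa).
BSA_MOLAR_MASS = 66_430.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Molar mass (g/mol) of a Hill-notation molecular formula like ``C6H14O6``."""
    pos = 0
    mass = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        element, count = m.group(1), m.group(2)
        if element not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        mass += ATOMIC_WEIGHTS[element] * (int(count) if count else 1)
        pos = m.end()
    if pos != len(formula) or mass == 0.0:
        raise ValueError(f"cannot parse formula {formula!r}")
    return mass


@dataclass(frozen=True)
class Constants:
    """Read-only physical constants shared across the pipeline.

    Attributes
    ----------
    R : float
        Universal gas constant, J/(K mol).
    cal : float
        Thermochemical calorie, J. Used for the kJ/mol -> kcal/mol column.
    pKw : float
        Ionic product of water, -log10 scale. 14.00 is adequate at 22 degC
        relative to pH-meter precision.
    M_OH : float
        Molar mass of the hydroxide ion, g/mol.
    """

    R: float = 8.314
    cal: float = 4.184
    pKw: float = 14.00
    M_OH: float = ATOMIC_WEIGHTS["O"] + ATOMIC_WEIGHTS["H"]  # 17.007


DEFAULT_CONSTANTS = Constants()


@dataclass(frozen=True)
class CyclitolSpec:
    """A cyclitol (polyhydroxylated small molecule) and its MS identity.

    ``structure_class`` distinguishes open-chain polyols ("linear", e.g.
    D-sorbitol, adonitol) from hydroxylated cyclohexane/-ene carboxylic
    acids ("cyclic", e.g. shikimic and quinic acid). ``pKa`` is carried as
    interpretation metadata only and enters no computation.
    """

    name: str
    formula: str
    structure_class: str
    molar_mass: float | None = None
    pKa: float | None = None
    mz: float | None = None
    ionization: str = "negative"

    def __post_init__(self) -> None:
        if self.structure_class not in ("linear", "cyclic"):
            raise ValueError(
                f"structure_class must be 'linear' or 'cyclic', got {self.structure_class!r}"
            )
        computed = formula_mass(self.formula)
        if self.molar_mass is None:
            object.__setattr__(self, "molar_mass", computed)
        elif abs(self.molar_mass - computed) > 0.05:
            raise ValueError(
                f"molar_mass {self.molar_mass} inconsistent with formula "
                f"{self.formula} ({computed:.3f} g/mol)"
            )
        if self.ionization not in ("positive", "negative"):
            raise ValueError(f"ionization must be 'positive' or 'negative', got {self.ionization!r}")


@dataclass(frozen=True)
class SolutionSpec:
    """Composition and state of a protein + ligand mixture.

    Volumes in mL, masses in mg, temperature in K. ``protein_conc`` is the
    protein concentration in the final mixture (mg/mL).
    """

    protein_conc: float
    protein_volume: float
    ligand_volume: float
    total_volume: float
    protein_mass: float
    temperature: float
    initial_pH: float

    def __post_init__(self) -> None:
        if not math.isclose(self.total_volume, self.protein_volume + self.ligand_volume,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("total_volume must equal protein_volume + ligand_volume")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if not 0 < self.initial_pH < 14:
            raise ValueError("initial_pH must lie in (0, 14)")

    @classmethod
    def from_mixing(
        cls,
        protein_stock_mg_ml: float,
        protein_volume_ml: float,
        ligand_volume_ml: float,
        temperature_c: float,
        initial_ph: float,
    ) -> "SolutionSpec":
        """Build the spec from how the mixture was actually prepared."""
        total = protein_volume_ml + ligand_volume_ml
        mass = protein_stock_mg_ml * protein_volume_ml
        return cls(
            protein_conc=mass / total,
            protein_volume=protein_volume_ml,
            ligand_volume=ligand_volume_ml,
            total_volume=total,
            protein_mass=mass,
            temperature=temperature_c + 273.15,
            initial_pH=initial_ph,
        )


def study_solution() -> SolutionSpec:
    """The default kinetic-study mixture: 2 mL protein stock (1 mg/mL) +
    1 mL cyclitol solution at 22 degC, initial protein-solution pH 7.14."""
    return SolutionSpec.from_mixing(
        protein_stock_mg_ml=1.0,
        protein_volume_ml=2.0,
        ligand_volume_ml=1.0,
        temperature_c=22.0,
        initial_ph=7.14,
    )


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


def molar_to_mass_conc(molarity: float, molar_mass: float) -> float:
    """Convert mol/L to mg/mL (numerically equal to g/L).

    >>> round(molar_to_mass_conc(3.01e-2, 182.172), 2)
    5.48
    """
    _require_finite("molarity", molarity)
    _require_finite("molar_mass", molar_mass)
    if molarity < 0:
        raise ValueError("molarity must be non-negative")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    return molarity * molar_mass


def hydroxide_conc(pH: float, pKw: float = DEFAULT_CONSTANTS.pKw) -> float:
    """Hydroxide-ion concentration (mol/L) at a given pH: 10**(pH - pKw)."""
    _require_finite("pH", pH)
    if not 0 <= pH <= pKw:
        raise ValueError(f"pH must lie in [0, pKw={pKw}], got {pH}")
    return 10.0 ** (pH - pKw)


def hydrogen_conc(pH: float) -> float:
    """Hydronium-ion concentration (mol/L): 10**(-pH)."""
    _require_finite("pH", pH)
    return 10.0 ** (-pH)


def kj_to_kcal(x: float) -> float:
    """kJ/mol -> kcal/mol using the thermochemical calorie (4.184 J)."""
    _require_finite("x", x)
    return x / DEFAULT_CONSTANTS.cal


def mixture_conc(stock_conc: float, stock_volume: float, total_volume: float) -> float:
    """Concentration of a component after dilution into a mixture.

    Volumes may be in any single consistent unit.
    """
    for name, v in (("stock_conc", stock_conc), ("stock_volume", stock_volume),
                    ("total_volume", total_volume)):
        _require_finite(name, v)
    if stock_volume <= 0 or total_volume <= 0:
        raise ValueError("volumes must be positive")
    if stock_volume > total_volume:
        raise ValueError("stock_volume cannot exceed total_volume")
    return stock_conc * stock_volume / total_volume


def _parse_optional_float(section: configparser.SectionProxy, key: str) -> float | None:
    raw = section.get(key, "").strip()
    return float(raw) if raw else None


def load_cyclitol_registry(path: str | Path | None = None) -> dict[str, CyclitolSpec]:
    """Load the cyclitol registry from a key-value config file.

    Without a path, the built-in registry of the four study cyclitols is
    loaded. Users can extend or replace it with a file of the same format::

        [d-sorbitol]
        formula = C6H14O6
        class = linear
        mz = 181
        ionization = negative
    """
    parser = configparser.ConfigParser()
    if path is None:
        text = resources.files("cyclibind.data").joinpath("cyclitols.cfg").read_text()
        parser.read_string(text)
    else:
        read = parser.read(str(path))
        if not read:
            raise FileNotFoundError(path)
    registry: dict[str, CyclitolSpec] = {}
    for name in parser.sections():
        sec = parser[name]
        registry[name] = CyclitolSpec(
            name=name,
            formula=sec["formula"],
            structure_class=sec["class"],
            pKa=_parse_optional_float(sec, "pka"),
            mz=_parse_optional_float(sec, "mz"),
            ionization=sec.get("ionization", "negative"),
        )
    return registry
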