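"""Published reference values for the BSA-cyclitol system.

These constants are the reported experimental outcomes for the four study
cyclitols (D-sorbitol, adonitol, shikimic acid, D-(-)-quinic acid) binding
to bovine serum albumin. They serve three roles:

1. inputs to the consistency audit of the reported binding table;
2. targets/scales for the synthetic reconstructions in :mod:`cyclibind.simulate`;
3. fixtures for the regression tests.

The raw instrument traces behind the kinetic constants were never deposited,
so the kinetic entries are *reported fit results*, not data; synthetic
reconstructions built from them preserve the regime structure (see
``RECONSTRUCTION_PARAMS`` and docs/methods.md) rather than claiming to
regenerate the originals.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "STOCK_MOLARITY",
    "REPORTED_STOCK_MG_ML",
    "REPORTED_KINETICS",
    "REPORTED_CALIBRATIONS",
    "reference_binding_table",
    "RECONSTRUCTION_PARAMS",
    "STUDY_TIME_GRID",
    "MIXTURE_PROTEIN_MOLARITY",
]

#: Molar concentration of every cyclitol stock solution (mol/L).
STOCK_MOLARITY = 3.01e-2

#: Reported stock mass concentrations (mg/mL, 2 d.p.) for the four cyclitols.
REPORTED_STOCK_MG_ML = {
    "d-sorbitol": 5.48,
    "adonitol": 4.58,
    "shikimic-acid": 5.24,
    "quinic-acid": 5.78,
}

#: Reported kinetic / sorption / thermodynamic fit results per cyclitol.
#: k0 in min^-1 (None = no such step reported), A in mg/g,
#: K_ip in (mg/g)/min^0.5, dG in kJ/mol and kcal/mol.
REPORTED_KINETICS = {
    "d-sorbitol": {"k0_step1": 0.031, "k0_step2": 5.7e-5, "A": 0.00199,
                   "K_ip": 4.77e-5, "dG_kJ": -21.74, "dG_kcal": -5.20},
    "adonitol": {"k0_step1": 0.030, "k0_step2": 6.4e-5, "A": 0.00230,
                 "K_ip": 3.52e-5, "dG_kJ": -21.69, "dG_kcal": -5.18},
    "shikimic-acid": {"k0_step1": 0.364, "k0_step2": None, "A": 0.00281,
                      "K_ip": 2.89e-5, "dG_kJ": -26.37, "dG_kcal": -6.30},
    "quinic-acid": {"k0_step1": 1.94, "k0_step2": -0.017, "A": 0.00282,
                    "K_ip": 2.85e-5, "dG_kJ": -26.16, "dG_kcal": -6.25},
}

#: Reported SIM calibration curves: area = slope * conc(mol/L) + intercept,
#: fitted over 1e-6 to 1e-5 M. No linear response was obtained for adonitol.
REPORTED_CALIBRATIONS = {
    "d-sorbitol": {"slope": 4.00e11, "intercept": 506_935.0, "r_squared": 0.9985},
    "shikimic-acid": {"slope": 1.29e11, "intercept": 85_318.0, "r_squared": 0.9982},
    "quinic-acid": {"slope": 5.00e11, "intercept": 433_847.0, "r_squared": 0.9960},
}

_BINDING_ROWS = [
    # analyte, molar_ratio, bound_percent, sd_percent, n_bound, sd_n_bound
    ("d-sorbitol", 2, 49.92, 0.29, 0.99, 0.01),
    ("d-sorbitol", 5, 17.75, 1.02, 0.89, 0.01),
    ("d-sorbitol", 7, 23.92, 1.13, 1.67, 0.08),
    ("d-sorbitol", 10, 20.89, 1.25, 2.09, 0.13),
    ("shikimic-acid", 2, 92.56, 1.49, 1.85, 0.03),
    ("shikimic-acid", 5, 2.75, 0.09, 54.98, 1.77),
    ("shikimic-acid", 7, 3.20, 0.02, 45.70, 0.31),
    ("quinic-acid", 2, 3.95, 0.44, 0.08, 0.01),
    ("quinic-acid", 7, 32.55, 1.31, 2.28, 0.09),
    ("quinic-acid", 10, 39.27, 0.94, 3.93, 0.09),
]


def reference_binding_table() -> pd.DataFrame:
    """The reported binding table, exactly as printed (including the two
    shikimic-acid rows whose percent and n_bound columns appear swapped —
    the consistency audit flags them)."""
    return pd.DataFrame(
        _BINDING_ROWS,
        columns=["analyte", "molar_ratio", "bound_percent", "sd_percent",
                 "n_bound", "sd_n_bound"],
    )


#: Sampling grid of the kinetic experiments (minutes).
STUDY_TIME_GRID = (1.0, 5.0, 10.0, 30.0, 60.0, 120.0, 300.0, 1440.0)

#: Protein concentration in the 300 uL binding mixture (mol/L):
#: 1 mg/mL stock diluted 200/300 (= 0.667 g/L), over the BSA monomer mass.
MIXTURE_PROTEIN_MOLARITY = (1.0 * 200.0 / 300.0) / 66_430.0

#: Synthetic-reconstruction parameters per cyclitol (see docs/methods.md).
#: The linear cyclitols use the reported constants verbatim (they are
#: consistent with the sampling grid). The cyclic acids' reported rapid-step
#: constants describe transients faster than the grid resolves, so their
#: reconstructions preserve the regime structure instead: shikimic acid
#: completes its drop before the first sample (one-step equilibrium),
#: quinic acid drops fast within the first five minutes then rebounds
#: slightly (two-step with negative second-step constant). Equilibrium pH
#: levels are chosen so the end-to-end Gibbs energies land in the reported
#: -27 to -21 kJ/mol range.
RECONSTRUCTION_PARAMS = {
    "d-sorbitol": {"initial_pH": 7.14, "breakpoint": 30.0,
                   "k0_step1": 0.031, "k0_step2": 5.7e-5},
    "adonitol": {"initial_pH": 7.14, "breakpoint": 30.0,
                 "k0_step1": 0.030, "k0_step2": 6.4e-5},
    "shikimic-acid": {"initial_pH": 7.14, "breakpoint": 0.5,
                      "k0_step1": 2.94, "k0_step2": 0.0},
    "quinic-acid": {"initial_pH": 7.14, "breakpoint": 5.0,
                    "k0_step1": 0.318, "k0_step2": -5.0e-5},
}
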