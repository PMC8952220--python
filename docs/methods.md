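# Methods

This note documents the models implemented in `cyclibind`, the choices made
where the methodology was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Zero-order kinetics and changepoint detection

Within a sorption regime the pH of a protein–cyclitol mixture is modelled
as pH(t) = pH₀ − k₀·t, with k₀ (min⁻¹) positive while the mixture
acidifies. Trajectories may show one regime (rapid sorption followed by
immediate equilibrium) or two (rapid then gradual, occasionally with a
late pH rebound, i.e. a negative second-step constant).

**Breakpoint search.** Candidate breakpoints are restricted to the observed
sampling times: the experiments behind this design sample only eight times
(1, 5, 10, 30, 60, 120, 300, 1440 min), so a continuous breakpoint
parameter is over-parameterised. Each candidate knot τ is scored by the SSE
of the *continuous* segmented regression
pH = b₀ + b₁·t + b₂·max(t − τ, 0). Continuity matters for identifiability:
because the underlying trajectory is continuous, the observation at the
knee lies on both segments' lines, and scoring by unconstrained per-segment
fits would leave the knee position undetermined up to one grid position
(the two adjacent candidates tie in expectation). The continuous score is
uniquely minimised at the true knee. After selection, the per-step rate
constants are reported from unconstrained per-segment ordinary least
squares — the convention of per-step linear fits — with the breakpoint
observation closing Step I (the "rapid stage" includes its last sample).

**Model selection.** The best two-segment fit is compared with the single
line by an F-test with 2 numerator degrees of freedom (slope change +
knot) and n − 4 denominator degrees of freedom, at α = 0.05 by default.
BIC for both models is reported as a diagnostic. A perfect single line is
always classified one-step; a perfect two-segment fit with a worse single
line is always two-step.

**Classification.** One segment → "rapid-equilibrium"; two segments with a
non-negative second-step constant → "rapid-then-gradual"; a negative
second-step constant (pH rebound) → "rebound".

## From pH to sorbed quantity

The sorbed quantity is defined as the change in hydroxide availability per
gram of protein:

    q_t = ([OH⁻]₀ − [OH⁻]_t) · M_OH · V / m      [mg/g]

with [OH⁻] = 10^(pH − pKw) mol/L, M_OH = 17.007 g/mol, V the mixture
volume and m the protein mass. This is the only dimensionally consistent
reading of "change in the number of hydroxyl groups on the protein, mg/g";
the map is exactly invertible (`ph_from_sorption`), and q_t may be negative
if the pH rises above its initial value. pKw is fixed at 14.00
(configurable); at 22 °C the error against the true ion product is
negligible relative to pH-meter precision (±0.01).

**Unit discord, honoured literally.** The Weber–Morris equation uses q in
mg/g while the distribution-constant equation uses mg/kg. Both conventions
are followed as stated: q_t stays in mg/g for the √t fit, and the
equilibrium value is multiplied by 1000 for K_D = q_eq/C_e, with C_e the
equilibrium hydroxide concentration in mg/L. K_D is then used as a bare
number in ΔG = −RT·ln(K_D). This convention is prominent rather than
hidden because K_D (and hence ΔG) shifts by RT·ln(1000) ≈ 17 kJ/mol under
the alternative mg/g reading; with the mg/kg convention the synthetic
reconstructions land in the reported −27…−21 kJ/mol band.

**Other conventions.** Equilibrium is the last observation (1440 min)
unless overridden. A negative equilibrium q (rebound above initial pH) is
clipped to zero with a warning and ΔG is reported undefined. The headline
(A, K_ip) pair is the full-series fit — reported tables print a single pair
per cyclitol even for visibly two-step sorption plots, and which segment
such tables report is not stated — with per-segment fits emitted as
diagnostics.

## Stoichiometry

Calibration is unweighted OLS of peak area on concentration over
1×10⁻⁶–1×10⁻⁵ M; inversion is (area − intercept)/slope times the dilution
factor (30× by default). A below-blank response clips to 0 mol/L with a
warning (blank-level noise is expected at the weakest-binding conditions);
a back-calculated concentration outside the calibration range warns but
proceeds. c₀ is taken as the initial ligand concentration in the
pre-centrifugation mixture (stock × 100/300), since the bound percentage is
defined against the mixture. The bound fraction is clipped to [0, 100] %
with a warning; n_bound = bound%/100 × ratio exactly. Adonitol has no
built-in calibration (no linear response could be obtained for it); it is
quantified only if the user supplies a curve.

**Binding-table audit.** The reference binding table shipped with the
package satisfies n_bound = r·bound%/100 to the printed precision (one
unit in the second decimal) in 8 of 10 rows; the shikimic-acid 1:5 and 1:7
rows satisfy it only with the two columns swapped, and the audit flags
exactly those as "transposed". The audit records the anomaly; it does not
decide which orientation was intended.

## Spectra

Preprocessing is Savitzky–Golay smoothing (window 7, order ≤ 3) followed by
iterative polynomial baseline estimation (fit, clip-from-above, refit;
degree 3 by default, ≤ 5). Peaks are local maxima above a prominence
threshold, with positions refined by parabolic interpolation over the three
samples at each maximum. Pairing of control vs complex peaks is greedy
nearest-neighbour within a tolerance defaulting to the instrument
resolution (8 cm⁻¹ for the FTIR acquisitions this mirrors); reported
shifts smaller than that tolerance are flagged "sub-resolution" rather than
suppressed, because meaningful shifts of ±2 cm⁻¹ occur in this system.
Unpaired complex peaks are new bands, unpaired control peaks lost bands;
each is annotated with the first matching window of the assignment table
(narrow side-chain windows are listed before the broad amide windows, so
first-match-wins names a side-chain feature inside an amide region
correctly; overlaps emit a warning). Intensities between separately
acquired spectra are deliberately never compared — the acquisitions are
not quantitative.

## Synthetic reconstructions

The generators emulate the study conditions: the eight-point sampling grid,
an initial protein-solution pH of 7.14, 2 mL protein (1 mg/mL) + 1 mL
cyclitol at 22 °C, additive Gaussian pH noise of σ = 0.01 (pH-meter
precision), 2 % multiplicative noise on MS peak areas, calibration over
1×10⁻⁶–1×10⁻⁵ M with 30× supernatant dilution, and Gaussian-peak spectra
with polynomial baselines in the 1700–900 cm⁻¹ fingerprint window.

Per-cyclitol kinetic reconstructions (in `cyclibind.reference`):

- **D-sorbitol / adonitol** use the reported constants verbatim
  (k₀ᴵ = 0.031 / 0.030 min⁻¹, knee at 30 min, k₀ᴵᴵ = 5.7×10⁻⁵ /
  6.4×10⁻⁵ min⁻¹) — these are fully consistent with the grid.
- **Shikimic acid / quinic acid**: the reported rapid-step constants
  (0.364 and 1.94 min⁻¹) describe transients faster than the grid can
  resolve — extended over even the first sampling interval they drive the
  pH far below zero. The reconstructions therefore preserve the *regime
  structure*: shikimic acid completes its drop before the first sample
  (one-step, immediate equilibrium); quinic acid drops rapidly within the
  first five minutes and then rebounds slightly (two-step with a negative
  second-step constant). Their equilibrium pH levels are set so the
  end-to-end ΔG lands in the reported −27…−21 kJ/mol range. Recovering the
  printed rapid-step constants for the cyclic acids is therefore *not* a
  goal of the synthetic tests; regime labels, the linear-cyclitol
  constants, and the thermodynamic band are.

**What passing tests show.** Parameter recovery on these conditions
demonstrates that the estimators are correct and well-behaved at the
study's noise level and design; it does not validate the zero-order model
against real trajectories (the raw traces were never published), nor does
it probe instrument artefacts (drift, electrode hysteresis, MS carryover)
that the noise models omit.

## Numerical choices

- OLS via `numpy.linalg.lstsq`; tests verify agreement with closed-form
  normal equations to 1×10⁻¹⁰ and the changepoint search against an
  independent brute-force enumeration.
- Exact SSE ties in the breakpoint search (possible only on noise-free
  data) resolve to the *latest* candidate, so the rapid step extends
  through the last observation consistent with it.
- All computation is double precision; rounding happens only in the report
  writers (ΔG and bound molecules to 2 d.p., rate constants to 3 s.f.).
  Report files use fixed formatting, so identical inputs and seed give
  byte-identical outputs.
- Problem sizes in tests and the acceptance script (100 recovery seeds,
  8-point grids, 10-level calibrations, ~400-point spectra) mirror the
  study scale; the full suite runs in a few seconds.

## Known limitations

- The pH→q_t map treats all hydroxide change as protein-surface sorption;
  buffer effects, activity coefficients and temperature dependence of pKw
  are out of scope.
- Pseudo-first/second-order sorption models and Langmuir/Freundlich
  isotherms are not implemented (the zero-order + Weber–Morris pair is the
  scope).
- Spectral analysis reports band positions only; secondary-structure
  content estimation by amide-I deconvolution is out of scope.
- The F-test assumes independent homoscedastic Gaussian errors; with only
  eight observations its power against subtle second regimes is limited,
  which is why BIC is also reported.
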