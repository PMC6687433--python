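# Methods

This note documents the models implemented in shuttlekit, their
assumptions, the defaults and why they were chosen, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## Diffusion–production model

A biofilm streak secreting a redox shuttle into a gel is reduced to one
spatial dimension (the coordinate perpendicular to the streak):

    ∂C/∂t = D ∂²C/∂x² + P(x),   C(x, 0) = 0,   C(0, t) = C(L, t) = 0

* C — shuttle concentration, mol cm⁻³ internally; converted to nM
  (× 10¹²) only at reporting boundaries, in one tested converter.
* D — gel diffusion coefficient, cm² s⁻¹. The default derivation takes
  an aqueous coefficient of 5.2 × 10⁻⁶ cm² s⁻¹ and scales it by 0.95,
  the retention fraction typical for small molecules in dilute (1.5%)
  agarose, whose porosity is large relative to the molecule; rounded to
  one significant figure for reporting, this gives 5 × 10⁻⁶ cm² s⁻¹.
  Rounding is never fed back into computation.
* P(x) — volumetric production, nonzero inside a rectangular streak of
  width 0.1 cm at volumetric cell density 1 × 10⁹ cells cm⁻³ by
  default. **Non-identifiability:** the solution is linear in
  `cell_density × per_cell_rate × width`; a concentration profile
  cannot distinguish these factors, and absolute predictions are only
  as good as the assumed source strength. Every headline accumulation
  number must be read with this caveat.

A note on the equation's sign: the diffusion term must enter with a
positive sign (+D ∂²C/∂x²); the anti-diffusive sign is unconditionally
unstable and produces no bounded solution. The package implements the
physically correct form.

### Per-cell secretion rate

From a stationary-phase planktonic culture accumulating concentration
C_f (mol L⁻¹) over time t at cell density ρ (cells mL⁻¹):

    p = C_f / (10³ ρ) / t    [mol cell⁻¹ s⁻¹]

For the bench values shipped in the demo (1.5 nM over 4 days at
1 × 10⁹ cells mL⁻¹) this yields 4.34 × 10⁻²⁷ mol cell⁻¹ s⁻¹. A value of
4 × 10⁻²³ is sometimes quoted for the same inputs — four orders of
magnitude larger; `per_cell_production_rate` accepts an `expected`
value and emits a `ProductionRateDiscrepancyWarning` whenever the
recomputation differs from it by more than 10×, returning the
recomputed value unmodified. Transparency is preferred over silent
agreement in either direction. (The demo simulation uses the larger
quoted rate for its source term; with the default streak geometry it
peaks near 450 nM after two days, while the recomputed rate would give
four orders of magnitude less. Both are reported, neither is asserted
as ground truth.)

### Numerics

Forward-time centred-space (FTCS): second-order centred Laplacian, the
source added as P·dt each step, endpoints pinned to the boundary value.

* Stability: dt ≤ dx²/(2D) is enforced — a larger timestep raises an
  error rather than running unstably. `dt="auto"` uses 0.4 × the bound,
  a comfortable margin at negligible cost for desk-scale problems; the
  timestep is then shrunk slightly so an integer number of steps lands
  exactly on `t_end`.
* Grid: dx = 0.01 cm on the 10 cm domain (1001 nodes) by default. The
  domain is deliberately much longer than the diffusion length
  √(4Dt) ≈ 0.9 cm at two days, keeping the Dirichlet boundaries inert.
* Verification: a continuous plane source of areal strength q at x = 0
  in an infinite medium has the closed form
  C(x,t) = q[√(t/(πD))·e^(−x²/4Dt) − (|x|/2D)·erfc(|x|/√(4Dt))]
  (time-integral of the instantaneous-source Green's function; checked
  in the tests against independent quadrature). The solver matches it
  to ≪ 2% in relative L∞ at dx = 0.01 cm and converges at second order
  in dx (error ratio ≈ 4 when dx is halved). Mass balance
  ∫C dx = ∫∫P dx dt holds to rounding error while the front is away
  from the boundary.

## Exact-mass identification

Monoisotopic masses are pinned constants (version `pinned-2020.1`,
CODATA/AME values to 10 significant figures) rather than a library
lookup, so calculated m/z values are stable to the fourth decimal
regardless of dependency drift. Supported adducts: [M+H]⁺, [M+Na]⁺,
[M+D]⁺, [M−H₂O+H]⁺, [M+NH₄]⁺, [M−H]⁻ (all |z| = 1).

* Two m/z conventions are first-class because published values mix
  them: with the electron-mass correction (subtract z·mₑ; the physical
  ion mass; default) and without (neutral-atom sums). For the
  C₁₁H₇NO₄ shuttle these give 218.0448 and 218.0453 for [M+H]⁺.
* ppm error puts the calculated mass in the denominator and is
  reported to one decimal. Candidate screening annotates each match
  with the calculated m/z at reporting precision (4 decimals), which is
  how printed ppm values are conventionally derived.
* Exchangeable (labile) hydrogens are counted from a functional-group
  profile (primary amine 2, secondary amine/OH/SH/COOH 1 each, amide
  N–H per hydrogen) instead of parsing structures — this avoids a
  cheminformatics dependency and keeps the arithmetic testable. The
  shuttle's 2-amino and 3-carboxy groups give 3 of its 7 protons.
* D₂O-exchange shifts: exact shift k·(m_D − m_H) with k = n_labile
  under the default exchange-only convention. The alternative
  include-ionizing-deuteron convention (k = n_labile + 1, protonated
  adducts only) is provided because the ionizing proton of an [M+D]⁺
  species is itself a deuteron; which convention an observed nominal
  shift reflects depends on in-source back-exchange and cannot be
  resolved from the shift alone. Both are exposed; exchange-only
  reproduces the nominal 3 Da sodiated-adduct shift for 3 labile
  hydrogens.

## Standard-curve quantification

Areas of the extracted-ion chromatograms for a compound's adducts
(e.g. [M+H]⁺ + [M−H₂O+H]⁺) are summed and read against an external
standard curve fitted by unweighted ordinary least squares with a free
intercept (a force-through-zero option exists). Weighting is not
applied because calibration noise structure is rarely known at these
point counts (4–6 standards). Back-calculation divides by a recovery
fraction estimated from an isotope-labelled spike (measured/spiked).
Negative back-calculated concentrations are reported and flagged
`below_blank`, never clipped; values outside the calibration range are
flagged `extrapolated` but allowed, since real unknowns often sit near
the curve's low end. Detection/quantification limits are instrument
properties and are out of scope.

## Dose–response (EC₅₀)

The four-parameter logistic in the OriginLab `DoseResp`
parameterization,

    y = A₁ + (A₂ − A₁) / (1 + 10^((log₁₀x₀ − log₁₀x)·p)),

is fitted by unweighted nonlinear least squares so published EC₅₀
semantics carry over directly. Replicates enter as individual points.
Zero-dose controls cannot sit on the log axis; they are split off and
used only to seed the lower asymptote. Optimisation runs
Levenberg–Marquardt from a fixed-order multi-start grid (5 log₁₀x₀
values spanning the observed range × Hill slopes {0.5, 1, 2}), keeping
the fit deterministic and robust to local minima; the best RSS wins.
Standard errors are asymptotic (σ²(JᵀJ)⁻¹ at the optimum) and labelled
as such; the EC₅₀ SE uses the delta method from the log₁₀ scale.
Bootstrap intervals are out of scope.

## Electroanalytical feature extraction

All currents are carried as densities (µA cm⁻², normalized by geometric
electrode area at ingestion); potentials are V vs Ag/AgCl within the
−0.8 … +0.6 V instrument window.

* **Steady-state currents** are windowed means (≥ 10 samples) with a
  linear drift slope as a did-it-really-plateau diagnostic; percent and
  fold changes are computed between windowed means. Windowed means are
  used rather than instantaneous samples because they are robust to
  noise; this choice is documented since reported percent
  drops/recoveries depend on it.
* **DPV**: a linear baseline is fitted over the outer 20% of the scan
  on each side; the apex of the lightly smoothed (Savitzky–Golay,
  11-point, order 2) baseline-subtracted signal must exceed 3× the raw
  flank noise, else a no-peak error; W_1/2 comes from linear
  interpolation of the two half-height crossings. The apparent electron
  count uses the small-amplitude Nernstian limit W_1/2 = 3.526·RT/nF
  (≈ 90.6/n mV at 298.15 K, configurable temperature). This criterion
  is an interpretive layer: it assumes a reversible couple probed with
  a pulse amplitude small relative to RT/nF; a 66 mV width maps to
  n ≈ 1.4, i.e. more than one electron.
* **CV**: the catalytic-wave onset is the first potential on the
  positive-going sweep where the smoothed current exceeds a linear
  baseline (fitted over a user-supplied pre-wave potential window) by
  3× the baseline noise SD (with a tiny relative floor so noiseless
  traces behave). The midpoint potential is the mean of the anodic and
  cathodic peak potentials, reported only when both are interior local
  extrema with ≥ 10% prominence relative to their excursion — a
  monotone steady-state catalytic wave therefore yields an onset but no
  midpoint. A trace with no wave returns a no-wave result, not an
  exception.

## Synthetic-data generators

Each generator takes explicit truth parameters and a mandatory seed,
draws from its own `numpy.random.default_rng` stream, and returns the
consuming module's container plus a `truth` record, so every estimator
is round-tripped against known truth. Noise is Gaussian throughout;
heavier-tailed options are deferred.

Defaults encode the study conditions the package targets: 8 doses × 3
replicates with noise at 2% of the dynamic range and EC₅₀ 25 nM for
dose–response; 1 mV-resolution scans with a formal potential of
−0.32 V; chronoamperometry plateaus near 22 µA cm⁻² with media-swap
segments; six-point calibration lines.

* The DPV peak is the analytic small-amplitude Nernstian shape
  (∝ sech²(nF(E−E₀)/2RT)) rather than a full pulse-train simulation —
  deliberately, since that is the regime the W_1/2 criterion assumes.
* The reversible CV couple is produced by an explicit finite-difference
  simulation of semi-infinite diffusion with a Nernstian surface
  condition and equal diffusivities (24 internal time substeps per 1 mV
  sample). Its anodic–cathodic peak separation is an emergent property,
  checked in tests against the textbook ≈ 57–59/n mV at 25 °C.
* The catalytic wave is zero below a stated foot potential and rises as
  1 − exp(−(E−foot)/w), giving the onset detector a well-defined truth.
* Chronoamperometry is piecewise-exponential relaxation toward segment
  plateaus, continuous across segment boundaries, with labelled events.

What the generators do **not** emulate — and hence what passing tests
do not show about real data: instrument drift and 1/f noise, capacitive
and ohmic distortions of voltammograms, adsorbed-species contributions,
chromatographic peak-shape variability, matrix effects on ionisation,
and any biological variability between cultures. Estimator performance
quoted here (e.g. median EC₅₀ error ≈ 4% at 2% noise) is a property of
these idealised conditions.

## Problem sizes

The shipped analyses run at desk scale by design: 1001–2001 grid nodes
and ≤ 10⁴ timesteps for the diffusion verification, 100 datasets × 24
points for the EC₅₀ recovery study, 1401-point voltammograms, two-day
simulation horizon at dt = 4 s. The full test suite and the acceptance
script each complete in well under a minute on one CPU.

## Known limitations

* 1-D geometry only; no shuttle consumption, degradation, cell growth,
  or electrode-kinetics coupling in the transport model.
* Source strength is non-identifiable from concentration profiles
  (see above); absolute accumulation predictions inherit its
  uncertainty linearly.
* The electron-count criterion and the reversible-couple generator both
  assume Nernstian (fast) electrode kinetics.
* Quantification assumes linear response over the calibration range and
  a single scalar recovery factor.
* Asymptotic standard errors for the 4PL can be optimistic near
  parameter bounds or with few doses.
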