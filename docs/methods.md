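# Methods

## Model

The cantilever is a driven damped harmonic oscillator: spring constant
`k_cant` (N/m), first-mode eigenfrequency `f_cant` (Hz) and quality factor
`Q_cant`, from which the modal mass `m_cant = k_cant/(2π f_cant)²` and the
damping coefficient `c_cant = √(k_cant m_cant)/Q_cant` follow. The cell is
a point mass `m` attached to the lever end through a Kelvin–Voigt element
(spring `k_cell` and damper `c_cell` in parallel). All responses use the
`e^{+iωt}` time convention, so dissipation enters as `+iωc` and the complex
coupling stiffness is `K(ω) = k_cell + iω c_cell`.

Eliminating the cell coordinate gives the effective dynamic mass the
payload presents to the lever,

    m_eff(ω) = m K(ω) / (K(ω) − ω² m),

with `Im{m_eff} ≤ 0` under this convention (the payload only ever absorbs
energy; asserted in tests). The lever end deflection under a harmonic
force `F` is `X(ω) = F / (k_cant − ω²[m_cant + m_eff(ω)] + iω c_cant)`.
`Re{m_eff}` evaluated at `ω = 2π f_cant` gives the closed-form readout
accuracy `m_app/m_real` quoted in the README; the identity between the two
routes is checked to 1e-10 over 10⁴ random parameter draws.

Assumptions worth keeping in mind: a single flexural mode, a single point
payload, no hydrodynamic loading model, no photothermal transfer function
of the drive; shape effects enter only through the scalar shape factor
`F(S)` in `k_cell = E·F(S)`.

## Eigenfrequency readout

Instrument practice extracts eigenfrequencies by sweeping the drive and
fitting the amplitude with a simple-harmonic-oscillator (SHO) model
`A(f) = s/√((1−u²)² + (u/Q)²) + b`, `u = f/f0`. That is the default
(`method="sho_fit"`, optimized in log-parameters after normalizing
amplitude and frequency scales; optional constant baseline). A `peak`
method (parabolic interpolation of log-amplitude) is kept for diagnostics;
its estimate is de-biased back to `f0` through the SHO peak position
`f_peak = f0 √(1 − 1/(2Q²))` using a half-power-bandwidth Q estimate.

Simulated mass readouts sweep 2001 log-spaced points over
`[f_cant/5, 5 f_cant]`, locate the peak, then refit on a linear window of
±3 amplitude half-widths. Because the SHO fit averages `m_eff(ω)` over the
resonance linewidth, the sweep-simulated apparent mass converges to the
closed-form law only as the mass ratio `m/m_cant → 0` *and* `Q_cant → ∞`;
at `Q_cant = 100` the residual bias is below 1% wherever the readout curve
is flat across the fit window but can reach a few percent when the payload
resonance sits near the lever's. Tests assert 1% agreement in the flat
regime and at the convergent end of the allowed regime otherwise.

Exact undamped poles (drive at the cell resonance with `c_cell = 0`) raise
errors rather than returning inf/nan.

## Mass bookkeeping

Apparent mass from an eigenfrequency pair uses the rigid-payload relation
`m* = (k/4π²)(1/f_after² − 1/f_before²)`; its exact inverse is provided and
round-trips to 1e-10. Negative masses (possible under noise when
`f_after > f_before`) are reported with a flag, never clipped, so
downstream averages stay unbiased.

A payload at fractional beam position ξ (1 = free end) contributes
`φ(ξ)²` of its mass to the modal mass, with φ the first clamped-free
Euler–Bernoulli mode shape normalized to `φ(1) = 1`
(`λ₁ = 1.87510407`, `σ₁ = (cosh λ + cos λ)/(sinh λ + sin λ)`); the
corrected mass is `m*/φ(ξ)²`. This standard-beam-theory correction is a
declared stand-in for the instrument's calibrated correction and is
isolated behind `mode_shape` for easy replacement. Positions below
ξ = 0.2 (configurable) are refused — the correction there exceeds ~40× and
is dominated by position noise.

Optical-lever conversion divides photodiode volts by the sensitivity
(V/m); the typical drive level corresponds to ~0.16 nm oscillation
amplitude, which anchors the synthetic sweep scale.

## Ensemble inference

The relative readout `(f_cant, m_app/m_real)` of a cell population weighed
across a 3–110 kHz cantilever bank is fitted with the readout-accuracy law
in `(f_cell, Q_cell)`. Choices:

* **Parametrization and bounds.** Log-parameters, `f_cell ∈ [0.5, 500]` kHz,
  `Q ∈ [0.01, 100]`.
* **Weighting.** The measurement scatter is multiplicative, so the default
  is the matching lognormal maximum likelihood: least squares of
  `log(ratio)` against `log(model) − s²/2`, where the offset enforces the
  mean-one noise convention and the log-noise scale `s` is taken from a
  known noise CV when supplied or otherwise estimated from the residual
  variance by a three-step fixed-point iteration. Plain linear-space least
  squares (`weighting="unweighted"`) is retained but is *not* the default:
  under CV-0.4 multiplicative scatter its estimate is dominated by the
  large-variance low-frequency points and carries a ≈5% median bias on
  `f_cell` (measured over 200 replicates), whereas the likelihood-matched
  fit is median-unbiased (≈0.2%).
* **Multi-start.** The cost surface has a physically meaningful degenerate
  valley: the pure-dashpot limit (`k_cell → 0` at fixed `c_cell`) produces
  a Lorentzian-like readout curve `1/(1 + (f_cant Q/f_cell)²·…)` that
  mimics the true law everywhere except the low-frequency overshoot
  region. Fits restart from four canonical plus seeded random positions
  and keep the lowest cost.
* **Uncertainty.** Jacobian covariance scaled by residual variance,
  delta-method back from log-parameters; a seeded nonparametric bootstrap
  is available since the noise is strongly non-Gaussian.
* **Rigid payloads.** Data flat at ratio 1 across the bank (beads,
  tolerance 0.05 on bin means) identify only a lower bound on `f_cell`;
  the fit returns the highest probed lever frequency with a
  `rigid_limit` flag and NaN standard errors instead of a point estimate.
* **Binning.** Seven equidistant bins on the linear frequency axis
  summarize the scan (empty bins dropped with a note); fitting the
  inverse-variance-weighted bin means is available for comparison, with
  the caveat that bin means differ from the curve at bin centers wherever
  the curve is convex.

**Identifiability.** Under the default synthetic conditions (n = 178,
levers uniform on 3–110 kHz, iid multiplicative lognormal noise with
CV 0.4), the Fisher information of the fit gives a Cramér–Rao bound of
roughly 31% relative on `f_cell` and 0.09 absolute on `Q`, with a
parameter correlation of 0.997 along the dashpot valley. No estimator can
do better under these exact conditions; the implemented estimator reaches
this bound (empirical spread ≈ 0.37 relative) and is median-unbiased. Any
single seeded ensemble therefore yields a point estimate that can sit far
from the generating values even though the procedure is correct — the
reported standard errors say so honestly. Real instrument data are
expected to constrain the fit more tightly than this noise model does,
because their low-frequency readout scatters much less than a constant
multiplicative CV implies (see Generator, below).

Derived mechanics: `k_cell = 4π² m f_cell²` with the reference mean cell
mass; `E = k_cell/F(S)` only when the user supplies the FEM-derived shape
factor (the implied magnitude reconciling `k ≈ 0.026 N/m` with
`E ≈ 1.3 kPa` is `F(S) ≈ 2e-5 m`, which also sets the damping-rule
default below).

## Reference masses

Suspended rounded specimens are spheres: `mass = ρ π d³/6`, cell density
1.06 g/cm³, glass-bead density 1.8 g/cm³, diameter gate 9–24 µm (all
config keys). Histogram input uses bin centers (documented
approximation). Grouped repeat labels yield both within-population and
across-repeat summaries. Chemical crosslinking shrinks cell volume; the
reference distribution is scaled by a mass factor (default 0.8),
implemented as a `factor^(1/3)` diameter rescale at constant density.

## Synthetic-data generator

All generators are pure functions of (spec, seed) via
`numpy.random.Generator`; identical seeds give identical outputs.

* **Population defaults**: mass Normal(3.14, 0.26) ng, population-average
  cell eigenfrequency 14.4 kHz, Q 0.3. Between-cell eigenfrequency spread
  defaults to zero because the ensemble fit targets the population
  average; a spread knob exists for robustness studies.
* **Cantilever bank**: six classes spanning 3–110 kHz with spring-constant
  ranges 0.09–15.6 N/m; liquid Q defaults to 3 (a typical first-mode value
  for such levers in aqueous medium — an assumption, exposed in config).
* **Measurement noise**: multiplicative lognormal with CV 0.4 on the
  apparent mass, mean one. This is a deliberate simplification: the real
  scan's scatter is tight near ratio 1 at low lever frequencies and wide
  at high frequencies (plausibly dominated by between-cell mechanical
  variability), whereas an iid multiplicative CV spreads both ends
  equally. Consequently, passing tests demonstrate correctness of the
  chain under this noise model, not the precision the instrument reaches
  on real data; the identifiability limit above is a property of this
  noise choice.
* **Stiffening ramps**: `k_cell` linear from 0 to 0.4 N/m, damping
  `c_cell = c_min + β k_cell` with `c_min = μ_min F(S)`
  (μ_min = 2.5 mPa·s, `F(S) = 2e-5 m` → 5e-8 N·s/m) and β = 3.5e-5 s
  chosen so `Q_cell` stays ≈ 0.3 near the fitted stiffness; a constant-Q
  rule is also provided. Reading the minimal damping as a viscosity times
  the shape factor is this package's interpretation of the
  viscosity-valued damping parameter; all three constants are config
  knobs.
* **Growth profiles** are phenomenological mass/stiffness time courses (no
  adhesion biology). The collagen-like profile holds the true mass at the
  population reference and ramps `k_cell` between the values whose
  closed-form readout on the chosen lever matches apparent masses of
  0.59 ng at t = 0 and 3.04 ng at t = 120 min — i.e. the observed growth
  curve is reproduced by construction through the full sweep-fit chain.
* **Crosslinking**: stiffness ×3, mass ×0.8, damping kept (viscosity scale
  and shape factor unchanged), so the cell eigenfrequency rises by
  √(3/0.8) ≈ 1.94 and Q is recomputed.
* **Coulter samples**: truncated-normal diameters inside the gate; the
  default 17.8 µm mean is the mass-equivalent diameter of the 3.14 ng
  reference at 1.06 g/cm³, inside the 16–20 µm selection window.

## Numerical choices

SI units internally; kHz/ng/µm only at the I/O boundary. Sweep fits
normalize amplitude and frequency scales before optimizing
(scipy `least_squares`, tolerances 1e-15). Exact poles and singular
readouts raise typed errors. Strictly increasing grids are enforced at
construction. The generator's truncated draws resample rather than clip.
Problem sizes used by the test suite and acceptance script: ensembles of
n = 178 (200 replicates for the bias study), 10⁴ draws for the algebraic
identity, 50 draws for the simulation-vs-closed-form comparison, 3000
diameters per Coulter sample.

## Known limitations

* Single-mode, point-payload model: no higher cantilever modes,
  multi-compartment cells, or distributed loading.
* The position correction is generic beam theory, not an
  instrument-calibrated correction.
* The ensemble fit returns population averages; per-cell eigenfrequency
  inference is out of scope.
* The noise model is a modelling choice (see Generator); absolute
  precision claims about real instrument data cannot be read off the
  synthetic studies.
* `F(S)` must come from the user (e.g. FEM); without it no Young's modulus
  is produced.
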