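# Methods

This note documents the models behind `nirshelf`, the design of the
synthetic storage-study generator, and the numerical conventions the
implementation commits to.

## Study design being emulated

The pipeline targets a destructive longitudinal design: 72 fruits,
randomly divided into 18 groups of 4, stored at a fixed 20 °C. Every
remaining fruit is scanned daily (FT-NIR, 12,000–4,000 cm⁻¹ at 8 cm⁻¹
steps → 1001 points, 3 probe positions averaged per fruit), and each
day one whole group is removed and titrated for vitamin C by the
2,6-dichloroindophenol method, so group k accumulates exactly k daily
spectrum sets before destruction. Storage time is counted as
`t = day − 1`: the day-1 scan is the intake measurement at t = 0.
Chemistry is therefore observed *across* fruits (one titration each),
never within a fruit — which is exactly why a spectroscopic predictor
of the initial content is needed for kinetic fitting.

Titration arithmetic: `VCC = (V − V₀)·T·A/W × 100` (mg/100 g) with dye
volumes V, V₀ (mL), titer T (mg/mL), dilution multiple A and sample
weight W (g). The assay constants are not standardised anywhere
usable; the generator's defaults (T = 0.2 mg/mL, A = 10, W = 10 g,
V₀ = 0.1 mL) are conventional magnitudes for this assay and are
config-exposed. Generated titration records are obtained by inverting
the formula from the true content plus Gaussian measurement noise
(default sd 5 mg/100 g), so the assay round-trips exactly at zero
noise.

## Synthetic spectra

No public generative model exists for these spectra, so the generator
uses an explicitly stylised one:

    A(ν) = s·[ baseline(ν) + Σ_b (a₀_b + a₁_b·VCC)·G(ν; c_b, σ_b) ] + o + ε(ν)

- `baseline(ν)` is a gentle linear rise toward low wavenumber (as water
  absorption produces in practice);
- Gaussian bands sit at 10,300, 8,330, 6,900, 5,666, 5,150, 4,710 and
  4,060 cm⁻¹ — the water-combination regions plus the five effective
  wavenumbers of the long-wavelength calibration. The five bands at
  8,330, 6,900, 5,666, 5,150 and 4,060 cm⁻¹ have amplitudes affine in
  vitamin C (slopes of order 10⁻³ AU per mg/100 g, mixed signs); the
  10,300 and 4,710 cm⁻¹ bands are vitamin-C-independent. This plants a
  recoverable ground truth for wavelength selection while keeping
  uninformative structure in the spectrum.
- `s ~ 1 + N(0, 0.05)` and `o ~ N(0, 0.02)` are per-spectrum
  multiplicative/additive scatter (what MSC removes); `ε` is white
  noise, sd 0.005 AU.

Initial contents are truncated-normal, mean 350, sd 40 mg/100 g
(consistent with reported sample ranges for fresh jujube); the default
decline is zero-order at 20.677 mg/100 g/day, floored at zero because
concentrations cannot be negative (the *fitted* linear model is
deliberately not floored; see below). Late-storage decay: fruits still
in storage from day 12 can spoil; by default exactly 5 fruits (the
emulated study's observed count, making the 67-candidate 50/17 split
reproducible under any seed) are marked and their spectra from the
spoilage day onward get 8× noise, emulating the disordered late-storage
spectra of rotting fruit. A per-day Bernoulli spoilage mode
(`n_decayed=None`, hazard 0.045/day) is available.

What the generator does **not** emulate: radiative-transfer physics,
instrument drift, temperature or humidity effects, band shifts with
matrix composition, and nonlinear detector response. Passing tests
therefore demonstrate the *statistical machinery* (selection finds
planted signal, fits recover generating parameters, the pipeline keeps
calibration and prediction information separate) — not that any fixed
wavenumber set is chemically meaningful for real fruit.

## Pretreatment

- **Savitzky–Golay**: half-window 10 (21-point window), polynomial
  order 2 (the conventional default; sources rarely state it).
  Derivatives are S–G derivatives with the same window, scaled by the
  grid spacing so units are AU·cm (per cm⁻¹), with the sign corrected
  for the descending wavenumber axis. Edges are mirror-reflected so
  the output stays on the input grid (needed for fixed wavenumber
  bookkeeping); a `shrink` policy that drops edge points is available.
- **MSC**: reference = point-wise mean of the *calibration* set (the
  standard convention); prediction-set spectra are corrected against
  the stored calibration reference, never their own mean — the
  transformer's fit/transform split enforces this. MSC removes affine
  scatter exactly: `msc_apply(a + b·x, x) = x` for any `a, b ≠ 0`.

One consequence worth knowing: when the analyte signal is a large
share of total spectral variance (as in the noise-free synthetic
limit), the per-sample MSC slope `b` itself depends on the analyte, so
corrected absorbances are mildly *nonlinear* in concentration and a
small-N MLR on MSC-corrected noise-free data is near-perfect but not
exact (Rc ≈ 0.995 rather than 1). This is a property of MSC, not an
implementation artifact.

## Wavelength selection and calibration

The RC (regression coefficient) method is implemented as: centre X and
y; solve `(XᵀX + λI)β = Xᵀy` with `λ = 10⁻³·trace(XᵀX)/p` (the ridge
term only stabilises the underdetermined full-spectrum solve); find
plateau-aware local maxima of |β| over the wavenumber axis (endpoints
excluded); keep the N largest, breaking near-exact ties (10⁻¹⁰
relative) toward the lower wavenumber; report them sorted descending.
The final model is plain OLS with intercept on the selected columns —
rank-deficient designs are rejected with the dependent columns named,
which matters in the noise-free limit where all analyte-coupled
columns are exactly collinear.

Conventional selection sizes: 6 wavenumbers for raw/smoothed/MSC
spectra, 12 for first and 10 for second derivatives, 5 on the
long-wavelength (9,091–4,000 cm⁻¹) region. Region intervals are
closed on both ends; the 9,091 cm⁻¹ boundary shared by the two
half-range regions falls off the 8 cm⁻¹ grid, so in practice no point
belongs to both.

Metrics follow NIR convention: R is the Pearson correlation between
predicted and measured (not R²), RMSE uses denominator n (a flag
switches to n − p − 1). Constant predictions yield an
`undefined_correlation` flag instead of an exception. The 95 %
interval reported with a calibration is the t-based interval for the
mean of the fitted values; per-sample prediction intervals are out of
scope.

## Kinetics

Zero-order fitting is OLS of VCC on (1, VCC₀, t), reporting
`K = −(t coefficient)` with its standard error and 95 % t-interval;
the textbook two-parameter form (a = 0, b = 1) is the `fixed_vcc0`
special case. First-order fitting is nonlinear least squares of
`C₀·e^(−Kt)`, initialised from a log-linear regression on the positive
observations only — log-linearisation is biased under additive noise,
so it never serves as the estimator itself. Model comparison reports
R and RMSEC for both forms on the same observations; the larger R
wins, with exact ties resolved to the simpler zero-order form.

`predict_kinetic` deliberately does **not** floor the zero-order
prediction at zero: the shelf-life arithmetic inverts the linear model
through its zero crossing, and flooring would destroy the inverse.

Simulation checks (run by the test suite): with n = 200 observations
per replicate and noise sd 5 mg/100 g, the OLS rate estimator is
unbiased to within 1 % over 200 replicates and its 95 % interval
covers the generating rate at close to nominal frequency; under the
default generator the estimate is mildly attenuated (~4 %) because
late-storage observations sit on the concentration floor — a real
feature of degradation data near exhaustion.

## Shelf life

Two inversion readings are exposed behind a `method` flag:

- `algebraic` (default): `t = (a + b·VCC₀ − VCC)/K`, the exact inverse
  of the fitted zero-order model (round-trips with `predict_kinetic`
  to 10⁻¹⁰);
- `as_printed`: the published inversion
  `t = 17.128 − 0.002·VCC₀ − 0.046·VCC`, kept verbatim because it is
  *not* the algebraic inverse of the published zero-order model (the
  intercept and the sign of the VCC₀ term disagree — at
  VCC₀ = VCC = 0 it gives 17.128 days where the algebraic inverse of
  the published model gives 338.787/20.677 ≈ 16.385). The discrepancy
  is asserted in the tests and recorded in prediction metadata.

Safe storage time uses threshold 0 mg/100 g by default — a modelling
convention (vitamin C "about zero"), not a safety standard, hence
config-exposed. Negative storage-time estimates (day-t spectrum
implying more vitamin C than day 0) are returned with a
`negative_time` flag rather than clamped.

## Problem sizes

The default synthetic study (72 fruits → 684 fruit-days → 2,052
spectra of 1,001 points) runs the full pipeline in a few seconds;
parameter-recovery simulations use 200 observations × 200 replicates.
These sizes give standard errors small enough that the recovery
assertions (3 SE, 1 % bias, CI coverage within [0.90, 0.99]) are
meaningful without being fragile.

## Known limitations

- The generator's band parameterisation is stylised; selection
  recovery results do not transfer to claims about real jujube spectra.
- MLR on RC-selected wavenumbers is kept deliberately simple (no PLS,
  PCR, interval selection or cross-validation — single hold-out split
  by design).
- Kinetics assume a fixed 20 °C; no Arrhenius temperature dependence.
- The zero-order fit treats spectroscopically predicted VCC₀ as a
  fixed regressor; its measurement error is not propagated into the
  kinetic parameter uncertainties.
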