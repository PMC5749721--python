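# Methods

This note documents the models behind `flimpair`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical choices a user should know before trusting a number.

## Spectral prediction

The prediction chain is the textbook one: the donor emission spectrum is
area-normalised (trapezoidal rule), combined with the acceptor
excitation spectrum scaled to its peak molar extinction coefficient into
the overlap integral J = ∫ f_D(λ) ε_A(λ) λ⁴ dλ (nm⁴ M⁻¹ cm⁻¹, 1 nm
default resampling grid, linear interpolation, zero outside either
support), and converted to the Förster radius

    r0 = 0.02108 · (K · φ_D · n⁻⁴ · J)^(1/6)   [nm]

with n = 1.4 for cellular cytoplasm. Efficiency at separation r is
E = r0⁶/(r0⁶ + r⁶).

**The orientation-term convention.** For freely rotating dipoles the
orientation factor is κ² = 2/3, and `standard_two_thirds` sets K = 2/3.
The published benchmark radii this package reproduces, however, are only
recovered when the term inside the sixth root equals (2/3)² = 4/9 — a
discrepancy of exactly (3/2)^(1/6) ≈ 1.07 in r0, or about 0.35 nm at
these radii. The source of the discrepancy in the benchmark table is not
documented, so no intent is guessed: both conventions are implemented,
and `table2_compat` (K = 4/9) is the default because it reproduces every
published radius to ±0.01 nm. Anyone computing radii for new pairs
against literature values should check which convention their reference
uses.

Predictions from spectra use parametric Gaussian stand-ins (the exact
spectral datasets behind the published J values are external); J values
for the benchmark pairs are therefore taken from the packaged published
table rather than recomputed, and the Gaussian route is validated against
closed-form Gaussian-product integrals instead.

## Frequency-domain model

Homodyne detection at modulation frequency f (default 40 MHz, ω = 2πf)
maps a decay with intensity fractions a_i and lifetimes τ_i to

    g = Σ a_i/(1+(ωτ_i)²),  s = Σ a_i ωτ_i/(1+(ωτ_i)²),
    φ = atan2(s, g),        m = √(g²+s²),

the exact normalised Fourier transform of the decay at ω (verified
against adaptive quadrature in the tests). Phase and modulation each
invert to a lifetime; they agree for mono-exponential decays and
τ_φ < τ_m strictly for mixtures. The reported single-number lifetime is
the **phase lifetime** — the more common FD readout — with the
modulation lifetime and phasor coordinates always available; the choice
is configurable because instrument software conventions differ.

Calibration transfers the known phase/modulation of a reference
fluorophore (fluorescein, τ = 4.000 ns, or erythrosin B, τ = 0.086 ns)
to remove the instrument's common phase offset and gain; the
implementation is exactly invariant to such offsets (tested).

**Noise model.** No noise model is published for the benchmark FD data,
so the simulator uses the simplest one that supports parameter-recovery
testing: independent Gaussian perturbations of φ and m, each with
σ = 1/√N for photon budget N (default 10⁶, i.e. σ = 10⁻³). This ignores
the φ–m correlation and detector-specific excess noise of real
intensifiers; recovered-parameter standard errors are therefore
illustrative, not instrument predictions.

## Time-domain model

TCSPC histograms use 80 ps bins over a 12.5 ns window (80 MHz
Ti:Sapphire repetition convention; the benchmark instrument's window is
unpublished). Expected bin contents are exact per-bin integrals of the
multi-exponential decay, scaled to the requested photon total, with
Poisson sampling. Incomplete-decay wrap-around and an instrument
response function are **not** modelled: excitation is a delta function.
A warning is raised when the window is shorter than 3× the longest
lifetime, where truncation bias becomes material.

Mono-exponential fits maximise the Poisson likelihood of A·e^(−t/τ)
(analytic gradient, L-BFGS-B, log-linear-regression initialisation) —
exact for counting statistics and unbiased in the tested photon range
(10⁴–10⁶). A flat background term is available but off by default:
fitting a boundary-constrained background to background-free data
biases τ̂ low by ~0.5 % at 10⁵ photons. Bi-exponential fits minimise
Neyman-weighted least squares (weights max(c,1), via lmfit) with the two
amplitudes deliberately unconstrained in sign, so that forcing a second
component onto mono-exponential data surfaces as a negative amplitude
(`physical = False`) instead of being hidden by a bound. Model selection
accepts the two-component fit only when it is physical *and* lowers the
Neyman reduced χ² by more than 0.05 (default); on simulated
mono-exponential data this rejects the second component in ≥95 % of
runs, while a genuine 1 ns/4 ns mixture at 10⁶ photons is always
detected. Both fits report the Neyman reduced χ² for comparability;
equal-lifetime truths are an identifiability limit and collapse to the
mono model.

## Assay evaluation

FRET efficiency is E = 1 − τ_DA/τ_D against the **day-matched**
donor-alone mean; small negative efficiencies are retained (flagged, not
clipped) so distributions stay honest. The Z′-factor uses per-day means
and n−1 standard deviations over cells, one day = one repeat, summarised
as mean ± SD across days. Static mode uses t = 0 only; dynamic mode
pools every timepoint of every cell within the day before computing
μ/σ, so temporal drift honestly degrades the dynamic Z′ (per-cell
averaging first is available as an option via pre-aggregation).
Stimulation responses compare pre- vs post-stimulus per-cell lifetime
changes with a two-sided Wilcoxon rank-sum test, starred at
0.05/0.01/0.005. Donor sensitivity is reported analytically as
10·τ_D ps per %E (Δτ = τ_D·ΔE) with an empirical through-origin
Δτ/ΔE estimator alongside.

## Time-course summaries

Traces are normalised to the across-cell mean of the t = 0 values of
their experimental day (idempotent; days without a baseline are dropped
with a warning). Drift is the OLS slope of the mean normalised trace
(≥3 timepoints). Endpoint-change percentiles use linear interpolation
between closest ranks, fixed so the sort-based oracle test is exact.
The predicted-vs-measured regression is through the origin,
b = Σxy/Σx², with R² = 1 − Σ(y−bx)²/Σy² (the no-intercept definition —
conventions differ and none is documented for the benchmark) and a
t-based 95 % CI from SE(b) = √(Σ(y−bx)²/(n−1)/Σx²). Outlier exclusion
(the mRuby2 pairs) is always an explicit argument, never automatic.

## Synthetic generator

Defaults reproduce the benchmark design: 3 days × 3 dishes × 15 cells
per dish (the studies used 10–20), donor lifetimes drawn per cell from
Normal(τ_D, σ_cell) with σ defaults taken from the published day-level
errors (e.g. Clover 3.12 ± 0.05 ns FD), pair-cell efficiencies from
Normal(E, 0.02), intensities lognormal (σ = 0.4) around 1000 a.u.
Measured lifetimes are produced by the actual estimation code paths
(FD: simulate → offset/gain → calibrate → phase lifetime; TD: Poisson
histogram → Poisson MLE fit); `noise_mode="gaussian"` is a fast shortcut
for large sweeps. Time courses add exponential intensity bleaching and a
fractional per-minute upward drift of the pair lifetime (acceptor
photodamage → less transfer); drift/bleach rates and the
maturation-failure mixture fraction for heterogeneous acceptors
(two-component E distribution, default fraction 0.5 when enabled) are
**illustrative** — the benchmark does not quantify them. Everything is
deterministic given the seed (NumPy PCG64).

What the generator does *not* emulate: spatial/image structure and
segmentation error, pH and organelle effects on lifetimes, acceptor
dark-state photophysics, detector-specific noise, day-level systematic
shifts beyond sampling noise. Passing recovery tests therefore show the
*estimators* are unbiased under the assumed noise, not that real-cell
data will match.

## Problem sizes and tolerances

Acceptance-style recoveries use 250 cells (donor-lifetime) and a
3×3×15-cell study (efficiency) at 10⁶ photons per measurement; Monte
Carlo consistency tests use 30–200 replicates — sizes at which the
standard errors are a few ×10⁻³ ns / a few tenths of a %E, comfortably
resolving the published precision. Recovery assertions use 3-standard-
error bands; exact algebraic identities are asserted at 10⁻⁹–10⁻¹²;
the phasor semicircle at 10⁻¹².

## Known limitations

- The (2/3)² orientation-term convention is a reproduction device, not a
  physical claim; κ² distributions (restricted dye rotation) are out of
  scope.
- FD noise is an uncorrelated Gaussian approximation; TD fitting ignores
  IRF and wrap-around.
- The bi-exponential least-squares objective is mildly biased at very low
  counts (Neyman weighting); use ≥10⁵ photons for quantitative two-
  component work.
- Published dynamic-mode Z′ values depend on unpublished per-day raw
  data and are represented only qualitatively (drift lowers dynamic Z′).
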