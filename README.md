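# flimpair

Benchmarking fluorescent-protein donor–acceptor pairs for FLIM-FRET.

FRET biosensors report signalling activity through a conformational change
that alters the energy transfer between two fluorescent proteins, and
fluorescence lifetime imaging (FLIM) is the most quantitative way to read
that transfer out: only the donor lifetime is measured, so the readout is
independent of expression level, light scattering and acceptor emission.
Choosing the *right* pair, however, involves more than spectra. `flimpair`
implements the full evaluation chain for candidate pairs, for people
designing lifetime-based biosensor assays:

- **Spectral prediction** — overlap integral
  J = ∫ f_D(λ) ε_A(λ) λ⁴ dλ, Förster radius
  r₀ = 0.02108 (K φ_D n⁻⁴ J)^{1/6}, and efficiency
  E = r₀⁶/(r₀⁶ + r⁶) at any separation r.
- **Frequency-domain FLIM** — the homodyne forward model
  (φ = arctan ωτ, m = 1/√(1+(ωτ)²) for a mono-exponential decay),
  reference calibration against fluorophores of known lifetime, phase and
  modulation lifetime estimators, and phasor coordinates
  (g, s) = (m cos φ, m sin φ).
- **Time-domain FLIM** — TCSPC histogram simulation (80 ps bins), Poisson
  maximum-likelihood mono-exponential fits, sign-unconstrained
  bi-exponential fits, and physicality-based model selection.
- **Assay scoring** — FRET efficiency E = 1 − τ_DA/τ_D, the Z′-factor
  Z′ = 1 − 3(σ_max + σ_min)/|μ_max − μ_min| evaluated per experimental
  day, statically (t = 0) or dynamically (whole time courses), plus
  cross-platform concordance and the ps-per-%E sensitivity rule.
- **Time-course stability** — trace normalisation, drift slopes,
  endpoint-change percentile summaries, variability correlations, and
  through-origin predicted-vs-measured regressions.
- **Synthetic studies** — a deterministic generator reproducing the
  multi-day, multi-dish cell-study design (10–20 cells per dish, 3 days),
  routing true lifetimes through the actual FD/TD estimation code so that
  estimator biases are exercised end to end.

The package ships the published photophysical constants of nine benchmark
fluorescent proteins (donors mTFP1, mTq2, EGFP, Clover; acceptors YPet,
Venus, sREACh, mCherry, mRuby2), the (QY, J, r₀) table of their ten
donor–acceptor pairings, and the published static/dynamic Z′/E summaries
on both FLIM platforms.

## Worked example

```python
from flimpair import (SyntheticStudyConfig, generate_study, evaluate_assay,
                      forster_radius, efficiency_at_distance)

# spectral prediction for Clover-mCherry (QY 0.76, J = 2.50e15 nm4/(M cm))
r0 = forster_radius(0.76, 2.50e15, "table2_compat")
print(f"r0 = {r0:.2f} nm, E(6 nm) = {100*efficiency_at_distance(r0, 6.0):.0f}%")

# a synthetic 3-day frequency-domain study of the same pair
cfg = SyntheticStudyConfig(pair_name="Clv-mCh", tau_donor_true=3.12,
                           tau_donor_cell_sd=0.05, E_true=0.241,
                           E_cell_sd=0.02, rng_seed=7)
cells = generate_study(cfg)
ev = evaluate_assay(cells[cells.construct == "Clv"],
                    cells[cells.construct == "Clv-mCh"], mode="static")
print(f"E = {100*ev.E_mean:.1f} ± {100*ev.E_sd:.1f} %, "
      f"Z' = {ev.Zprime_mean:.3f} ± {ev.Zprime_sd:.3f}")
```

prints

```
r0 = 5.18 nm, E(6 nm) = 29%
E = 24.0 ± 0.3 %, Z' = 0.529 ± 0.041
```

The predicted radius says half the donor excitations would transfer at
5.18 nm separation, falling to 29 % at the ~6 nm separation typical of a
protein fusion.  The evaluation recovers the generating efficiency
(24.1 %) through the complete simulated measurement chain — homodyne
response, shot noise, fluorescein-reference calibration, phase-lifetime
estimation, day-matched efficiency and Z′ — and the Z′ above 0.5 marks a
usable assay window.

More narrative walk-throughs live in `examples/` (one script per
capability); `flimpair --help` exposes the same stages as a small CLI
(`predict`, `simulate`, `fit-fd`, `fit-td`, `evaluate`, `timecourse`).

## Layout

```
src/flimpair/
  spectra.py     overlap integral, Förster radius, E(r)
  fd.py          homodyne frequency-domain model + estimators
  td.py          TCSPC simulation + decay fitting
  metrics.py     FRET efficiency, Z'-factor, assay evaluation
  timecourse.py  stability and concordance analyses
  synthetic.py   deterministic study generator
  io.py          readers/writers + packaged reference tables
  cli.py         thin command-line interface
docs/methods.md  model assumptions, defaults and limitations
examples/        one narrative script per capability
```
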