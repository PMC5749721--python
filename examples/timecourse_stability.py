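"""Quantify photostability: drift slopes and endpoint-change distributions.

Generates a 10-minute time course with intensity bleaching but a stable
lifetime, normalises every cell's trace to its day's t = 0 mean, and
summarises drift and endpoint change for both quantities — reproducing the
qualitative finding that lifetime readouts are far more stable than
intensity readouts under identical illumination.
"""

from flimpair.synthetic import SyntheticStudyConfig, generate_timecourse
from flimpair.timecourse import (
    drift_slope,
    endpoint_change_summary,
    normalize_traces,
    percent_sd,
    variability_correlation,
)

cfg = SyntheticStudyConfig(
    pair_name="Clv-mCh",
    tau_donor_true=3.12,
    intensity_bleach_rate_per_min=0.04,  # 4 %/min photobleaching
    noise_mode="gaussian",
    rng_seed=5,
)
tc = generate_timecourse(cfg)
donor = tc[tc.construct == "Clv"]

for quantity, column in (("intensity", "intensity"), ("lifetime", "lifetime_ns")):
    traces = normalize_traces(donor, value_column=column)
    slope, se = drift_slope(traces)
    summary = endpoint_change_summary(traces, construct="Clv", quantity=quantity)
    print(f"{quantity:>9}: drift = {slope:+.4f} ± {se:.4f} per min, "
          f"t10-t0 change mean = {summary.endpoint_mean:+.3f}, "
          f"IQR = [{summary.endpoint_percentiles[25]:+.3f}, "
          f"{summary.endpoint_percentiles[75]:+.3f}]")

print("\nIntensity falls ~4 %/min while the lifetime trace stays flat:"
      "\nlifetime is the robust readout under photobleaching.")

# does lifetime variability track expression-level (intensity) variability?
sd_tau, sd_int = [], []
for cell_sd, seed in ((0.02, 1), (0.05, 2), (0.08, 3), (0.03, 4), (0.06, 5)):
    c = SyntheticStudyConfig(
        tau_donor_cell_sd=cell_sd, days=1, dishes_per_day=1,
        cells_per_dish=20, noise_mode="gaussian", rng_seed=seed,
    )
    study = generate_timecourse(c)
    d = study[(study.construct == "Clv") & (study.timepoint_min == 0)]
    sd_tau.append(percent_sd(d["lifetime_ns"]))
    sd_int.append(percent_sd(d["intensity"]))
rho, p = variability_correlation(sd_tau, sd_int)
print(f"\nSpearman rho(%SD lifetime, %SD intensity) = {rho:+.2f}, p = {p:.2f}")
print("(lifetime spread is set independently of expression spread, so no"
      "\n significant correlation is expected - or found)")
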