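"""Score a FRET pair's assay potential with the Z'-factor.

Generates a 3-day synthetic Clover / Clover-mCherry study through the
frequency-domain measurement pipeline and evaluates it statically (t = 0)
and dynamically (pooling a 10-minute time course), including the effect of
acceptor photodamage drift.
"""

from flimpair.metrics import evaluate_assay, sensitivity_ps_per_percent
from flimpair.synthetic import SyntheticStudyConfig, generate_study, generate_timecourse

cfg = SyntheticStudyConfig(
    pair_name="Clv-mCh",
    platform="FD",
    tau_donor_true=3.12,   # ns, Clover donor
    tau_donor_cell_sd=0.05,
    E_true=0.241,          # generating FRET efficiency
    E_cell_sd=0.02,
    rng_seed=7,
)
cells = generate_study(cfg)
donor = cells[cells.construct == "Clv"]
pair = cells[cells.construct == "Clv-mCh"]
ev = evaluate_assay(donor, pair, mode="static")
print(f"{ev.pair} [{ev.platform}, static]: "
      f"E = {100 * ev.E_mean:.1f} ± {100 * ev.E_sd:.1f} %, "
      f"Z' = {ev.Zprime_mean:.3f} ± {ev.Zprime_sd:.3f} over {ev.n_days} days")
print("(the recovered E matches the generating 24.1 %; Z' > 0.5 marks a"
      "\n usable assay window between donor-alone and pair lifetimes)")

# an unstable acceptor: lifetime drifts up 1 %/min as the acceptor bleaches
drifting = SyntheticStudyConfig(
    pair_name="mTq2-YPet",
    tau_donor_true=4.04,
    tau_donor_cell_sd=0.08,
    E_true=0.33,
    lifetime_drift_per_min=0.01,
    noise_mode="gaussian",
    rng_seed=11,
)
tc = generate_timecourse(drifting)
d, p = tc[tc.construct == "mTq2"], tc[tc.construct == "mTq2-YPet"]
static = evaluate_assay(d, p, mode="static")
dynamic = evaluate_assay(d, p, mode="dynamic")
print(f"\nmTq2-YPet with acceptor drift: static Z' = {static.Zprime_mean:.3f}, "
      f"dynamic Z' = {dynamic.Zprime_mean:.3f}")
print("(pooling the drifting time course inflates sigma, so the dynamic Z'"
      "\n drops - exactly why photostable acceptors matter for kinetic assays)")

print(f"\nsensitivity: a 4.0 ns donor shifts {sensitivity_ps_per_percent(4.0):.0f} ps "
      f"per %E vs {sensitivity_ps_per_percent(2.4):.0f} ps for a 2.4 ns donor")
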