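"""Surfactant-displacement kinetics: fit time constants, label affinity.

Simulates fluorescence peak-shift traces (1129 -> 1115 nm) for a weak
binder, a strong binder and a censored (no-shift) construct, fits the
first-order displacement time constant for each and applies the 90-s
high/low affinity rule.
"""

from cntbind import kinetics, synthetic

cases = {
    "weak binder  (tau  30 s)": 30.0,
    "strong binder(tau 342 s)": 341.6,
    "no shift     (censored) ": None,
}

print("fitted displacement time constants (20-s sampling, SC at 100 s):")
for name, tau in cases.items():
    trace = synthetic.simulate_kinetic_trace(tau, noise_sd_nm=0.3, seed=7)
    res = kinetics.fit_time_constant(trace)
    label = kinetics.label_affinity(res)
    tau_str = "INF" if res.censored else f"{res.tau_s:7.1f} s"
    print(f"  {name}: tau = {tau_str:>9}  ->  {label.label}-affinity")

print()
print(
    "A longer time constant means the surfactant needs longer to displace\n"
    "the DNA, i.e. stronger binding; INF (no measurable shift within the\n"
    "window) marks the strongest binders and is labelled high-affinity."
)

# the nuclease cut ratio compares band intensities after DNase digestion
cr = kinetics.cut_ratio(I_a=4.0, I_c=1.0)
print(f"\ncut ratio for intact:cleaved band intensities 4:1 -> CR = {cr:.2f}")
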