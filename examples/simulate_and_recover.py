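"""Synthetic replication pairs and parameter recovery.

Simulates compatible study pairs (equal true effects, Labels-scale SEs),
reanalyzes each with the uniform-alpha power prior, and summarizes bias and
95% HPD coverage for the effect size.
"""

from powerep import SimulationSpec, parameter_recovery_report, recovery_summary

spec = SimulationSpec(
    truth="fixed", theta_o=0.21, theta_r=0.21, se_o=0.05, se_r=0.05,
    n_sims=200, seed=42,
)
summary = recovery_summary(parameter_recovery_report(spec, grid_size=401))

print(f"simulations        : {summary['n_sims']}")
print(f"theta bias         : {summary['theta_bias']:+.4f}")
print(f"95% HPD coverage   : {summary['coverage']:.3f}")
print(f"mean E[alpha|data] : {summary['alpha_mean_avg']:.3f}")
print()
print("Coverage sits slightly above 0.95: mixing over alpha widens the")
print("interval relative to the exactly calibrated fixed-alpha=1 analysis.")
print("The alpha posterior mean near 0.54 (vs prior mean 0.5) shows how")
print("little two compatible studies can say about the power parameter.")
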