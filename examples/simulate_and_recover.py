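"""Simulate a two-burst genome and recover the burst ages end to end.

Two amplification bursts (0.61 and 2.0 Ma) each deposit 1,000 decayed,
fragmented copies of a 5-kb master element.  The pipeline bins the
fragment-weighted dots, separates the two peaks, fits each with a Gaussian
and reports both clocks: the width clock K = 2.58*sigma and the
mean-divergence clock K = (100 - mu)/100.
"""

from ltrburst import SimConfig, recovery_report, simulate

config = SimConfig(bursts=((0.61e6, 1000), (2.0e6, 1000)), seed=42)
dataset = simulate(config)
print(f"simulated {len(dataset.hits)} hits from {len(dataset.truth)} bursts")

report = recovery_report(dataset)
cols = ["true_age_yr", "mu", "sigma_pct", "t_sigma_yr", "t_mean_yr", "rel_err_mean"]
print(report[cols].to_string(float_format=lambda v: f"{v:,.4g}"))
print()
print("Each row pairs a true burst age with the peak that recovered it")
print("(youngest first).  t_mean_yr tracks the true age closely because the")
print("peak mean records accumulated divergence; t_sigma_yr is the width")
print("clock used for real genomes, where the peak width reflects the")
print("burst's divergence spread.")
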