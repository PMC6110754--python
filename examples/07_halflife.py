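"""Protein half-life estimation from cycloheximide chase densitometry.

Simulates three constructs with true half-lives 15/22/58 minutes (3
replicates, 10% multiplicative noise), fits each replicate by log-linear
OLS, and compares mutants against wild type with a Welch t-test.
"""

import nrf2atlas as na

cfg = na.SimulationConfig(seed=11, chase_spec=na.ChaseSpec(
    {"WT": 15.0, "R34L": 22.0, "E82G": 58.0},
    timepoints=(0, 30, 60, 90, 120), noise_sd=0.1, replicates=3))
chase = na.simulate_chase(cfg)
fits = na.fit_chase_table(chase)
summary = fits.groupby("construct")["t_half"].agg(["mean", "std"])
print(summary.round(1).to_string())

wt = fits.loc[fits["construct"] == "WT", "t_half"]
for construct in ("R34L", "E82G"):
    mut = fits.loc[fits["construct"] == construct, "t_half"]
    out = na.compare_halflives(mut, wt)
    print(f"{construct} vs WT: {out['mean_a']:.1f}±{out['sd_a']:.1f} vs "
          f"{out['mean_b']:.1f}±{out['sd_b']:.1f} min, p = {out['p_value']:.3g}")
# t_half = ln(2)/lambda from the fitted decay rate; p < 0.05 marks a mutant
# whose stabilization is resolvable at 3 replicates and this noise level.
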