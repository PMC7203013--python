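"""Fit one amplification peak and convert its width to a burst age.

Builds a histogram from a Gaussian peak centred at 88.25% identity with
width 0.24147 percentage points — the profile of the burst shared by both
diploid cotton A-genomes — fits it, and applies the clock K = 2.58*sigma,
t = K/r with the cotton substitution rate r = 7e-9 per site per year.
"""

import numpy as np

from ltrburst import burst_time, fit_gpdf
from ltrburst.dots import IdentityDistribution

edges = 86.5 + 0.1 * np.arange(36)
mids = 0.5 * (edges[:-1] + edges[1:])
counts = 1000.0 * np.exp(-0.5 * ((mids - 88.25) / 0.24147) ** 2)
dist = IdentityDistribution(bin_edges=edges, counts=counts)

peak = fit_gpdf(dist, (86.5, 90.0))
est = burst_time(peak, r=7e-9)

print(f"fitted peak:  mu = {peak.mu:.3f}%  sigma = {peak.sigma_pct:.5f} pct points")
print(f"goodness:     adjusted R^2 = {peak.adj_r2:.6f}")
print(f"clock:        K = 2.58*sigma = {est.K:.6f} substitutions/site")
print(f"burst age:    t = K/r = {est.t_ma:.3f} Ma")
print()
print("A peak width of ~0.24 percentage points at r = 7e-9 dates the")
print("amplification burst to ~0.89 Ma, before the A1/A2 speciation.")
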