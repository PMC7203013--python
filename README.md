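# ltrburst

Dating LTR-retrotransposon amplification bursts from fragment-weighted
identity distributions.

LTR retrotransposons dominate plant genomes — nearly three quarters of the
cotton A-genomes are LTR sequence — and their amplification history drives
genome expansion and can bracket speciation and polyploidy events. Classical
insertion-time estimates need both LTRs of a full-length element, which
over-represents recent insertions because old copies decay into fragments.
`ltrburst` instead dates bursts from *all* aligned TE material: every hit of
a genomic fragment against a family's representative element contributes
dots proportional to its length, the resulting identity distribution shows
one peak per amplification burst, and each peak's fitted Gaussian width is
converted to an age with a molecular clock.

## The method

Given hits with alignment length *l* and percent identity:

1. **Dot weighting.** Each hit contributes *n* = *l*/30 dots (one per 30-bp
   unit, floored, minimum one) at its identity, so fragmented old copies are
   weighted by their sequence content, not their copy count.
2. **Peak separation and GPDF fitting.** The dots are binned (0.1%
   identity bins by default), single peaks are separated at the valleys of
   the smoothed curve, and each is fitted by least squares with a Gaussian
   probability density function *A*·exp(−(*x*−*μ*)²/2*σ*²). Fit quality is
   screened by adjusted R² (accept ≥ 0.95 by default; failures are flagged,
   not dropped).
3. **Clock calibration.** The average nucleotide substitution ratio of a
   peak is *K* = 2.58 *σ* (σ converted from percentage points to a per-site
   fraction), and the burst age is *t* = *K*/*r* with
   *r* = 7 × 10⁻⁹ substitutions per site per year for cotton.

Companion modules classify intact elements into families (5′-LTR greedy
centroid clustering at identity ≥ 80%, coverage ≥ 80%, copy number ≥ 100),
date single intact elements from their 5′/3′-LTR divergence
(*t* = *d*/2*r*), simulate multi-burst hit tables with known ages under
JC69 for validation, and count synonymous "identical sites" in ortholog CDS
alignments.

## Worked example

```python
import numpy as np
from ltrburst import fit_gpdf, burst_time
from ltrburst.dots import IdentityDistribution

edges = 86.5 + 0.1 * np.arange(36)
mids = 0.5 * (edges[:-1] + edges[1:])
counts = 1000.0 * np.exp(-0.5 * ((mids - 88.25) / 0.24147) ** 2)
dist = IdentityDistribution(bin_edges=edges, counts=counts)

peak = fit_gpdf(dist, (86.5, 90.0))
est = burst_time(peak, r=7e-9)
print(f"mu = {peak.mu:.3f}%  sigma = {peak.sigma_pct:.5f}  t = {est.t_ma:.3f} Ma")
```

prints

```
mu = 88.250%  sigma = 0.24147  t = 0.890 Ma
```

A peak of width 0.24 percentage points centred at 88.25% identity dates its
burst to 0.89 Ma: K = 2.58 × 0.0024147 ≈ 0.0062 substitutions per site,
divided by r = 7 × 10⁻⁹ per year. The `examples/` directory holds more
narrative scripts: end-to-end simulation and recovery of a two-burst
genome, family classification with representative selection, and
identical-site counting.

The same pipeline runs from the shell:

```sh
ltrburst simulate --ages 0.61e6,2.0e6 --copies 2000,2000 --seed 42 --out hits.tsv
ltrburst profile --hits hits.tsv --out dist.tsv
ltrburst fit --dist dist.tsv --out peaks.json
```

`peaks.json` then carries one entry per detected burst with μ, σ, adjusted
R², K, t and r; peaks at ≥ 96% identity are flagged too recent to date
reliably.

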