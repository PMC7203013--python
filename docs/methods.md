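# Methods

## Model and procedure

`ltrburst` dates LTR-retrotransposon amplification bursts from the percent
identities of TE hits — alignments of genomic fragments against a family's
representative element. The underlying model: a burst deposits many copies
of a master element in a short interval; each copy then accumulates
substitutions neutrally, so the copies' identities to the representative
form a peak whose position reflects the burst's age and whose spread
reflects the divergence accumulated plus sampling effects. The pipeline is

1. dot weighting: a hit of length *l* yields max(1, ⌊*l*/30⌋) dots at its
   identity;
2. binning dots into a uniform identity histogram;
3. separating single peaks at the valleys of the smoothed histogram;
4. fitting each peak with a Gaussian *A*·exp(−(*x*−*μ*)²/2*σ*²) by
   unweighted least squares on bin midpoints;
5. calibrating each peak to an age by *K* = 2.58 *σ* (per-site fraction) and
   *t* = *K*/*r*.

The weighting step is the method's point: full-length-only dating
over-represents young elements because old copies survive mostly as
fragments. Weighting by 30-bp units makes a decayed 4-kb element count the
same as an intact one of equal aligned content.

### Assumptions

- Substitutions accumulate clock-like at rate *r* (default 7 × 10⁻⁹
  per site per year, the cotton rate; set `--r` for other lineages).
- One burst produces one approximately Gaussian peak; overlapping bursts
  closer than their combined widths are not separable by valley splitting.
- Identity is taken as given by the aligner (RepeatMasker "perc div."
  complement or BLAST pident); no multiple-hit correction is applied to the
  identity axis.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `unit` | 30 | bp | dot size; divides hit length into dots |
| `bin_width` | 0.1 | % identity | histogram resolution; resolves the narrowest real peaks (σ ≈ 0.17 pct) |
| `min_prominence` | 0.05 | fraction of global max | peak acceptance in detection |
| `smooth_window` | 5 | bins | moving-average width before peak finding |
| `min_adj_r2` | 0.95 | — | Gaussian fit acceptance; failures flagged `rejected` |
| `r` | 7e-9 | subs/site/yr | molecular clock rate |
| `lineage_factor` | 2 | — | intact-pair dating *t* = *d*/(factor·*r*) |
| `recent_identity` | 96.0 | % | peaks at or above are flagged `too_recent` |

The *l*/30 rounding is not uniquely determined by the construction; the
package floors with a minimum of one dot so sub-30-bp hits still register
(`--dot-rounding round` switches to round-half-up). The 0.95 adjusted-R²
acceptance operationalises "high" fit quality and is configurable; rejected
peaks are reported with their statistic rather than dropped.

## The two clocks

The canonical clock takes *K* = 2.58 *σ* — the peak width, not its mean,
parameterises the substitution ratio. The package also provides a
`mode="mean"` clock, *K* = (100 − *μ*)/100, which reads the peak's mean
divergence directly. The two generally disagree: width responds to burst
duration, rate heterogeneity and fragment-length sampling noise, while the
mean tracks accumulated divergence. On real data the width clock is the
supported convention; the mean clock exists because on simulated data it is
the one with a ground-truth relationship (mean divergence =
JC69(age · r)), making it the right tool for validating the pipeline
end to end. Reports from the simulator carry both.

Identity ranges for display are reported as μ ± 1.96σ; this is a
presentation convention only.

## Family classification and intact-pair dating

5′-LTR sequences are clustered greedily: sorted by length descending (id
ascending on ties), each sequence joins the first centroid at identity
≥ 80% and coverage ≥ 80%, else founds a cluster. Identity is matched
columns over the aligned span of a global alignment (match 1, mismatch −1,
gap −2); coverage is the aligned span over the longer sequence. Greedy
centroid clustering was chosen over all-vs-all graph clustering for
determinism and desk-scale speed; the sorting rule makes the result
independent of input order. Clusters under 100 copies are reported
separately as below-threshold. A family's representative is its *most
recent* member, operationalised as minimal 5′/3′-LTR divergence (the two
LTRs are identical at insertion), ties broken lexicographically.

Intact elements are dated by *t* = *d*/(2*r*): both LTRs drift after
insertion, so their mutual divergence accrues at 2*r*. This is a different
convention from the fragment clock *t* = *K*/*r*, where divergence is
measured against a fixed reference; both are exposed and the factor is a
parameter.

## Identical-site statistic

For a codon-anchored pairwise CDS alignment, gap-free columns with
differing bases are SNP sites; a SNP site is an *identical site* when its
containing codons translate to the same amino acid in both sequences
(synonymous). Codons containing ambiguity codes are excluded from all
counts and tallied, which avoids fabricating calls. When one codon holds
two SNPs, both columns share the whole-codon synonymous status by default;
`snp_codon_mode="single"` re-evaluates each column in isolation. Gap runs
must be codon-length multiples; a frame shift raises an error naming the
first offending codon.

## The synthetic-data generator

`ltrburst.sim` emulates the observable the pipeline consumes. Per burst of
age *t*, each copy of a fixed master receives substitutions at independent
sites with probability *p* = (3/4)(1 − e^(−(4/3)·r·t)) (JC69, one diverging
lineage against the fixed master, matching the one-reference clock; a
both-lineages mode doubles the branch). Copies are fragmented into
geometric-length pieces (memoryless decay, 30-bp floor), and each fragment
becomes a hit with identity 100·(1 − its mismatch fraction), optional
Gaussian percent-scale noise, clipped to [0, 100]. Everything is
reproducible from one seed.

**Fragment-length default (1000 bp).** A fragment of length *L* sampled
from a copy with divergence *p* has binomial identity spread
≈ 100·√(p(1−p)/L) percentage points. Evaluating the exact dot-weighted
mixture density analytically shows that with 300-bp mean fragments a
0.61-Ma and a 2.0-Ma burst blur into a single mode, which no detector
settings can honestly separate, while at 1000 bp they resolve cleanly —
and the 1000-bp dispersion at a 0.89-Ma burst (0.245 pct points)
reproduces the peak width observed for the real cotton burst of that age
(0.24 pct points). The default is therefore a width calibration to
observed data, fixed before any recovery experiments were run.

**What the generator does not emulate:** indels and nested insertions,
substitution-rate heterogeneity across sites or copies, GC-biased
conversion, alignment artefacts, and competition between families for the
same genomic hit. Passing recovery tests therefore demonstrate that the
pipeline's accounting, peak separation and calibration are correct under
the stated stochastic model — not that the 2.58σ width clock is unbiased on
real genomes, where peak width has additional sources.

Because the width of a simulated peak is set by binomial sampling rather
than by whatever width process real bursts have, simulated-age recovery is
asserted only for the mean-divergence clock; the width clock's output is
reported alongside for inspection.

## Numerical choices

- Gaussian fits use bounded Levenberg–Marquardt (trust-region) least
  squares; initialisation μ₀ = window argmax, σ₀ = window width/4,
  A₀ = max count, with up to 5 jittered restarts from a fixed seed on
  failure. σ is constrained positive; |σ| < 10⁻⁸ raises a degenerate-fit
  error.
- Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) with p = 3 over the window's
  n bins; windows need ≥ 4 bins.
- The terminal histogram bin is closed at the upper range limit so
  100%-identity dots are countable; identities outside the range go to a
  reported overflow tally, never dropped.
- Peak windows are contiguous: the valley bin between two peaks belongs to
  the right (lower-identity) window.
- Coordinates are 0-based half-open internally; RepeatMasker and BLAST
  1-based inclusive coordinates convert on read.
- In the simulator, a terminal fragment shorter than 30 bp is absorbed into
  the preceding piece so fragments tile each copy exactly.

## Problem sizes

The validation suite simulates bursts of 400–2,000 copies of a 5-kb master
(2–10 Mb of evolving sequence per scenario), which gives per-peak standard
errors well below the tolerances being asserted while the full suite runs
in a few seconds. Family-clustering tests use hundreds of sequences of
120–300 bp, the scale at which O(n²) pairwise global alignment is
comfortable.

## Known limitations

- Valley splitting cannot separate bursts closer than their combined peak
  widths; the EM/mixture alternative common elsewhere is deliberately not
  the default, to keep the separation rule transparent.
- No Kimura or other multiple-hit correction on the identity axis: at the
  oldest dated peaks (~30% divergence) observed identity understates true
  divergence substantially.
- The width clock *K* = 2.58σ is applied as defined; the package takes no
  position on its bias, and provides the mean clock for comparison.
- Ortholog statistics are pairwise; multi-way alignment columns must be
  projected to pairs upstream.
- No bootstrap confidence intervals on burst ages.
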