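# Methods

`gamrec` analyses meiotic recombination events carried by individual
long sequencing reads from sperm.  A read aligned to both of a donor's
assembled haplotypes exposes a string of heterozygous markers, each
assigned to one haplotype; crossovers (CO), gene-conversion
non-crossovers (NCO) and complex events appear as characteristic
switch patterns in that string.  Because access-controlled data cannot
ship with the package, every analysis here runs on synthetic reads
from the package's own generator; the generator is first-class, tested
code and its defaults define the study conditions.

## The event model and likelihood

For a read whose QC-passing markers sit at integer positions
`x_1 <= ... <= x_n`, events originate in the window
`[x_1 - T, x_n + 1)` of integer size `W = x_n - x_1 + T + 1`.  The left
pad `T` (default 200,000 bp) lets a conversion tract that starts
upstream of the read still convert its leftmost markers; 200 kb keeps
the neglected tail mass of the longest tract scale the method targets
(~7.2 kb mean) below 1e-12.  Because per-pattern probabilities equal
`rho x (start-count mass)`, enlarging `T` beyond the reachable scale
changes nothing except the bookkeeping split between `lambda = rho W`
and the conditional start distribution; `T` is therefore a fixed model
constant shared by the simulator and the likelihood rather than a
tunable.

Per read:

* background haplotype ~ Bernoulli(1/2);
* at most one event, with probability `lambda_r = rho W_r` (`rho` in
  events per bp of window; configurations must keep `lambda_r < 1`);
* with probability `q` the event is a CO: breakpoint `b` uniform on the
  window flips all markers at positions `>= b`;
* otherwise an NCO: tract start uniform on the window, tract length
  geometric on {1, 2, ...} with mean `L` — a single geometric (single
  model, parameters `rho, q, L`, k = 3) or a two-component mixture
  (weight `m` on the long component, means `L1 <= L2`; mixture model,
  k = 5).  Markers covered by `[s, s + l)` flip.

The probability of an observed label vector marginalises the
background and the unobserved event.  Only flip sets that are empty,
a prefix, a suffix, the full set (1-switch or consistent patterns) or
a contiguous interior run (2-switch patterns) are possible; all sums
over starts and lengths have closed geometric forms, verified in the
tests against brute-force enumeration to 1e-10 and by exhaustive
pattern sums (all `2^n` label vectors sum to 1 for n up to 12).
Patterns with three or more switches have probability zero under the
at-most-one-event model; such reads (complex events, from e.g. patchy
mismatch repair) are excluded from fitting and counted separately.

Two deliberate simplifications:

* **Sequencing error is not modelled in the likelihood.**  Markers are
  taken to be the post-QC set; the matched simulator conditions
  (`SimulationConfig.tract_study`) emit only high-confidence,
  error-free markers.  Fitting noisy markers with this likelihood
  would inflate the short component.
* **At most one event per read.**  With realistic `lambda` well below
  1 this loses nothing; it is also what makes the closed forms exact.

With the background marginalised, a specific all-one-haplotype label
vector has probability 1/2 each; the *consistent class* (either
background) has probability 1 when `rho = 0`.

## Fitting, model comparison, uncertainty

The total log-likelihood is maximised over transformed parameters
(`log rho`, `logit q`, `logit m`, `log(L1 - 1)`, `log(L2 - L1)`; the
ordering `L1 <= L2` is built into the parameterisation, resolving
component-label switching) with L-BFGS-B under box bounds
(`rho < 1/max W_r` so every read's event probability stays below 1;
`L` in (1, 5e4]).  Multi-start (default 20 starts: one
moment-flavoured start plus dispersed random draws; ties resolve to
the lowest start index) guards against the ridge-shaped surface that
appears when few informative reads are available.  Convergence
tolerances: `ftol` 1e-13, projected-gradient 1e-9 on the transformed
scale.  AIC = 2k - 2 logL; model comparison reports the AIC difference
and relative likelihood in log10 form so nothing overflows.

Bootstrap CIs resample reads with replacement (implemented as per-read
weights over the packed sufficient statistics, so nothing is re-packed)
and refit from the full-data MLE; percentile 2.5/97.5 intervals,
default B = 200, refit failures counted and more than 20% failing is an
error.

Likelihood evaluation packs each read into a handful of integer
exponents plus its gap multiset; gap values repeat heavily across
reads, so each evaluation exponentiates only the unique gap values
(~5e3) and gathers.  One evaluation over 6e5 reads takes ~0.1 s on one
core.

## The synthetic-data generator

The generator emulates: marker maps with geometric inter-marker gaps
(default rate 4.5e-4/bp, i.e. ~2.2 kb spacing, giving ~9.8 expected
markers per mean-length read, matching the reported per-read marker
mean); truncated-normal read lengths (mean 21,778 bp — the reported
mean — SD 4,000 bp, bounds [2,000, mean + 4 SD]; only the mean is
reported, the shape is our choice); event placement exactly as the
likelihood above, with defaults at the published sperm MLE (`q` =
14.2%, `m` = 1.8%, `L1` = 34.6 bp, `L2` = 7,214.1 bp); two
base-quality bins per platform with configurable per-bin label-flip
error rates (high bins error-free, low bins 2e-3 by default), since
the platform QC thresholds act on binned BQ; complex events as >= 3
alternating geometric segments (default rate 0 — they exist for
classifier tests, not for fitting); and alignment-operation fixtures
that round-trip through the partition module, with optional planted
soft-clips and double-mismatch errors to exercise the read filters.

The event rate `rho` has no published value (the real experiment's
per-read event probability is far too small to study at desk scale).
The default 3.2e-6/bp compresses the ~10^8-read experiment into a few
10^5 reads by raising the per-read event probability to ~0.7 while
respecting `rho W < 1` for every read, so that a simulation of 2-6 x
10^5 reads carries a detected event set of the same order as the real
study's (~10^3 classified events).  It was chosen once from this
design calculation.

What the generator does *not* emulate: base-level sequence and
alignment artefacts (chimeras, mapping error), assembly phase
switches, real hotspot clustering of events (events land uniformly in
each read's window), inter-chromosome structure, and ascertainment
differences between platforms.  Passing tests therefore demonstrate
the correctness and internal consistency of the inference machinery —
not that real sperm data would yield the published numbers.

## Detection summaries

Given fitted parameters, the package reports the probability that an
NCO tract is *observed* — converts at least one marker and forms an
interior run (a two-switch pattern; tracts touching the first or last
marker mimic crossovers) — as a window-weighted average over reads,
the share of that detected mass contributed by the long component, and
the distribution of the number of consecutive converted markers.
Under the default window convention with its 200-kb pad, most of each
window cannot touch a marker at all, so the absolute detection
fraction is diluted relative to conventions with tighter windows; the
share quantities are unaffected.

## Event calling and classification

The partition module intersects the two per-haplotype alignment
partitions into a refined partition; 1-bp segments matching one
haplotype and mismatching the other are candidate SNVs.  Filters, in
order: >= 10 bp of match-to-both flank on each side (the strictest
reading of "matched alignment", and a deletion or mismatch on either
haplotype breaks the flank); distance from read ends and base quality
with platform thresholds (high tier: BQ >= 60 and >= 1,500 bp for
Sequel II, BQ >= 40 and >= 400 bp for Revio; classification tier: BQ
>= 30 with >= 500/200 bp); low-complexity and tandem-repeat mask
exclusion in either haplotype's coordinates (masks are consumed as
BED, producing them is out of scope).  Whole reads are dropped for
> 10 bp of soft clipping to either haplotype or > 100 double-mismatch
segments.  The coverage-support rule requires >= 3 overlapping reads
> 95% consistent with each haplotype.

Classification on the label string: 0 switches consistent; 1 switch
with >= 2 markers on each side CO, otherwise ambiguous; 2 switches
NCO (converted markers = the interior minority run); >= 3 complex.
Candidacy is decided on high-confidence markers; the final switch
structure is re-scored on the union of high- and classification-tier
markers (full re-scoring — the union may create new switches; the
alternative, support-only extension, is not what "added back to
improve resolution" suggests to us).  Reads sharing a transition-pair
coordinate key with another read are removed (all sharers), and
transition gaps must be covered by >= 3 reads per haplotype.  A manual
curation hook accepts an exclusion list of read ids.

## Statistics

The two-sample Anderson-Darling statistic follows the rank form
`A2 = 1/(nm) sum (M_i N - n i)^2 / (i (N - i))`, with only
distinct-value boundaries contributing — for tie-free data this is
exactly the classical statistic, and with ties it stays invariant to
tie ordering.  Significance is by label permutation with sample sizes
preserved (default 10,000 permutations); the p-value counts permuted
statistics at least as large as the observed one.  A strictly-larger
count would be marginally smaller and is what the source text's
wording suggests, but it returns p = 0 on fully tied inputs, so the
tie-inclusive convention is used; for continuous measurements the two
are almost surely identical.  The one-vs-many variant sums pairwise AD
statistics of a focal sample against each other sample, permuting each
pair independently.  Calibration suites verify ~5% type-I error at
alpha = 0.05 under iid nulls.

Fisher's exact test is two-sided by summing hypergeometric outcomes
with probability at most the observed (verified against explicit
enumeration); chi-squared is Pearson without continuity correction;
Fisher's method combines p-values via `-2 sum ln p ~ chi2(2k)`.
GC-bias is the fraction of converted strong/weak (G/C vs A/T)
heterozygous sites whose transmitted allele is strong, with a Wald
95% CI by default (clamped to [0, 1]; Clopper-Pearson available) —
the Wald form matches the published interval's width at the published
counts; the original CI method is not stated.  Motif-offset asymmetry
uses a sign-flip null: each source read's offsets flip orientation
together with probability 1/2 (the original permutation scheme is not
described; orientation randomisation is the natural null for a
strand-oriented asymmetry).

## Annotations

Genetic maps are linear interpolations of cumulative cM over anchor
positions, clamped (with a warning) outside the anchored range;
interval rates are cM/Mb.  All annotations share the marker-table
coordinate system — cross-assembly liftover is out of scope.  A read's
detectable interval is [2nd marker, 2nd-to-last marker); reads with
fewer than four markers are excluded from detectable-interval
analyses (a 3-marker read's interval would be empty).  CO events are
localised to the interval between the switch-flanking markers, NCOs to
the converted-marker span; offsets to the nearest oriented motif
(ties: smallest centre-to-midpoint distance, then leftmost; the motif
search extends 20 kb — read scale — around the localisation interval)
are signed positive-downstream and flip sign on minus-strand motifs.
CO-interval offsets weight each base of intervals <= 500 bp by
1/interval-length; NCO offsets weight each converted marker by 1/k.
Telomere-distance expectations distribute each read's unit mass over
its inter-marker intervals proportional to their genetic length, then
histogram by telomere distance (1 Mb bins within 20 Mb by default),
scaled to the observed event count.

## Numerical and interface choices

Coordinates are 0-based half-open throughout; markers are points at
base starts.  Geometric quantities use the continuation probability
`phi = 1 - 1/L` with the `0^0 = 1` convention so `L = 1` degenerates
cleanly.  Report percentages round half away from zero to one
decimal.  Every written table and JSON carries the package version,
seed and a configuration hash.  Outputs are deterministic for a fixed
seed; no computation is threaded.

## Problem sizes

The test suite simulates 2 x 10^5 reads for the mixture-recovery
check (bootstrap B = 40), 10^5 reads for the single-model recovery
and the simulator/likelihood consistency property, and smaller sets
elsewhere.  The acceptance script uses 1.2 x 10^6 reads — the largest
size whose simulate-plus-fit cycle runs comfortably on one core — with
the mixture's multi-start seeded from a cheap single-model fit.  Even
at that size the recovered mixture weight and CO fraction remain
genuinely stochastic quantities: their sampling spread across seeds is
of the same order as the published bootstrap CIs for the corresponding
parameters (the mixture weight is intrinsically hard to pin down, as
its wide published CI reflects), so recovered values scatter around
the generating truth rather than reproducing it digit-for-digit.  The
analysis drivers default to 3 x 10^4 reads so the whole pipeline
narrative runs in about a minute.

## Known limitations

* Identifiability of the mixture at realistic event rates is weak on
  small read sets: `(rho, q, L)` trade off along a likelihood ridge
  until a few hundred informative (switch-carrying) reads are
  available, and the long component's mean `L2` stays noisy well
  beyond that (mirrored in the wide published CI for the long
  component).
* The likelihood ignores residual sequencing error; applying it to
  markers that have not passed the BQ filters biases tract-length
  estimates.
* Complex events are simulated and classified but not resolved into
  CO/NCO outcomes, and are excluded from tract fitting.
* The absolute NCO detection fraction depends on the window-pad
  convention (see above); only share-type summaries are
  convention-free.
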