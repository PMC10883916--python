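# Methods

This note records the models, conventions and numerical choices behind
`arraychrom`, and what the synthetic data do and do not establish.

## Coordinate conventions

Internal coordinates are 0-based half-open on a circular replicon; interval
arithmetic is modulo the genome length, and fragments spanning the origin
are stored unwrapped (`end > length`). BED and bedGraph files use the same
convention on disk; GFF3 is converted at the boundary (1-based inclusive,
`start+1 / end`). Promoter-relative coordinates for in vitro templates are
1-based with no zero: the TSS is +1 and the base immediately upstream −1.
Strand is always `+`/`-`; operations that need a strand reject anything
else.

## Fragment-length resampling normalization

ChIP libraries differ in fragment-length distribution, which distorts
occupancy comparisons. Each library is thinned so retained lengths follow a
target normal — N(120, 18²) bp for *S. solfataricus* P2 data, N(150, 20²)
for *S. islandicus* LAL14/1. The algorithm is density-ratio thinning: the
empirical length density is a 1 bp histogram over the observed range with
empty lengths floored at one count (this keeps acceptance ratios finite and
bounded on sparse data at the cost of a slightly conservative yield when the
in-range support has holes); each fragment of length *l* is retained with
probability proportional to `normal_pdf(l) / empirical_density(l)`, the
constant chosen as large as possible with all probabilities ≤ 1, which
maximizes yield while keeping the retained distribution exactly
proportional to the target over the observed support. Resampling is refused
when no fragment lies within ±4 target standard deviations of the target
mean. On a 200,000-fragment uniform-[40, 300] library the retained set
(~35,000 fragments) matches the target to a one-sample Kolmogorov–Smirnov
statistic below 0.02; that threshold is this package's own acceptance bar —
no tolerance is inherited from elsewhere — and about half of the residual
statistic is the unavoidable discretization of integer lengths.

## Input normalization and replicate combination

IP and input binned tracks (30 bp default) are each scaled to counts per
million before taking a per-bin ratio with a +1 pseudocount on both sides.
This CPM-ratio contract is deliberately simple: it is scale-invariant,
exactly testable, and preserves the downstream quantity of interest
(enrichment over input). Replicates are combined per position by arithmetic
or geometric mean; the geometric mean is the default for zero-inflated
5′-end tracks in aggregate profiles. The geometric mean uses no pseudocount
by default (so the mean of 4 and 9 is exactly 6, and any zero gives zero);
an opt-in pseudocount *c* computes `exp(mean(log(x+c))) − c` for zero-heavy
tracks where a hard zero in one replicate should not erase the position.

## TSS discovery

Candidate positions require, relative to the adjacent upstream position in
the strand's 5′→3′ direction (wrapping at the origin): a count increase
strictly greater than `abs_min` (default 20 read 5′-ends) and a ratio
strictly greater than `fold_min` (default 5), with a zero predecessor
passing the ratio criterion. The absolute criterion is read as the
*difference* of counts; because the sentence could also be read as the
position's own count, `count_mode="absolute"` toggles that alternative.
Reproducibility is exact-position and strand-matched across ≥ 2 samples,
before clustering — clustering after calling implies candidates carry exact
coordinates. Chains with member gaps strictly below 5 bp form clusters; the
centre is the median member, rounded toward the lower coordinate for even
counts (a deterministic tie-break; nothing downstream is sensitive to the
direction). Signal is the 11 bp window sum centred on the cluster.

Classification searches, per operon, the window from 300 bp upstream to
3 bp downstream of the first CDS start on the operon strand; 300 bp covers
archaeal 5′-UTR ranges and +3 admits leaderless starts at the codon. The
strongest window count wins (ties: closest, then lower coordinate); a
cluster claimed by several operons keeps the closest. Remaining clusters
inside a CDS body are internal sense or antisense by strand, everything
else intergenic, so classes partition the clusters. The UTR is the
strand-aware distance from centre to CDS start (negative inside the codon);
primary TSSs with UTR < 4 nt are leaderless.

The differential stub is plumbing, not a dispersion model: condition-mean
CPM log2 fold changes with a +1 pseudocount, and a two-sided exact binomial
test of the condition-A count against the pooled library-size proportion,
with a Benjamini–Hochberg flag reported separately. It orders clusters
sensibly and is exactly testable, but it understates variance relative to a
negative-binomial model and its p-values should not be compared to ones
from such a model.

## ChIP-exo footprints

Replicate 5′-end tracks are scaled (reads per million by default; 1×
mean-coverage scaling is available because both conventions are in use for
such data), combined by geometric mean, and averaged over anchor windows
(±60 bp default), with minus-strand anchors flipped and strands swapped so
"sense" always means sense-of-array. Borders are modal exonuclease stops:
the upstream border is the argmax of the sense-strand aggregate in the
upstream search window, the downstream border the argmax of the antisense
strand downstream — λ-exonuclease stalls at the protein edge, piling read
5′-ends there, so the mode is the natural estimator and is exactly
recoverable on planted data. A border is reported only when its peak
reaches `min_peak_ratio` (default 3) times the strand's profile median;
ties take the lowest coordinate. The synthetic truth plants stops at −5 and
+16 relative to the repeat start; recovery is exact at zero jitter and
within ±1 bp at ±1 bp jitter with 200 anchors and 10⁵ ends.

## Peaks and proximity

Summit matching between replicates is greedy nearest-first with an
inclusive 40 bp bound ("maximal 40 bp" read as ≤), each peak in at most one
pair, ties toward the lower coordinate; window-join semantics would differ
only when three summits crowd within one bound, which the tests cover.
Filtering keeps peaks with mean enrichment strictly above 5 whose summit
lies outside excluded regions (CRISPR arrays, rRNA loci — supplied as
annotation). TSS-to-summit linking is strand-agnostic nearest-summit with
an inclusive 50 bp bound. Replicate consistency is reported as a
correlation of matched enrichments rather than an irreproducible-discovery-
rate model; the downstream peak set is defined by the match + enrichment
filter either way.

## Enrichment statistics

`fisher_exact_2x2` computes the two-sided probability-mass p-value by
enumerating the margin-fixed hypergeometric family in log space (gammaln),
including tables whose probability is at most the observed one times
(1 + 1e−7); the slack absorbs floating-point ties, matching the dominant
convention. Degenerate margins give p = 1. Bonferroni is `min(1, m·p)` with
a declared family size; for CID enrichment the family is fixed at
2 × (number of CIDs), covering both regulation directions. Operons are
assigned to CIDs by midpoint; an operon is flagged when at least one of its
genes carries the flag; empty CIDs are excluded with a warning.

## Synthetic data: what it emulates, what it does not

The generator builds a circular chromosome with CRISPR arrays (25 bp
repeats, 38 bp spacers, a leader per array, arrays alternating strand so
minus-strand logic is exercised), operons of 1–3 CDS, 21 bp non-canonical
binding sites (half with a nearby cryptic promoter), and a CID partition.
Planted truth: a strong leader TSS per array, cryptic spacer TSSs (a
configurable fraction of spacers, log-normal strengths reflecting the
heterogeneous activity of cryptic promoters), a primary TSS per operon
(~60% leaderless), per-repeat protection borders (−5/+16 default), and
per-feature occupancy levels (arrays 10×, non-canonical sites 5×,
leader 3× background). Fragment starts are drawn from the occupancy
density; 5′-end counts are a single multinomial draw over (position,
strand) weights — planted points spread uniformly over ±jitter plus a
uniform background — so track totals are conserved exactly and all
simulators are byte-reproducible under a fixed seed.

The simulators deliberately omit sequence-composition bias, read-level
errors, PCR duplicates, mappability and cross-linking bias. Passing tests
therefore demonstrate that the *inference logic* is correct under the
stated statistical structure, not that the pipeline is robust to every
artefact of real libraries. Genome-scale counts from the real datasets
(tens of thousands of TSSs, hundreds of differential calls) require the
deposited raw reads and external aligners and are out of scope; the
pipeline's recovery contracts on planted truth stand in for them.

## Problem sizes and defaults

The demo pipeline and tests use a ~33 kb chromosome, 2 arrays × 10 repeats,
20 operons, 2 replicates per assay, 2×10⁴–10⁵ fragments or 5′-ends per
sample — sizes chosen so planted effects are recovered with wide margins
while the whole suite runs in well under a minute, with the Fisher
enumeration sweep (all 2×2 tables with margins ≤ 30, ~164,000 tables) the
single largest test. Footprint-recovery checks scale up to 8 arrays × 25
repeats (200 anchors). All randomness flows from a single seed through
`numpy.random.default_rng`; the pipeline spawns per-stage child seeds from
the master seed and logs every parameter in its JSON report.

## Known limitations

- The resampling yield depends on the overlap between the empirical and
  target length distributions; heavily mismatched libraries retain few
  fragments, and the histogram floor makes the acceptance constant
  conservative when the observed length range has gaps.
- TSS reproducibility is exact-position; sub-base jitter between samples
  larger than the candidate spread can split true sites (mitigated by
  clustering, bounded in tests at ±2 bp recovery).
- The differential stub's binomial test ignores biological overdispersion.
- Border detection reports a single modal stop per side; double-peaked
  (shoulder) footprints yield the taller mode only.
- Circularity is assumed throughout; linear replicons are supported in
  coverage and windows but anchors near the ends of a linear replicon are
  rejected rather than truncated.
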