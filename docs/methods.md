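# Methods

This note records the models, conventions and numerical choices behind
coreskew, what the synthetic-data generator does and does not emulate,
and the problem sizes the test suite runs at.

## Coordinates, annotations, genetic code

Internally every feature is 0-based half-open; GFF3 I/O is 1-based
inclusive.  The chromosome is treated as circular but must be supplied
linearized (single contig); features wrapping the sequence end are
rejected rather than split.  Translation uses the bacterial genetic
code (NCBI table 11); a trailing stop is stripped and an internal stop
is an error by default (maskable to X).  The coding-gene set excludes
rRNA/tRNA features and any CDS whose product text matches
"RNase"/"ribonuclease" (case-insensitive) — ribonucleases are
untranslated-RNA machinery that expression analyses leave out; a
`drop_pseudo` option additionally removes products mentioning
"pseudo", since annotation pipelines differ in whether pseudogenes
survive to the feature table.

## Skew curves and terminus calling

Cumulative skews are per-base counts: +1 per G / −1 per C (GC skew),
+1 per T / −1 per A (TA skew), accumulated 5'→3' along the supplied
strand and stored every 1 kb (configurable stride) plus the final base.
A `cds3` variant restricts the increments to third codon positions of
coding sequences, where selection is weakest and the replication-strand
mutational bias shows most cleanly; for strongly skewed genomes both
modes place the extrema in the same location.  The coding-direction
skew adds +1 per forward gene and −1 per reverse gene at gene
midpoints.

The combined curve is the equal-weight sum of the component curves
after linear interpolation onto the union grid and min–max scaling to
[−1, 1]; scaling prevents the per-base curves (thousands of counts)
from drowning the per-gene curve (hundreds).  Weights are exposed.

The terminus is the global extremum of the combined curve whose value
lies farther from the mean of the curve's endpoint values; the opposite
extremum is the origin.  Ties break to the smallest coordinate, for
determinism.  Because assemblies are conventionally rotated so the
origin sits at coordinate 0, an `origin_override` (e.g. 0) replaces the
curve-derived origin when the user knows better.

**No-signal guard.**  A skewless sequence still produces a ±1 random
walk whose range grows like √N.  `call_terminus` computes, for each
component curve, range/√(contributing steps) and raises
`NoSkewSignalError` when every curve falls below `snr_min = 5` — about
twice the null expectation, and an order of magnitude below genuine
replication skews at these genome sizes.

**Terminal regions.**  Around the called terminus the caller expands
the maximal contiguous interval on which (a) the combined curve stays
within `epsilon = 0.02` × its range of the terminus value and (b) the
20-gene windowed forward-strand fraction is compatible with no bias.
Two numerical adjustments make (b) usable: the nominal band
[0.40, 0.60] is widened to at least ±2 binomial standard deviations
(0.5/√window ≈ 0.11 at window 20), and failing stretches shorter than
¾ of the window's genomic span are bridged before expansion — otherwise
single noisy windows inside a genuinely unbiased plateau truncate it
almost surely.  A call is a *region* when the interval exceeds
`region_min = 10 kb`.  The detector's resolution is about one window
span (~25 kb at typical gene density): recovered widths below that are
not meaningful, and a sharp terminus can carry an apparent region of
that order.  All thresholds are parameters.

**Strand conventions.**  The replichore × strand classes use assembly
coordinates: the right replichore is the origin→terminus arc in
increasing coordinates, and "forward" is the assembly plus strand, so a
genome with leading-strand bias shows ~77% forward on the right
replichore and ~23% forward on the left.  Published tables of this kind
often count "forward" in a replication-oriented convention instead
(leading-strand genes on both replichores), which is why printed
genome-wide "forward strand" percentages can reach ~75%; the strand-
bias reporter is agnostic — it sums whatever four class counts it is
given, and its forward/reverse totals and percentages (rounded half
away from zero to one decimal) are exact arithmetic on those counts.

## Codon metrics

GC content ignores N bases entirely.  CAI follows the classical
relative-adaptiveness construction: within each synonymous family of
the reference set, w = count / max family count; unobserved codons get
w = 0.5/max (a pseudo-count that keeps log w finite); families never
observed at all get w = 1 for every member (no information, no
penalty).  A gene's CAI is the geometric mean of w over its codons,
excluding ATG, TGG and stops, which offer no choice.  The reference set
defaults to all coding sequences of the genome — reproducible on any
input — and can be restricted to a named gene list (e.g. ribosomal
proteins) when a curated reference is preferred.  Absolute CAI values
depend strongly on that choice, so cross-dataset CAI comparisons are
meaningful only within one reference convention.

## Gene families, core and pan genome

Protein identity is computed from one optimal global alignment
(BLOSUM62, affine gap: first residue 11, each further residue 1) as
identical columns / alignment length *including gap columns* — one
defensible reading of "percent identity"; a shorter-sequence
denominator would only raise identities and is not used.  Clustering is
greedy centroid: genes sorted by decreasing length (ties by gene id,
then genome label, so genome input order is irrelevant), each gene
joining the first cluster whose representative aligns at ≥ cutoff
(default 0.70), else founding one.  Greedy centroids cannot chain two
distinct families through an intermediate, unlike transitive single
linkage; on instances whose within-family identities sit ≥10 points
above the cutoff and between-family identities well below it, the two
procedures agree (tested against an independent DP oracle).  A k-mer
prefilter (shared 5-mer fraction ≥ 0.2 of the smaller sequence's k-mer
set) skips hopeless alignments; at identities near 0.8 the expected
shared-5-mer fraction is ≈0.8⁵ ≈ 0.33, comfortably above the
threshold, and the suite verifies the prefilter never changes the
clustering on test instances.  Paralogs may share a cluster; presence
is boolean per genome.  Rarefaction averages pan growth over random
genome orderings (exhaustive when G! is within the requested count) and
is seeded.

A nucleotide clustering mode (match 2 / mismatch −3, gaps 5/2) exists
for users who prefer DNA-level identity; protein mode is the default.

## Expression, mass sets, core transcriptome

RPKM_i = counts_i / ((length_i/10³) × (Σcounts/10⁶));
TPM_i = (counts_i/length_i) / Σ(counts/length) × 10⁶.  Technical
replicates are averaged into their biological replicate first; the
per-gene summary is the arithmetic mean and sample (ddof 1) standard
deviation of RPKM over biological replicates; a single replicate
reports sd 0 with a warning.

The p mRNA-mass set ranks genes by decreasing mean RPKM (ties by gene
id) and takes the smallest prefix whose RPKM sum reaches p × total.
This cumulative-mass reading — rather than a value-percentile cut — is
what makes "the genes carrying 90% of the mRNA" well defined for
heavy-tailed expression; a `percentile_threshold_set` helper implements
the value-percentile alternative for comparison only.  Mass is computed
on un-normalized RPKM by default; a TPM option exists since TPM mass is
the molar-fraction-correct choice (`mass_metric: tpm` in the run
config).  The core transcriptome is the set of core families with at
least one member gene inside the 0.9 mass set of every organism; it is
by construction a subset of the core genome, asserted on every run.

## Comparative statistics

Core vs non-core comparisons use Welch's t (unequal variances,
Welch–Satterthwaite df, two-sided p) per organism and factor:
log₁₀ mean RPKM (zeros floored at RPKM 0.01 — below any expressed
gene, so floored genes rank last without −∞), GC fraction, CAI, and
length.  No multiple-testing correction is applied; p is reported raw
against α 0.05 and the factor count is small.  Cross-organism
correlations are Pearson on per-cluster values over core clusters with
exactly one member in every organism (single-copy, so values are
unambiguous), reported as R² with stars at p < 0.05 / 0.001 / 0.0001.
Gene location is midpoint / genome length measured from the assembly
start, in [0, 1); assemblies rotated to the origin make this
directly comparable across genomes.

## Synthetic data: what it emulates, and what it does not

The generator plants, per dataset: an origin at 0 and a terminus at
55% of the genome (making the right replichore the longer arc); gene
families (default 400 core + accessory in nonempty *proper* subsets of
the genomes, so the planted core count is exact); within-family
divergence by independent per-site substitution from a family ancestor
at rate 1 − √(target identity), giving the target expected pairwise
identity (realized ±0.03 at 300 aa); back-translation with codon
weights that target the genome GC and prefer G/T-bearing codons
(`coding_keto_bias = 0.35`) so coding regions carry the
replication-strand asymmetry; intergenic background with a per-strand
G-over-C and T-over-A excess (`skew_amplitude = 0.15`) flipping sign at
the terminus — these lactobacilli show unusually strong TA skew, and
the amplitude is chosen so the planted skew towers over the √L random
walk even on 0.5 Mb scaled-down genomes; genes on the leading strand
with probability 0.77, matching the clade's strand bias; optionally an
unbiased plateau of stated width around the terminus (flat skew, 50/50
strands) emulating a terminal region.

Expression: family-level rates from a lognormal body
(log₁₀ ~ N(1.0, 0.45)) with a Pareto tail (α = 0.95) grafted above the
body's 90th percentile.  This tail placement and exponent were chosen
so that, at ~1,600 genes, the 50% mass set is below 4% of genes in
essentially every draw and the 90% set spans ~25% of genes — the
concentration regime of the real data; a tail grafted at the 95th
percentile with α = 1.0 concentrates too weakly at this gene count.
Core families are shifted by +0.8 log₁₀ (the direction and scale of
the observed core-expression excess); per-organism jitter of
0.1 log₁₀ around the family rate makes cross-organism expression
highly correlated, as observed.  Counts are gamma-Poisson
(variance m + 0.1 m²) around depth × rate × length at 5 × 10⁶ reads.

Emulated deliberately *not*: phylogenetic structure (members diverge
independently from an ancestor — no tree), indels within families,
operons and terminators, rRNA/tRNA sequence content (placed as
features, filled with background), horizontal transfer, condition-
dependent expression.  Consequently, passing tests show the pipeline
recovers planted architecture, family structure and expression
concentration under realistic noise; they do not show robustness to
assembly errors, annotation noise, or real phylogenetic correlation.
Coding regions come out slightly GC-richer than the intergenic target
(codon constraints plus the keto preference), so whole-genome GC runs
~0.04 above the `gc_content` parameter at the defaults.

## Determinism and problem sizes

Every stochastic stage takes a seed; a fixed seed makes the generator
byte-identical (hash-tested) and the pipeline outputs reproducible.
The suite and the acceptance script run at deliberately scaled sizes:
terminus recovery on twenty 0.5 Mb genomes (~430 genes each);
core/pan recovery on 300 + 100 families across 3 genomes at 80–300 aa;
the expression analyses at 1,600 genes with 400 core over 20 seeds,
plus 200 null simulations; mass-set properties on 1,000 random
vectors.  These sizes keep each property estimable with tight margins
while a full run of suite plus acceptance script completes in a few
minutes on one core.

## Known limitations

- Terminal-region calling resolves widths only down to ~one bias
  window (~25 kb at 1 gene/1.2 kb); narrower published "terminal
  regions" cannot be distinguished from sharp termini by this
  detector.
- Greedy centroid clustering guarantees agreement with single linkage
  only when family divergences sit well away from the cutoff; families
  straddling the cutoff are split/merged by representative choice
  (longest member), which is deterministic but not globally optimal.
- Absolute CAI values are reference-set dependent (see above).
- The strand-bias reporter reproduces published totals only for rows
  whose printed per-class counts are internally consistent; rows with
  inconsistent printed arithmetic are not reconstructed.
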