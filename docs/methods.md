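# Methods

This note documents the models and procedures the package implements, the
defaults and why they are set where they are, what the synthetic-data
generator does and does not emulate, and the numerical choices that make
results deterministic.

## Intermutational distances

For each clone, mutations are sorted by (chromosome, position) and the IMD
of a mutation is the distance in bp to the next downstream mutation on the
same chromosome. Two classes of mutations carry no IMD and are counted
separately: the most downstream mutation of each multiply-mutated
chromosome (one per clone × chromosome) and mutations alone on their
chromosome. The bookkeeping identity
`entries + terminal + chromosome-singletons = total mutations`
is asserted in tests. Duplicate (clone, chromosome, position) records are
a hard error — an IMD of zero is undefined — and unknown chromosomes are
rejected rather than dropped, because silently losing coordinates would
bias every downstream spacing statistic.

## Proximal/distal partition and calling threshold

Pooled IMDs from many clones of one genotype are strongly bimodal:
within-cluster spacings of hundreds of bp versus between-singlet spacings
of tens to hundreds of kb. The partition is two-group k-means **on
log₁₀(IMD)**. The log scale is the scale on which the two modes are
roughly symmetric and separable; on raw distances the heavy right tail
dominates the within-group variance and the split point is unstable.
Initialization is deterministic — centroids at the 10th and 90th
percentiles of the log-distances — followed by Lloyd iteration to
convergence (scikit-learn's exact Lloyd k-means with `n_init=1`), so the
partition has no seed sensitivity; on small inputs the result is verified
in tests against the exhaustive optimal 1-D two-partition. The group with
the smaller median is labelled *proximal*. Fewer than four entries, or an
all-identical IMD set, is a degenerate input and raises an error rather
than returning an arbitrary split.

The calling threshold is the empirical (1 − exclusion) quantile of the
distal group (linear interpolation between order statistics;
`numpy.quantile`), with exclusion defaulting to 0.99: at least 99% of
distal IMDs strictly exceed the threshold. The threshold is intended to be
set once on a pooled reference dataset (e.g. all wild-type clones) and
then applied to every genotype being compared; `KataegisDetector` accepts
an explicit `threshold=` for exactly this use.

## Cluster calling

A kataegic cluster is a **maximal run of at least `min_mutations`
(default 5) adjacent mutations whose successive gaps are all strictly
below the threshold**, per clone and per chromosome. The "≥ 5 mutations"
reading (4 internal gaps) rather than "≥ 5 gaps" is used because clusters
with exactly five members are meaningful units; strict inequality at the
threshold is chosen so that ties break runs deterministically. Cluster
length is reported as `end − start` in bp. Runs never merge across
chromosomes or clones; maximality means the flanking gaps (where they
exist) are ≥ the threshold, so no two calls can overlap. The run-finding
core is a single shared function; the Monte Carlo null calls it verbatim,
which keeps the false-positive estimate an estimate for the actual caller.

Each call carries its members' strand polarity — `max(#ref C, #ref G) /
n` — and its pyrimidine-oriented spectrum. Aggregate strand coordination
over many clusters sums majority-strand members over all clusters and
divides by all members (rather than averaging per-cluster polarities);
this weights clusters by size and is the reading adopted for the
"fraction of clustered mutations that are strand-coordinated" statistic.

## Monte Carlo null model

The null scatters n distinct positions uniformly over the concatenated
genome (chromosome chosen proportional to length; collisions resampled)
and reports the fraction of replicate clones in which the caller finds at
least one cluster, with a Clopper–Pearson 95% interval. Per-clone loads
can be supplied as the observed load list, which the replicates cycle
through — clone loads vary widely and IMDs are clone-conditional, so
conditioning on the observed loads is the fairer null. Placement ignores
sequence context deliberately: the null asks about position scatter only.
Context-aware placement belongs to the synthetic generator.

Two analytic limits anchor the simulation and are checked in tests: the
mean interior spacing of n uniform points on a length-L chromosome is
L/(n+1), and for large L the spacing distribution approaches
Exponential(rate n/L) (Kolmogorov–Smirnov distance < 0.02 at n = 100,
L = 10 Mb, 10⁴ replicates). A union bound,
P(≥1 cluster) ≤ (n−k+1)·p^(k−1) with p = 1 − exp(−threshold·n/L),
bounds the estimate from above in tests.

At study-like settings — 25 mutations on a ~12.1-Mb 16-chromosome genome,
8.5-kb threshold, 5-mutation minimum — the estimated per-clone probability
of a spurious cluster is ~10⁻⁵ or below (0 hits in 10⁵ replicates is
typical), comfortably below the 10⁻³ scale at which cluster calls would
become suspect.

## Pyrimidine orientation, spectra and contexts

Deaminases act on cytosine, so every C:G-pair mutation is expressed as a
change at C: `C>N` records are plus-strand as written; `G>N` records map
to the complementary change on the minus strand (G>A ≡ C>T). A:T-pair
mutations are retained in totals but excluded from all at-C statistics.
Orientation is idempotent and the complement map is an involution
(property-tested).

Flanking contexts are read 5′-relative on the pyrimidine strand: offset o
of a plus-strand C is the base at pos+o; for a minus-strand C it is the
complement of the base at pos−o. Offsets default to (−2, −1) — the
positions at which deaminase preferences are quantifiable — but arbitrary
offset sets are accepted. Sites whose context would run off the
chromosome end are skipped and counted.

Context PFMs are per-position base frequencies; each position sums to 1
(checked to 10⁻⁹). Optional background normalization divides each
frequency by the genomic availability of that base and renormalizes —
e.g. against the −2 composition at TC dinucleotides, counted on **both
strands** (TC on plus, GA on plus read as minus-strand TC), since
pyrimidine-oriented targets exist on both.

## Motif similarity

Sandelin–Wasserman similarity between aligned equal-width PFMs:
Σ over columns of [2 − Σ_b (p₁(b) − p₂(b))²], bounded by [0, 2w] and
attaining 2w iff the motifs are identical (symmetry and bounds are
property-tested). Significance uses a fully specified permutation null:
random query motifs with columns drawn from a Dirichlet centred on the
genomic background composition (concentration 20 by default, i.e. mildly
perturbed background), and
p = (1 + #{null ≥ observed}) / (n_perm + 1). Database-driven motif
comparison tools tie their null to a target database and configuration
that is not reproducible here; the permutation scheme is a documented,
seedable substitute and is calibrated — when the query itself is a null
draw, p-values are uniform (KS-checked in tests) — but its p-values are
not numerically interchangeable with any specific external tool's.

The built-in motif library encodes the canonical deaminase preferences at
(−2, −1): AID 5′-WRC (W = A/T, R = A/G, soft 0.45/0.45 columns), APOBEC3G
5′-CCC (0.85 C at both positions), and APOBEC3A/APOBEC3B with 91% T at −1
and −2 columns A:C:G:T = 25:26:7:42 and 35:14:20:31 respectively. The A3A
and A3B motifs differ only in the mild −2 discrimination; with ≥ 1000
sites the squared-distance separation between the two −2 columns (~0.053)
is several times the sampling noise, so best-match assignment is reliable
(≥ 95% of trials in the acceptance suite).

## Synthetic-data generator

The generator emulates the *statistical structure* of
deaminase-mutagenized clone genomes, not the mechanism:

* **Genome**: 16 chromosomes with yeast-like lengths totalling ~12.07 Mb,
  i.i.d. bases at GC 0.38 (both configurable). I.i.d. sequence has no
  repeats, genes or replication-timing structure; context availability is
  uniform along the genome, which real genomes' local composition is not.
* **Singlets**: Poisson(mean 25 per clone, the wild-type-like median
  load) positions uniform over C/G sites, alternate allele drawn from the
  unclustered spectrum mix.
* **Clusters**: Poisson(0.65 per clone — ~26 clusters per 40 clones in
  the wild-type-like preset) clusters per clone. Member count is
  5 + Geometric(mean 5), capped at 26, giving the observed 5–26 range
  with mean ≈ 10. Gaps are log-normal with median 727 bp and
  σ(log₁₀) = 0.4418 — the value pinned by requiring the log-normal mean
  to equal the observed 1220-bp mean spacing within kataegic stretches —
  and the resulting spans are resampled (bounded retries) into the
  1.8–30-kb observed envelope. The generator draws gaps first and derives
  the span; span and member count are therefore not independently
  controlled, and their joint distribution is this package's own choice.
* **Strand and context**: each cluster draws a majority strand; members
  defect to the opposite strand with probability 1 − 0.88. Each member
  samples a target (−2, −1) context from the genotype's PFM and snaps to
  the nearest site (within a ±300-bp window, widened on failure) carrying
  the mutated base on its strand with exactly that context, so the
  realized context frequencies reproduce the planted PFM up to multinomial
  noise. Typical snap displacement on an i.i.d. genome is ~15 bp, which
  leaves the gap median recoverable within the tested 15%.
* **Spectra**: kataegic members draw from the kataegic mix (wild-type-like
  default 46:47:7 for C>T:C>G:C>A), singlets from the unclustered mix
  (87:11:2); the `ung1_delta` preset is 99.3:0.2:0.5 and `rev1_delta`
  100:0:0, reflecting loss of the abasic-site route to transversions.
* **Truth**: every mutation is labelled singlet or cluster-k; cluster
  intervals, planted strands and member counts are emitted alongside the
  catalog, and generation is byte-reproducible under (params, seed).

What passing recovery tests shows: the pipeline correctly inverts data
generated under its own distributional assumptions at realistic densities
(sensitivity ≥ 0.95, FDR ≤ 0.05 at ~200+ clones). What it does not show:
performance on real genomes with inhomogeneous mutation rates, repeat
regions, copy-number variation or mutation-calling artifacts — none of
which the generator models.

## Problem sizes and numerical choices

Defaults used by the test and acceptance runs: 10⁵ replicates for the
null probability (binomial CI half-width ~2·10⁻⁵ near zero), 10⁴
replicates for the spacing-distribution checks, 240 clones for
planted-cluster recovery, and ≥ 5000 sites for spectrum/PFM recovery at
the 2-point tolerance; each completes in seconds on one core. All
randomness flows through `numpy.random.default_rng` seeds; k-means is
deterministic by construction; quantiles interpolate linearly between
order statistics; gap ties at the threshold break runs; catalogs sort by
(clone, chromosome, position) with a stable sort so outputs are
byte-reproducible.

## Known limitations

* The IMD partition assumes genuine bimodality; on catalogs with a single
  spacing regime the split is degenerate and the package raises rather
  than guessing.
* The permutation p-value for motif similarity is internally consistent
  but not comparable to database-driven tools' E-values.
* The VCF importer handles single-allelic SNVs only, by design; complex
  and multi-allelic records must be decomposed upstream.
* BED export loses member-level detail (only span, size and polarity);
  the rainfall TSV retains per-mutation assignments.
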