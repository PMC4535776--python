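# Methods

This note documents the models behind each module, the parameter
defaults and why they were chosen, the numerical and design decisions
that were genuinely open, what the synthetic-data generators do and do
not emulate, and the known limitations. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Mitochondrial colonization clock (`insula.mito`)

**Model.** The sampled mitogenomes are assumed to form a star genealogy:
after a severe colonization bottleneck every sampled lineage descends
independently from a single founder haplotype, so mutations shared by
several animals are inherited (pre-colonization) and mutations private
to a lineage are new. The cohort consensus estimates the founder
sequence; each column where a genome departs from the consensus is a
candidate new mutation. With `m` counted mutation positions in `n`
genomes over `L` counted bases, the per-nucleotide mutation frequency is
`f = m/(n·L)`, which grows linearly with time since colonization under a
constant per-generation mutation rate and comparable generation times.
Dating is by proportionality against a calibration island of known age:
`t = t_cal · f/f_cal`.

**Counting rules.**

* The hypervariable control region (D-loop) is excluded from the
  numerator and the denominator: its mutation dynamics differ from the
  rest of the molecule and the calibration frequency was measured
  without it. The default interval is the mm9 chrM annotation,
  1-based 15,423–16,299 (877 bp of a 16,299 bp genome, leaving
  15,422 counted bp). The exclusion is part of the method; the
  coordinates are an explicit `control_region` argument everywhere, as
  the precise annotation is an assumption.
* Two-base IUPAC codes are read as Sanger double peaks (heteroplasmy).
  A position whose only evidence is heteroplasmic is flagged
  `counted=False`; when the same derived allele is fixed in another
  animal the double peak is interpreted as an inherited variant and the
  position enters the count exactly once (through its fixed carrier).
* Columns containing gap characters are indel columns and never yield
  point-mutation calls.
* Consensus is a strict per-column majority: unambiguous bases weigh 1,
  two-base ambiguity codes weigh 1/2 for each constituent. A tie or a
  column without any unambiguous call raises an error naming the
  column — ties are never broken silently, for reproducibility.
* Known recent immigrants are removed by the caller by id
  (`MitoAlignment.exclude`); the tool never auto-detects immigrants.

**Rounding.** The default age point estimate rounds the frequency
*ratio* to the nearest integer before multiplying by the calibration
age ("about twice as old" → 2 × 200 = 400 years). The unrounded value
and a 1-significant-figure alternative are always available; the
unrounded estimator is exactly linear in the focal frequency.

**Uncertainty.** The dominant sampling error is in the small mutation
count, so the interval resamples `K ~ Poisson(m)` (`n_boot` ≥ 100,
default 10,000) and maps each resample through the frequency and the
unrounded age; the central 95% percentile interval is reported, widened
if necessary to contain the point estimate. No uncertainty is
propagated from the calibration point itself, which the method treats
as exact.

**Conservation.** A call is "conserved" when every comparator species
in the matrix carries the consensus base at that position; an empty
species set is vacuously conserved, and a call position missing from
the matrix is an error naming the position.

**Packaged fixture.** `load_island_fixture()` reconstructs the
Heligoland cohort from the packaged 10-position mutation table: an
11-genome alignment on a deterministic synthetic mm9-length background
(only the tabulated columns carry information, which is all the clock
consumes), the six-species conservation matrix, and region annotations.
The optional 12th genome is the known recent immigrant with two private
variants, for exercising the exclusion path. The background sequence is
synthetic and fixed by a constant seed; it is part of the fixture
definition, not a tunable.

## Median-joining networks (`insula.haplonet`)

**Collapsing.** Columns containing a gap in any sequence are indel
columns; maximal runs of adjacent indel columns form one event each (an
11-bp insertion is one event). Haplotypes are classes of identical
sequence over the remaining polymorphic (substitution) columns; indel
events are recorded per haplotype (`annotate`) or dropped (`ignore`),
and never contribute mutational steps — matching how control-region
insertions are displayed as annotations rather than steps.

**Construction.** The network is built by iterating: (1) the ε-relaxed
minimum spanning network over the current sequence set — edge (u, v) is
included when the Hamming distance d(u, v) is within ε of the
bottleneck (minimax-path) distance between u and v, so ε=0 gives the
union of all minimum spanning trees; (2) for every pair of edges
sharing a node, the quasi-median of the three endpoint states
(per-site majority; a three-way disagreement contributes each value) is
a candidate latent vertex, and candidates whose connection cost to
their generating triple is within ε of the minimum are added. On
termination, unused median vectors are pruned: latent vertices of
degree ≤ 2 (a degree-2 Steiner point never shortens a path in Hamming
space), then medians that do not reduce the minimum spanning cost of
the node set. The retained medians are an exact minimum-cost,
minimum-cardinality subset while the candidate set is small (≤ 12),
greedy single-removal beyond. This is stricter than implementations
that keep cost-neutral alternative connections; it makes the output a
most-parsimonious network rather than a superposition of ties, and
makes the spanning cost well-defined for testing against an exhaustive
Steiner-tree oracle.

**Parameters and tie-breaking.** Default ε=0 (the convention of the
standard desktop implementation). All candidate orderings and MST
tie-breaks are lexicographic on the haplotype state string, so the
result is invariant to input order. Character weights are uniform.
Non-binary characters are treated as distinct states. At ε=0 the
candidate generation can miss a latent vertex that a globally optimal
(Steiner-minimal) connection requires — on exhaustive enumeration of
haplotype sets with ≤ 4 haplotypes over ≤ 6 binary sites this happens
in 6 of 1804 symmetry classes; at ε=1 the construction attains the
Steiner optimum on every class (this is the optimality scale used in
the acceptance test, with the unit-test suite covering the ε=0
properties: spanning-network containment, exact MST on tree-like
distances, single median for the perfect 3-star).

## Introgression blocks (`insula.introgression`)

**Input.** Per-SNP probabilities that a haplotype carries one copy from
the source subspecies, in the shape emitted by Hapmix HAPLOID mode:
rows (individual, haplotype ∈ {1,2}, chromosome, 1-based position,
probability), with the literal code 9 for unknown ancestry. The HMM
itself (phasing, copying model, generations-since-admixture, miscopying
rate) is upstream and out of scope — this module consumes its output.

**Calling and merging.** A SNP is introgressed when its probability is
≥ the certainty threshold (default 0.9). Code-9 SNPs are unknown:
under the default `bridge` policy they neither break nor extend a run
(sporadic unknowns would otherwise shatter real blocks); `break` is
available for sensitivity analysis. A single sub-threshold SNP always
terminates a run. A block runs from its first SNP to its last SNP + 1
(half-open): lengths are resolution-honest and never extrapolate past
observed support, at the cost of under-covering true block tails by up
to one SNP spacing per boundary. Reports use 1-based coordinates; BED
and bedGraph output is 0-based half-open.

**Profiles and fractions.** The cohort copy-number profile is a
sweep-line over block boundaries (verified against per-bp brute force);
overlapping blocks from the same haplotype violate the block invariant
and are rejected. Genome fractions with ≥ k copies use the summed
autosome lengths as denominator (sex chromosomes excluded unless an
explicit autosome list is given), and are non-increasing in k by
construction. Fixed regions are maximal intervals at full copy number
2N.

## Microsatellite diversity (`insula.microsat`)

Observed heterozygosity is the per-locus fraction of scored individuals
with two distinct alleles. Expected heterozygosity offers both the
plain gene diversity 1 − Σp̂² and Nei's small-sample unbiased estimator
(2n/(2n−1))(1 − Σp̂²); the unbiased form is the default since it is the
convention of the classic population-genetics packages, and the exact
estimator behind published tables is often unstated — both are reported
side by side. Allele frequencies are computed from scored alleles only,
so missing data is handled per locus; monomorphic loci give 0, not an
error. Mean alleles per locus is the arithmetic mean of distinct
observed allele counts, which can only decrease under subsampling.

## Geometric morphometrics (`insula.morpho`)

**Centroid size** is √Σᵢ‖xᵢ − x̄‖²: homogeneous of degree 1 in scale and
invariant to rotation and translation; degenerate (all-coincident)
configurations are rejected.

**GPA.** Full Procrustes superimposition: every configuration is
centered and scaled to unit centroid size, rotated onto the current
mean by the optimal orthogonal rotation, and the mean is re-estimated
(re-centered, unit size) until the Procrustes distance between
successive means falls below `tol` = 1e-10 (`max_iter` = 1000;
exceeding it returns `converged=False` with a warning rather than
raising, so partial results remain inspectable). Rotations are proper
(det +1): reflections are disallowed, so mirrored specimens (right
hemimandibles) must be flipped explicitly on input. Analyses operate in
Procrustes coordinates; orthogonal tangent-space projection is
available behind a flag but off by default, since shape variation at
the scales simulated here is small and the projection is numerically a
no-op to first order.

**Shape PCA** is the eigendecomposition of the covariance of the
aligned coordinates (specimens × 2k variables). Eigenvalues are clipped
at zero, component signs are fixed by making the largest-magnitude
loading positive (reproducible plots), and scores preserve pairwise
distances at full rank. Group shape differences are per-landmark
displacement vectors between group mean shapes, optionally projected
onto selected components, ready for wireframe plotting. Centroid-size
group comparisons use two-sided Mann–Whitney tests with Holm
correction; groups of fewer than 2 specimens are excluded with a
warning. When replicate digitization metadata is present, replicates
should be averaged after superimposition; the toolkit treats each row
of the input as one configuration and leaves replicate averaging to the
caller's preprocessing.

One recorded discrepancy: centroid size is sometimes described in
3-coordinate terms in the morphometrics literature even when landmarks
are digitized in 2-D; this implementation is strictly 2-D.

## Synthetic data (`insula.synthetic`)

All generators take an integer seed or a `numpy.random.Generator` and
are byte-deterministic under a fixed seed.

* **Mitogenome cohorts** — star genealogy: each genome independently
  accumulates `Poisson(mu·L)` mutations at uniform positions
  (within-genome collisions re-drawn: infinite-sites within a lineage,
  a safe approximation at ~10 mutations per ~170 kb of sequenced
  cohort), each mutation heteroplasmic with probability
  `heteroplasmy_prob` (emitted as the two-base IUPAC code). Defaults in
  the simulations mirror the study scale: 11 genomes, 16,299 bp
  genomes, 15,422 counted bp, ~10 expected counted mutations
  (mu = 10/(11 × 15,422) ≈ 5.9×10⁻⁵). Not emulated: shared internal
  branches, mutation-spectrum bias (transitions = transversions),
  selection. Passing tests show the estimator is calibrated *given* the
  star-genealogy assumption, not that real cohorts satisfy it.
* **Ancestry tracks** — SNPs on a regular grid (default spacing in the
  tests 4 kb, the density scale of the SNP arrays such local-ancestry
  panels use); the source-copy probability is 1 inside truth blocks for
  the listed haplotypes and 0 outside, plus Gaussian noise truncated to
  [0,1], with an optional fraction of code-9 unknowns. Truth blocks in
  the recovery tests are megabase-scale, as expected ~100 generations
  after admixture. Not emulated: HMM-correlated errors (noise is iid),
  variable SNP density, phase-switch errors.
* **Microsatellites** — Hardy–Weinberg draws from stated allele
  frequencies, optional missingness; expected heterozygosity
  identifiable as 1 − Σp² at large n.
* **Landmarks** — group mean shape + iid isotropic Gaussian landmark
  noise, then nuisance rotation/translation/scale drawn uniformly from
  stated ranges, with the applied transform recorded per specimen. Not
  emulated: digitization error structure, allometry, asymmetry,
  semi-landmarks.

## Problem sizes used in the test suite

The statistical checks run at sizes chosen to make their assertions
sharp: 1,000 simulated cohorts for clock calibration (unbiasedness
within 2 SE; ≥ 93% interval coverage), exhaustive enumeration of all
1,804 symmetry classes of ≤ 4 haplotypes over ≤ 6 binary sites for
network optimality, 100 random instances for the sweep-line/brute-force
identity plus 100 seeds at noise 0.05 for block recovery (mean coverage
Jaccard ≥ 0.95), and 10,000 genomes for the Poisson goodness-of-fit.

## Known limitations

* The clock assumes comparable generation times between focal and
  calibration islands, a strict star genealogy, and neutral
  accumulation; none is corrected for. The control-region coordinates
  are an annotation choice exposed as configuration.
* Published headline quantities that depend on unpublished or external
  data — the genome-wide introgression fraction of the real trio,
  published diversity tables, Bayesian population assignment, and real
  mandible coordinates — cannot be recomputed here; the corresponding
  pipelines are validated by ground-truth recovery on synthetic data
  instead.
* The median-joining network is a heuristic; its ε=0 form can miss
  Steiner-minimal connections (quantified above). Network layout and
  visualization are left to external viewers via GML/DOT.
* GO-term enrichment of fixed regions, the local-ancestry HMM itself,
  read processing and variant calling are out of scope; BED/bedGraph
  files are the hand-off points.
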