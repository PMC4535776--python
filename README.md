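# insula

Population-genetic and morphometric analyses for island colonization
studies of the house mouse (*Mus musculus*), built around the Heligoland
island population: dating a colonization from mitochondrial mutation
frequencies, summarizing haplotype relationships as median-joining
networks, segmenting local-ancestry probabilities into introgression
blocks, computing microsatellite diversity statistics, and analyzing
mandible shape with landmark-based geometric morphometrics. Every
analysis has a synthetic-data generator with known ground truth, so the
whole pipeline is testable without access to the original specimens or
sequencing data.

## The analyses

**Mitochondrial colonization clock** (`insula.mito`). After a
colonization bottleneck the sampled mitogenomes form a star genealogy:
each lineage descends independently from the founder haplotype, and
every base differing from the cohort consensus is a *new* mutation
accumulated since colonization. With `m` counted mutation positions in
`n` genomes over `L` counted bases (the hypervariable D-loop/control
region is excluded from both numerator and denominator), the
per-nucleotide mutation frequency is

    f = m / (n · L)

and, given a calibration island with frequency `f_cal` and historically
known age `t_cal`, the focal colonization age is `t = t_cal · f / f_cal`
(by default the frequency ratio is rounded to the nearest integer before
multiplying). Heteroplasmic double peaks (IUPAC two-base codes) are not
counted as new mutations when the same derived allele is fixed in
another animal — the variant is inherited, not new. A Poisson
resampling interval quantifies the counting uncertainty, and mutation
calls are scored for cross-species conservation against a comparator
matrix.

**Median-joining haplotype networks** (`insula.haplonet`). Aligned
control-region sequences are collapsed into haplotypes over their
variable substitution sites (indels are annotated as single events, not
counted as steps) and connected by the median-joining construction:
the ε-relaxed minimum spanning network, iteratively augmented with
quasi-median ("median vector") sequences where they reduce connection
cost, with unused medians pruned on termination. Networks are emitted
as GML and DOT with haplotype frequencies, population labels and
median-vector flags.

**Introgression blocks** (`insula.introgression`). Per-SNP
probabilities of carrying a haplotype copy from a source subspecies
(Hapmix HAPLOID-mode output shape; code 9 = unknown ancestry) are
thresholded at 0.9, merged into maximal runs (unknown SNPs bridge a run
but never start or end one), swept into a cohort copy-number profile,
and summarized as the genome fraction with ≥ k source copies plus the
regions fixed for the introgressing subspecies (all 2N haplotypes), in
BED/bedGraph.

**Microsatellite diversity** (`insula.microsat`). Observed
heterozygosity, expected heterozygosity (plain gene diversity and Nei's
unbiased 2n/(2n−1)·(1−Σp²)) and mean alleles per locus, per population,
from GenePop files or long TSV tables.

**Geometric morphometrics** (`insula.morpho`). Centroid size
(√Σᵢ‖xᵢ−x̄‖²), generalized full Procrustes superimposition (translation,
unit-centroid-size scaling, proper rotations only), shape PCA on the
covariance of aligned coordinates, group mean-shape difference vectors
for wireframe plots, and rank-based centroid-size comparisons with
multiple-testing correction.

## Worked example

The packaged mutation table for the Heligoland cohort (11 full
mitogenomes, 10 new point mutations outside the control region, two of
them with heteroplasmic co-carriers) runs through the clock in a few
lines:

```python
import insula
from insula.mito import counted_positions

alignment, matrix, annotations = insula.load_island_fixture()
cons = insula.consensus(alignment)
calls = insula.call_new_mutations(alignment, cons, annotations)
print(len(counted_positions(calls)))          # 10
freq = insula.mutation_frequency(calls, alignment.n_genomes,
                                 alignment.counted_length)
print(f"{freq:.3g}")                          # 5.89e-05
age = insula.estimate_age(freq, insula.KERGUELEN_CALIBRATION)
print(age.years, round(age.unrounded_years))  # 400.0 393
conserved = insula.conserved_positions(calls, matrix)
print([c.position for c in conserved])        # [5157, 5163, 15163]
```

The frequency 5.89×10⁻⁵ is 1.96 times the Kerguelen calibration
frequency (3.0×10⁻⁵, islands colonized ~200 years ago), so the island
population is about twice as old: the colonizing haplotype arrived
around 400 years ago. Three of the ten mutations (positions 5157, 5163
and 15163) sit at positions where rat, human, orangutan, dog, horse and
opossum all carry the consensus base — mildly deleterious variants
still segregating after the bottleneck.

The same pipeline is available from the shell:

```sh
insula date-colonization --alignment cohort.fasta \
    --control-region 15423:16299 --exclude HG_1450_2 \
    --calibration-freq 3.0e-5 --calibration-age 200 --out report/
insula build-network --fasta dloop.fasta --out net.gml
insula call-blocks --track track.tsv --chrom-sizes mm9.sizes \
    --threshold 0.9 --out blocks/
insula microsat-summary --genotypes pops.gen --out diversity/
insula morpho-gpa --landmarks mandibles.tsv --out morpho/
insula simulate mito --seed 7 --out sim/
```

Every command writes a `provenance.json` (version, parameters, seed)
sufficient to re-run it.

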