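# Methods

This note documents the models, algorithms, parameter choices and
known limits of `repeatfp`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic genomes and reads

The simulator builds a genome from an i.i.d. uniform A/C/G/T background
into which it *inserts* (never overwrites) single-copy UCOS-like genes
and TE family copies at uniformly drawn, non-overlapping insertion
points. Insertion rather than replacement means repeat content grows
the genome while leaving single-copy space untouched, so
UCOS-normalized copy number has an exact truth value. Each copy of a
family diverges from its consensus at Binomial(L, d) i.i.d.
substitution sites (d = per-copy divergence, in [0, 0.5)); indels are
not modelled, which keeps ungapped mapping-based recovery analytically
predictable. Satellite families tile a random 5–11 bp motif, giving the
low-complexity signature de novo clustering should flag. Class I
elements can carry a feature layout (5'LTR, GAG, AP, RT, RH, IT,
3'LTR with equal-length LTRs), class II a TIR–transposase–TIR layout;
layouts are lifted onto consensus coordinates and exported as GFF3
(1-based inclusive at the file boundary, 0-based half-open internally).

Paired-end reads: the number of pairs is
`round(mean_depth × G / (2 × read_length))` (Python `round`, i.e.
half-to-even at the boundary); fragment lengths are
Normal(insert_mean=300, sd=30) clipped to [read length, G]; fragment
starts uniform; mate 2 is the reverse complement of the fragment end.
Sequencing errors are i.i.d. substitutions at `base_error_rate`
(default 0.002); qualities are position-deterministic — constant Q35
with a 10-base linear tail down to Q8 — so Q20 end-trimming always has
a few bases to remove, while error placement remains independent of
quality, a deliberate simplification over platform error models. Read
ids encode the true fragment coordinates, which is how recovery tests
score error rates and mapping without a side table. A TSV truth file
records every placement with its mutated offsets; write→read→write is
byte-identical.

Features of real data the generator does not emulate: quality-dependent
errors, indels, GC bias, nested/fragmented insertions, heterozygosity.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to platform artefacts.

## Read preparation

End-trimming removes bases below Q20 iteratively from both ends
(interior low-quality bases stay); this is the plain reading of
"trimmed from the ends", not BWA's error-sum heuristic, and results
may differ slightly from BWA-style trimming. Equalized datasets clip
every read to its first 60 bp (the 3' end is the low-quality end on
this platform generation), size all libraries down to the smallest by
sampling without replacement, and repeat this for 49 seeded replicates;
replicate r under seed s is reproducible from (s, r) alone. Reads are
subsampled individually, not as pairs, since all downstream analysis is
single-end.

## Mapping

The mapper indexes every k-mer (default k = 13) of both strands of the
reference contigs and extends each candidate diagonal ungapped across
the full read, accepting the fewest-mismatch placement if mismatches ≤
ceil(0.08 × read length). Two choices matter for copy-number work:

- **Random tie-breaking.** A read from a multi-copy family often has
  several equal-best placements; one is chosen uniformly at random
  under the run's seed (mapq 0). Discarding multi-mappers would
  deflate family coverage; random placement keeps per-family totals
  unbiased.
- **Ungapped extension.** At the divergences studied (≤ 25%),
  substitutions dominate; coverage-based copy number is insensitive to
  rare small indels. This is a deliberate divergence from gapped
  aligners.

Seeds are non-overlapping k-mers of the read (plus the final k-mer), so
a read with more than (number of seeds − 1) mismatches can in
principle miss all seeds; at the default ceiling of 5 mismatches in a
60 bp read this is rare and the mapper's recall is validated against an
exhaustive sliding-window oracle in the tests. SAM import/export goes
through pysam with NM/MD tags; imported records use MD for mismatch
offsets when present.

Pileups store exact per-position depth and an aggregate high-quality
depth (bases ≥ Q20), but individual base qualities only where a read
disagrees with the reference. Memory is linear in mismatches rather
than coverage; every downstream rule (depth thresholds, alt support,
majority fraction) is computable exactly from these tallies. The one
constraint is that callers must use a base-quality cutoff equal to the
pileup's threshold (both default to 20); mismatched cutoffs raise an
error instead of silently under-filtering.

## Abundance

UCOS baseline = unweighted mean over UCOS contigs of per-contig mean
coverage (each gene counts equally regardless of length; a pooled,
base-weighted variant is available). Relative copy number = family mean
coverage / baseline. Superfamily totals sum member families' relative
copy numbers unweighted — a count-like quantity for fingerprint plots —
while genome fraction weights each family by consensus length:
Σ rel_cn × L / G. Both are exposed because they answer different
questions (how many elements vs how much genome).

## Diversity and feature partitioning

A site is variable iff quality-filtered depth ≥ 7 ("higher than 6"),
some non-reference base has ≥ 2 reads of quality ≥ 20, and the alt
fraction is ≥ 0.2. The explicit support/fraction rules replace legacy
consensus-quality semantics and are all configurable. Nucleotide
diversity is variable sites / contig length; it deliberately conflates
heterozygosity with inter-copy divergence — reads from all copies pile
onto one consensus and the two are not separable at this depth. For
log-scale plots, zero diversity is floored at 1/(2 × contig length),
recorded in output metadata.

Variants are partitioned across annotated features with precedence
gene features > LTR/TIR > outside; conservation (counts and lengths sum
to totals, percentages to 100) is asserted. Under uniform simulated
divergence the per-bp rates of LTR, GAG, AP, RT, RH and IT agree within
3σ binomial bounds — the machinery's null calibration. A caveat:
coverage thins over the first/last ~13 bp of a contig (reads must fit
entirely), depressing calls at element termini by far less than 3σ at
the validation depths.

Increasing simulated per-copy divergence increases called diversity
only until reads over locally dense mutation clusters exceed the
mapper's mismatch ceiling and drop out — the same truncation that
drives the mapping-vs-de-novo contrast below.

## Fingerprint PCA

Samples × superfamilies abundances are natural-log transformed (zero
cells floored at half the column's smallest positive value, recorded in
metadata), centered, scaled to unit variance, and decomposed via
`numpy.linalg.eigh` on the covariance matrix. Each component's sign is
fixed so its largest-magnitude loading is positive, which lets
replicate runs be compared by plain correlation without Procrustes
rotation. Replicate stability is summarised as the sign-aligned PC1/PC2
score correlation of each subsample replicate against the full-data
ordination. The independent check (tests and acceptance script)
recomputes components by SVD and by scikit-learn and requires agreement
to 1e-8.

A design note from calibrating the planted-structure scenario: dividing
every family by the same noisy UCOS baseline induces a common
compositional factor across all columns, and after unit-variance
scaling that factor competes with the planted signal for PC1. The
standard design therefore uses enough UCOS sequence (40 genes × 1.5 kb
at 6×) that baseline noise is small relative to per-family sampling
noise. Real studies face the same trade-off: the UCOS set is what
bounds comparability between libraries.

## Phylogeny

Per-sample consensus on each UCOS contig: positions with < 6 reads of
quality ≥ 20 become N; otherwise the top allele is emitted when it
holds ≥ 80% of filtered depth, else N (ambiguous/heterozygous). Note
the asymmetric depth conventions — consensus keeps depth-6 positions
("6 or more") while diversity requires depth 7 ("higher than 6");
both thresholds are configurable but default to their respective
readings. N→gap conversion, removal of every column containing any
gap, and a 50 bp minimum retained length per locus produce gap-free
locus alignments, a concatenated NEXUS matrix with a charset per locus,
and the locus set for gene trees.

Gene trees are neighbor joining on JC69 distances (p ≥ 0.75 raises a
saturation error); ties in the Q criterion break lexicographically, so
gene trees are fully deterministic, and NJ recovers additive matrices
exactly (the module's oracle). The STAR species tree roots each gene
tree on the outgroup, assigns ranks — root = taxon count, each child
internal node = parent − 1, all children of a non-binary node sharing
the same rank — and sets d(i, j) = 2 × rank(MRCA). Distances are
averaged over the gene trees containing both taxa and NJ on the average
gives the topology, rooted on the outgroup for presentation. Branch
lengths are in rank units, explicitly not substitutions; substitution
branch lengths and model selection are out of scope. Support comes from
a multilocus bootstrap: loci resampled with replacement (sites within
loci kept intact — the resampling unit is the locus; site-level
resampling is not performed), one STAR tree per replicate, point-tree
edges annotated with bipartition frequencies, and a majority-rule
consensus (dendropy) returned alongside. Gene trees are cached per
locus across replicates since they are deterministic.

## Repeat clustering

Candidate read pairs come from shared canonical k-mers (k = 17): the
index samples every 3rd position of each read, queries scan every
position (so discovery is independent of the pair's relative offset),
and k-mers seen in more than 64 reads are down-sampled with the run's
seed, bounding work on deep repeats without disconnecting them. Each
shared k-mer votes for an (orientation, diagonal); the top diagonal per
partner is verified by the ungapped overlap test (≥ 90% identity over
≥ 55% of the shorter read, boundary inclusive) and scored
identity × overlap fraction. Thresholds are exposed because the method
is a functional analogue of published graph clustering, validated
against planted truth rather than against any specific tool's output.

Louvain (networkx, seeded) partitions the graph. Louvain shatters very
dense single repeats — satellite blobs, and the positional segments of
long elements — so a supercluster pass merges communities whose
cross-edge count exceeds 0.2 × the smaller community's size.
Unrelated families share no edges and can never merge, and a single
bridge edge between two small communities sits at or below the
threshold. Reports list clusters at or above 0.01% of reads used
(boundary inclusive) with genome percentage = cluster reads / total
reads. If the read set exceeds the vertex budget it is subsampled with
the run's seed; percentages remain ratios of reads actually used.
Cluster annotation tests a DUST-like triplet score first (mean > 1.5 →
"low complexity"), then best k-mer containment (≥ 0.3) of
representative reads (highest graph degree) against a user-supplied
repeat library, else "unknown". Containment annotation degrades with
divergence from the library — expected, and why truth-based provenance
is used when scoring cluster-size recovery under consensus drift.

## Validation designs and problem sizes

The standard designs in `repeatfp.scenarios` are the package's study
conditions:

- Copy-number recovery: ~2 Mb genome, 20 UCOS × 1.5 kb, six 3 kb
  families at 1/5/5/20/20/100 copies with ≤ 5% per-copy divergence,
  60 bp reads at 6× — median relative error of relative copy number
  is the reported statistic.
- Divergence contrast: the same families re-simulated after mutating
  each consensus at 25% of sites, mapped against the *undrifted*
  reference (UCOS are shared, as conserved genes would be); de novo
  clustering runs on 15,000 subsampled reads and per-family fractions
  are attributed by read provenance and compared to true occupancy.
- Diversity gap: five class I families (5% divergence) vs five class II
  (0.5%), five copies each, so a single mutated copy sits at the 20%
  allele-fraction threshold in both classes and the contrast reflects
  the divergence rates.
- Partition uniformity: one 6 kb annotated LTR element, five copies at
  5% divergence, 8×.
- PCA: six accessions in two groups differing 2× in LTR/Copia and
  DNA/hAT copy number, 80 bp reads at 6× equalized to 60 bp, 49
  replicates. Libraries are mapped once and each replicate's
  abundances are accumulated from its read subset's alignments — a
  read's placement does not depend on the other reads sampled, so this
  is the same computation at ~50× less cost.
- Species tree: 100 gene trees on 6 taxa, 20% replaced by random
  topologies, STAR + 100 bootstrap replicates.

These sizes were chosen as the smallest at which the binomial sampling
bounds quoted above are meaningful; all scenario runners accept a seed
and are deterministic given one.

## Known limitations

- The mapper is calibrated on simulations, not on parity with any
  external aligner; its defaults (k = 13, 8% mismatch ceiling) are
  package choices.
- No gapped alignment anywhere; indel-rich repeats would be
  under-recovered by the mapping route (the clustering route tolerates
  them up to the identity threshold).
- Variant calling has no genotype-likelihood model and ignores indels.
- Cluster annotation by k-mer containment is a coarse stand-in for
  similarity search against a curated repeat database.
- Heterozygous genomes, nested insertions and platform error profiles
  are outside the simulator's model, so claims about them are outside
  the validation's reach.
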